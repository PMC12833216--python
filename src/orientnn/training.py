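"""Training protocol, accuracy metrics, statistics and efficiency profiling.

The evaluation protocol is intra-subject: a single continuous recording is
split chronologically into training (60%), validation (20%) and test (20%)
blocks — contiguous in time, so autocorrelated gait frames never leak across
the split. Accuracy is per-channel RMSE in degrees with a 5-degree
clinical-reliability threshold; efficiency is the trainable-parameter count,
the float32 storage footprint, and a per-frame FLOP census under an explicit
counting convention. Model comparisons over repeated training instances use
a pooled-variance two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from . import so3
from .baselines import BASELINE_SPECS, BaselineNet
from .model import OrientationNN, basic_module_angles, wrap_angle_deg
from .simulate import JOINTS, SyntheticTrial

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TTestResult",
    "chronological_split",
    "split_trial",
    "train_on_trial",
    "rmse_per_channel",
    "count_parameters",
    "storage_kb",
    "count_flops_per_frame",
    "ttest_compare",
    "phase_error_profile",
    "evaluate_on_trial",
    "static_calibration_error",
    "uncalibrated_report",
    "make_model",
]


@dataclass
class TrainConfig:
    """Optimisation protocol settings.

    ``learning_rate=None`` defers to the model's own default (0.005 for the
    physics-informed model; per-architecture values for the baselines).
    """

    learning_rate: float | None = None
    epochs: int = 100
    batch_size: int = 256
    split_fractions: tuple = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    df: int
    mean_difference: float


@dataclass
class MetricsReport:
    """Accuracy + efficiency summary for one trained model on one test block."""

    per_channel_rmse: np.ndarray          # (12,) degrees
    mean_rmse: float                      # degrees
    param_count: int
    storage_kb: float                     # float32 payload, KiB
    flops_per_frame: int
    phase_error_profile: np.ndarray | None = None  # (100, 12) degrees
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "per_channel_rmse": [float(v) for v in self.per_channel_rmse],
            "mean_rmse": float(self.mean_rmse),
            "param_count": int(self.param_count),
            "storage_kb": float(self.storage_kb),
            "flops_per_frame": int(self.flops_per_frame),
        }
        if self.phase_error_profile is not None:
            prof = np.where(np.isnan(self.phase_error_profile), None,
                            self.phase_error_profile)
            d["phase_error_profile"] = prof.tolist()
        d.update(self.extra)
        return d


def chronological_split(T: int, fractions=(0.60, 0.20, 0.20)):
    """Contiguous train/val/test index ranges covering ``[0, T)``.

    Sizes are ``floor(f1*T)``, ``floor(f2*T)`` and the remainder, preserving
    temporal order (train earliest).
    """
    if T < 5:
        raise ValueError(f"need at least 5 frames to split, got {T}")
    n1 = int(np.floor(fractions[0] * T))
    n2 = int(np.floor(fractions[1] * T))
    return range(0, n1), range(n1, n1 + n2), range(n1 + n2, T)


def split_trial(trial: SyntheticTrial, fractions=(0.60, 0.20, 0.20)):
    """Split a trial's streams chronologically; returns three dicts."""
    parts = []
    for rng_ in chronological_split(trial.n_frames, fractions):
        sl = slice(rng_.start, rng_.stop)
        parts.append({
            "X": trial.sensor_stream[sl],
            "y": trial.angle_stream[sl],
            "phase": trial.phase[sl],
        })
    return tuple(parts)


def make_model(name: str, seed: int | None = None, epochs: int | None = None,
               learning_rate: float | None = None, batch_size: int = 256,
               **kwargs):
    """Model registry: name -> fresh estimator."""
    name = name.lower()
    if name in ("orientationnn", "orientnn"):
        return OrientationNN(
            learning_rate=0.005 if learning_rate is None else learning_rate,
            epochs=100 if epochs is None else epochs,
            batch_size=batch_size, random_state=seed, **kwargs)
    if name in BASELINE_SPECS:
        return BaselineNet(kind=name, learning_rate=learning_rate,
                           epochs=epochs, batch_size=batch_size,
                           random_state=seed, **kwargs)
    raise ValueError(f"unknown model {name!r}")


def train_on_trial(model, trial: SyntheticTrial, cfg: TrainConfig | None = None):
    """Fit ``model`` on a trial's chronological training block.

    Returns ``(model, report)`` where the report carries test-block accuracy,
    the phase-wise error profile, and the efficiency census.
    """
    cfg = cfg or TrainConfig()
    train, val, test = split_trial(trial, cfg.split_fractions)
    model.set_params(epochs=cfg.epochs if cfg.epochs else model.epochs,
                     batch_size=cfg.batch_size)
    if cfg.learning_rate is not None:
        model.set_params(learning_rate=cfg.learning_rate)
    if getattr(model, "random_state", None) is None:
        model.set_params(random_state=cfg.seed)
    model.fit(train["X"], train["y"], validation_data=(val["X"], val["y"]))
    report = evaluate_on_trial(model, trial, cfg.split_fractions)
    return model, report


def evaluate_on_trial(model, trial: SyntheticTrial,
                      fractions=(0.60, 0.20, 0.20)) -> MetricsReport:
    """Test-block metrics report for a fitted model."""
    _, _, test = split_trial(trial, fractions)
    pred = model.predict(test["X"])
    rmse = rmse_per_channel(pred, test["y"])
    return MetricsReport(
        per_channel_rmse=rmse,
        mean_rmse=float(rmse.mean()),
        param_count=count_parameters(model),
        storage_kb=storage_kb(model),
        flops_per_frame=count_flops_per_frame(model),
        phase_error_profile=phase_error_profile(pred, test["y"], test["phase"]),
    )


def rmse_per_channel(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-channel root-mean-square error in degrees (angle-wrapped)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    err = wrap_angle_deg(pred - target)
    return np.sqrt(np.mean(err * err, axis=0))


def count_parameters(model) -> int:
    """Exact census of trainable scalars (builds the model if needed)."""
    if not hasattr(model, "n_parameters_"):
        model.build()
    return int(model.n_parameters_)


def storage_kb(model) -> float:
    """float32 parameter payload in KiB, reported to one decimal."""
    return round(count_parameters(model) * 4 / 1024, 1)


def count_flops_per_frame(model, convention: str = "mac2",
                          with_bias: bool = False,
                          include_rotation_algebra: bool = False) -> int:
    """Deterministic per-frame FLOP census of a model's forward pass.

    Conventions: ``mac1`` counts one FLOP per multiply-accumulate, ``mac2``
    two. ``with_bias`` adds one FLOP per bias addition. Only learned linear
    maps are counted by default; for the physics-informed model,
    ``include_rotation_algebra=True`` adds the fixed SO(3) pipeline cost
    (matrix products, exp/log maps, Euler extraction) on top of the MLP cost.
    Elementwise activations and normalisations are excluded under every
    convention.
    """
    if convention == "mac1":
        f = 1
    elif convention == "mac2":
        f = 2
    else:
        raise ValueError(f"unknown convention {convention!r}; use 'mac1' or 'mac2'")

    if isinstance(model, OrientationNN):
        macs = 12 * (3 * 32 + 32 * 3)       # two tiny MLPs per joint
        bias = 12 * (32 + 3)
        total = macs * f + (bias if with_bias else 0)
        if include_rotation_algebra:
            # per joint: 5 3x3 matrix products, 2 exp + 2 log maps (approx.
            # 30 FLOPs each as implemented), one Euler extraction (~20).
            rot = 6 * (5 * 27 * f + 4 * 30 + 20)
            total += rot
        return int(total)

    kind = model.kind
    if kind == "mlp":
        macs = 63 * 128 + 128 * 128 + 128 * 12
        bias = 128 + 128 + 12
    elif kind == "lstm":
        macs = 4 * 128 * (63 + 128) + 128 * 12
        bias = 8 * 128 + 12
    elif kind == "cnn":
        macs = 9 * 63 * 64 + 9 * 64 * 12
        bias = 9 * 64 + 12
    elif kind == "transformer":
        spec = BASELINE_SPECS["transformer"]
        D, FF, nh = spec["d_model"], spec["d_ff"], spec["n_heads"]
        dk = D // nh
        per_layer = 7 * (3 * D * D + D * D) + 2 * nh * 7 * 7 * dk + 7 * (D * FF + FF * D)
        macs = 7 * 9 * D + spec["n_layers"] * per_layer + 7 * D * 12
        bias = 7 * (D + spec["n_layers"] * (3 * D + D + FF + D)) + 12
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return int(macs * f + (bias if with_bias else 0))


def ttest_compare(scores_a, scores_b) -> TTestResult:
    """Two-tailed independent-samples t-test with pooled variance."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    df = a.size + b.size - 2
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, df, 0.0)
        return TTestResult(np.inf * np.sign(diff), 0.0, df, diff)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), df, diff)


def phase_error_profile(pred, target, phase, n_bins: int = 100) -> np.ndarray:
    """Mean absolute wrapped error per gait-phase bin and channel.

    Phase 0 is heel strike. Returns an ``(n_bins, 12)`` array in degrees;
    bins with no frames are NaN (missing), never zero.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if np.any((phase < 0) | (phase >= 1)):
        raise ValueError("phase values must lie in [0, 1)")
    err = np.abs(wrap_angle_deg(pred - target))
    bins = np.minimum((phase * n_bins).astype(int), n_bins - 1)
    profile = np.full((n_bins, err.shape[1]), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            profile[b] = err[mask].mean(axis=0)
    return profile


# -- calibration recovery --------------------------------------------------

#: Null gauge directions of the static calibration per joint family. A joint
#: supervising fewer than three Euler channels leaves a continuous family of
#: calibrations producing identical supervised outputs: for a pure-z (knee)
#: joint, (pre, post) -> (Rz(-b) pre, post Rz(b) Ry(g) Rx(d)); for a z-y
#: (ankle) joint, post -> post Rx(d). Recovery is assessed modulo this gauge.
_GAUGE_DIMS = {3: 0, 2: 1, 1: 3}


def static_calibration_error(model: OrientationNN, trial: SyntheticTrial) -> dict:
    """Geodesic distance (degrees) of learned static calibrations from the
    analytic optimum, modulo each joint's structural gauge freedom.

    With mounting offsets ``O_k`` composed on the sensor side, the exact
    optimum is ``dR_pre = O_parent^T`` and ``dR_post = O_child``.
    """
    out = {}
    for joint in model.joints_:
        P = so3.exp_map(joint.pre_vec.data)
        Q = so3.exp_map(joint.post_vec.data)
        P_opt = trial.true_offsets[joint.parent].T
        Q_opt = trial.true_offsets[joint.child]
        ndim = len(joint.channels)
        gauge = _GAUGE_DIMS[ndim]

        def residual(params):
            b = params[0] if gauge >= 1 else 0.0
            if ndim == 1:          # knee: Rz(-b) pre / post Rz(b)Ry(g)Rx(d)
                g_, d_ = params[1], params[2]
                P_t = so3.euler_zyx_to_rot(np.array([-b, 0.0, 0.0])) @ P_opt
                Q_t = Q_opt @ so3.euler_zyx_to_rot(np.array([b, g_, d_]))
            elif ndim == 2:        # ankle: post Rx(d)
                P_t = P_opt
                Q_t = Q_opt @ so3.euler_zyx_to_rot(np.array([0.0, 0.0, b]))
            else:
                P_t, Q_t = P_opt, Q_opt
            return float(so3.geodesic_angle(P, P_t) + so3.geodesic_angle(Q, Q_t))

        if gauge == 0:
            err_pre = so3.geodesic_angle(P, P_opt)
            err_post = so3.geodesic_angle(Q, Q_opt)
        else:
            x0 = np.zeros(gauge)
            best = optimize.minimize(residual, x0, method="Nelder-Mead",
                                     options={"xatol": 1e-6, "fatol": 1e-9,
                                              "maxiter": 2000})
            # multistart over the gauge circle to dodge local minima
            for b0 in np.linspace(-np.pi, np.pi, 9)[1:-1]:
                x0g = np.zeros(gauge)
                x0g[0] = b0
                cand = optimize.minimize(residual, x0g, method="Nelder-Mead",
                                         options={"xatol": 1e-6, "fatol": 1e-9,
                                                  "maxiter": 2000})
                if cand.fun < best.fun:
                    best = cand
            params = best.x
            b = params[0]
            if ndim == 1:
                P_t = so3.euler_zyx_to_rot(np.array([-b, 0.0, 0.0])) @ P_opt
                Q_t = Q_opt @ so3.euler_zyx_to_rot(np.array([b, params[1], params[2]]))
            else:
                P_t = P_opt
                Q_t = Q_opt @ so3.euler_zyx_to_rot(np.array([0.0, 0.0, b]))
            err_pre = so3.geodesic_angle(P, P_t)
            err_post = so3.geodesic_angle(Q, Q_t)
        out[joint.name] = (float(np.rad2deg(err_pre)), float(np.rad2deg(err_post)))
    return out


def uncalibrated_report(trial: SyntheticTrial,
                        fractions=(0.60, 0.20, 0.20)) -> np.ndarray:
    """Per-channel test RMSE of the physics-only basic module (no learning)."""
    _, _, test = split_trial(trial, fractions)
    pred = basic_module_angles(test["X"])
    return rmse_per_channel(pred, test["y"])
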