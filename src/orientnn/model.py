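"""OrientationNN: physics-informed joint-angle estimation from IMU orientations.

The model is built around the kinematic identity that the rotation of a joint
is the relative rotation of its two adjacent segments,

    R_joint = R_A @ R_B.T                                   (basic module)

with A the parent (proximal) and B the child (distal) sensor. Because sensors
are strapped to segments with unknown mounting rotations, each joint carries a
pair of *learnable static calibrations* (Delta R_pre, Delta R_post),
parameterised as rotation vectors through the exponential map so they are
valid rotations by construction. On top, two *tiny MLPs* per joint
(3 -> 32 -> 3, ReLU) predict instantaneous rotation-vector offsets from the
log-map of each sensor orientation, absorbing soft-tissue and other
non-rigid effects:

    R_pre  = Exp(MLP_pre(Log(R_A)))
    R_post = Exp(MLP_post(Log(R_B)))
    R_joint = R_pre @ dR_pre @ R_A @ R_B.T @ dR_post @ R_post

The joint rotation is converted to intrinsic Z-Y-X Euler angles; the model
supervises 12 channels across six joints (hip: flexion z / adduction y /
rotation x; knee: flexion z; ankle: dorsiflexion z / inversion y) and trains
with a motion-range-weighted, angle-wrapped L1 loss in degrees.

Parameter census: each joint has 2 x 227 MLP scalars + 2 x 3 calibration
scalars = 460; six joints give 2,760 trainable parameters (10.8 KiB as
float32), which is what makes the model deployable on microcontroller-class
hardware.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from . import so3
from .simulate import CHANNELS, JOINTS, SENSORS, DEFAULT_RANGES_ONE_SIDE

__all__ = [
    "OrientationNN",
    "JointModule",
    "basic_joint_rotation",
    "basic_module_angles",
    "dynamic_offsets",
    "joint_forward",
    "model_forward",
    "weighted_euler_loss",
    "channel_weights_from_range",
    "wrap_angle_deg",
]

_HIDDEN = 32  # tiny-MLP hidden width (3 -> 32 -> 3)


def wrap_angle_deg(d: np.ndarray) -> np.ndarray:
    """Wrap angular differences in degrees to (-180, 180]."""
    r = np.mod(np.asarray(d, dtype=float), 360.0)
    return np.where(r > 180.0, r - 360.0, r)


def channel_weights_from_range(ranges) -> np.ndarray:
    """Inverse-motion-range loss weights, normalised to sum to n_channels.

    Channels with small ranges (e.g. hip rotation) would otherwise be
    dominated by large-range channels (knee flexion); inverse weighting
    equalises relative influence. All-equal ranges give all-ones weights.
    """
    r = np.asarray(ranges, dtype=float)
    if np.any(r <= 0):
        raise ValueError("motion ranges must be strictly positive")
    w = 1.0 / r
    return w * (len(r) / w.sum())


def basic_joint_rotation(R_A: np.ndarray, R_B: np.ndarray) -> np.ndarray:
    """Relative joint rotation of adjacent segments: ``R_A @ R_B.T``."""
    return np.asarray(R_A, float) @ np.swapaxes(np.asarray(R_B, float), -1, -2)


def basic_module_angles(X: np.ndarray) -> np.ndarray:
    """Uncalibrated joint angles (degrees) from the basic relative-rotation
    module applied to raw sensor orientations — the physics-only baseline.

    ``X`` has shape (n, 7, 3, 3) in canonical sensor order.
    """
    X = _validate_frames(X)
    out = np.zeros((X.shape[0], 12))
    for name, parent, child, chans in JOINTS:
        Rj = basic_joint_rotation(X[:, parent], X[:, child])
        eul, _ = so3.rot_to_euler_zyx(Rj)
        out[:, list(chans)] = np.rad2deg(eul[:, : len(chans)])
    return out


class JointModule:
    """Learnable state of one joint: static calibration pair + two tiny MLPs."""

    def __init__(self, name: str, parent: int, child: int, channels,
                 rng: np.random.Generator, init_scale: float = 1e-2):
        self.name = name
        self.parent = parent
        self.child = child
        self.channels = tuple(channels)
        self.pre_vec = ad.parameter(np.zeros(3), name=f"{name}.pre_vec")
        self.post_vec = ad.parameter(np.zeros(3), name=f"{name}.post_vec")
        self.mlp_pre = self._init_mlp(rng, init_scale, f"{name}.mlp_pre")
        self.mlp_post = self._init_mlp(rng, init_scale, f"{name}.mlp_post")

    @staticmethod
    def _init_mlp(rng, scale, prefix):
        return {
            "W1": ad.parameter(scale * rng.standard_normal((_HIDDEN, 3)), name=f"{prefix}.W1"),
            "b1": ad.parameter(np.zeros(_HIDDEN), name=f"{prefix}.b1"),
            "W2": ad.parameter(scale * rng.standard_normal((3, _HIDDEN)), name=f"{prefix}.W2"),
            "b2": ad.parameter(np.zeros(3), name=f"{prefix}.b2"),
        }

    def parameters(self, include_dynamic: bool = True) -> list[ad.Tensor]:
        params = [self.pre_vec, self.post_vec]
        if include_dynamic:
            for mlp in (self.mlp_pre, self.mlp_post):
                params.extend(mlp.values())
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def _mlp_apply(mlp: dict, x: ad.Tensor) -> ad.Tensor:
    h = ad.relu(x @ ad.transpose(mlp["W1"]) + mlp["b1"])
    return h @ ad.transpose(mlp["W2"]) + mlp["b2"]


def dynamic_offsets(R_A: ad.Tensor, R_B: ad.Tensor, mlp_pre: dict, mlp_post: dict):
    """Instantaneous rotation offsets predicted from the sensor orientations."""
    R_pre = ad.exp_rotvec(_mlp_apply(mlp_pre, ad.log_rotmat(R_A)))
    R_post = ad.exp_rotvec(_mlp_apply(mlp_post, ad.log_rotmat(R_B)))
    return R_pre, R_post


def _euler_zyx_t(R: ad.Tensor) -> ad.Tensor:
    """Differentiable intrinsic Z-Y-X Euler extraction, (..., 3, 3) -> (..., 3)."""
    z = ad.atan2(R[..., 1, 0], R[..., 0, 0])
    y = ad.asin(-R[..., 2, 0])
    x = ad.atan2(R[..., 2, 1], R[..., 2, 2])
    return ad.stack([z, y, x], axis=-1)


def joint_forward(R_A, R_B, joint: JointModule, use_dynamic: bool = True) -> ad.Tensor:
    """Full per-joint pipeline -> Euler triple (radians), differentiable.

    Composes, in order, R_pre dR_pre R_A R_B' dR_post R_post and extracts
    intrinsic Z-Y-X Euler angles. With ``use_dynamic=False`` the dynamic MLPs
    are bypassed (static-calibration-only model).
    """
    R_A = R_A if isinstance(R_A, ad.Tensor) else ad.constant(R_A)
    R_B = R_B if isinstance(R_B, ad.Tensor) else ad.constant(R_B)
    core = ad.matmul(R_A, ad.transpose(R_B))
    core = ad.matmul(ad.exp_rotvec(joint.pre_vec), core)
    core = ad.matmul(core, ad.exp_rotvec(joint.post_vec))
    if use_dynamic:
        R_pre, R_post = dynamic_offsets(R_A, R_B, joint.mlp_pre, joint.mlp_post)
        core = ad.matmul(ad.matmul(R_pre, core), R_post)
    return _euler_zyx_t(core)


def model_forward(X, joints: list[JointModule], use_dynamic: bool = True) -> ad.Tensor:
    """Assemble the (n, 12) degree-valued output from all six joints.

    Note the composition order: the static calibration wraps the measured
    relative rotation, and the dynamic offsets wrap the calibrated result.
    """
    Xt = X if isinstance(X, ad.Tensor) else ad.constant(X)
    cols: list[ad.Tensor | None] = [None] * 12
    for joint in joints:
        eul = joint_forward(Xt[:, joint.parent], Xt[:, joint.child], joint,
                            use_dynamic=use_dynamic)
        for local, chan in enumerate(joint.channels):
            cols[chan] = eul[..., local] * (180.0 / np.pi)
    return ad.stack(cols, axis=-1)


def weighted_euler_loss(pred, target, weights) -> ad.Tensor | float:
    """Motion-range-weighted, wrapped L1 Euler loss (degrees).

    ``mean over frames of sum_j w_j |wrap(pred_j - target_j)|``. Accepts
    autodiff tensors (training) or plain arrays (returns a float).
    """
    tensor_in = isinstance(pred, ad.Tensor)
    p = pred if tensor_in else ad.constant(np.asarray(pred, float))
    t = target if isinstance(target, ad.Tensor) else ad.constant(np.asarray(target, float))
    w = np.asarray(weights, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    if p.shape[-1] != w.shape[0]:
        raise ValueError("weight vector length must match channel count")
    if np.any(w <= 0):
        raise ValueError("loss weights must be strictly positive")
    err = ad.absolute(ad.wrap_deg(p - t)) * ad.constant(w)
    loss = err.sum(axis=-1).mean()
    return loss if tensor_in else loss.item()


class OrientationNN(RegressorMixin, BaseEstimator):
    """Physics-informed lower-limb joint-angle regressor.

    A scikit-learn style estimator: ``X`` is an array of per-frame sensor
    orientations with shape ``(n, 7, 3, 3)`` (canonical order: pelvis,
    thighR, thighL, shankR, shankL, footR, footL; world-to-sensor matrices)
    or flattened ``(n, 63)``; ``y`` is ``(n, 12)`` joint angles in degrees.

    Parameters
    ----------
    learning_rate : Adam step size (default 0.005).
    epochs : full passes over the training data (default 100).
    batch_size : frames per optimisation step (default 256).
    channel_ranges : 12 peak-to-peak motion ranges (degrees) from which the
        loss weights are derived; defaults to representative walking ranges.
    init_scale : SD of the Gaussian init of the tiny-MLP weights. Calibration
        vectors start at zero, so a fresh model is a near-exact basic-module
        (relative-rotation) solver — the physics prior.
    freeze_dynamic : if True, only the static calibration vectors train and
        the dynamic MLPs are bypassed entirely (used for calibration-recovery
        experiments).
    random_state : seed for initialisation and minibatch shuffling.

    Attributes (after fit or build)
    -------------------------------
    joints_ : list of six :class:`JointModule`.
    channel_weights_ : the 12 loss weights.
    loss_history_ : dict with per-epoch ``train`` and ``val`` losses.
    n_parameters_ : trainable scalar count (2,760).
    """

    def __init__(self, learning_rate: float = 0.005, epochs: int = 100,
                 batch_size: int = 256, channel_ranges=None,
                 init_scale: float = 1e-2, freeze_dynamic: bool = False,
                 random_state=None, verbose: int = 0):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.channel_ranges = channel_ranges
        self.init_scale = init_scale
        self.freeze_dynamic = freeze_dynamic
        self.random_state = random_state
        self.verbose = verbose

    # -- construction -----------------------------------------------------
    def build(self) -> "OrientationNN":
        """Initialise parameters without fitting (usable for inference of the
        physics prior, profiling, and checkpoint loading)."""
        rng = np.random.default_rng(self.random_state)
        self.joints_ = [
            JointModule(name, parent, child, chans, rng, self.init_scale)
            for name, parent, child, chans in JOINTS
        ]
        ranges = (DEFAULT_RANGES_ONE_SIDE + DEFAULT_RANGES_ONE_SIDE
                  if self.channel_ranges is None else self.channel_ranges)
        self.channel_weights_ = channel_weights_from_range(ranges)
        self.n_parameters_ = sum(j.n_parameters for j in self.joints_)
        self.loss_history_ = {"train": [], "val": []}
        return self

    def _trainable(self) -> list[ad.Tensor]:
        return [p for j in self.joints_
                for p in j.parameters(include_dynamic=not self.freeze_dynamic)]

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = _validate_frames(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 12:
            raise ValueError(f"y must be (n, 12) degrees, got {y.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.build()
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        opt = ad.Adam(self._trainable(), lr=self.learning_rate)
        n = X.shape[0]
        use_dyn = not self.freeze_dynamic
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = model_forward(X[idx], self.joints_, use_dynamic=use_dyn)
                loss = weighted_euler_loss(pred, ad.constant(y[idx]),
                                           self.channel_weights_)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch + 1}, "
                        f"batch starting at frame {start}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(loss.item())
            self.loss_history_["train"].append(float(np.mean(batch_losses)))
            if validation_data is not None:
                Xv, yv = validation_data
                vp = self.predict(Xv)
                self.loss_history_["val"].append(
                    weighted_euler_loss(vp, yv, self.channel_weights_)
                )
            if self.verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} train {self.loss_history_['train'][-1]:.4f}"
                if validation_data is not None:
                    msg += f" val {self.loss_history_['val'][-1]:.4f}"
                print(msg)
        self.n_features_in_ = 63
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "joints_")
        X = _validate_frames(X)
        out = model_forward(X, self.joints_,
                            use_dynamic=not self.freeze_dynamic)
        return out.data

    # -- parameter interchange --------------------------------------------
    def params_dict(self) -> dict[str, np.ndarray]:
        check_is_fitted(self, "joints_")
        return {p.name: p.data.copy() for j in self.joints_ for p in j.parameters()}

    def load_params(self, params: dict[str, np.ndarray]) -> "OrientationNN":
        if not hasattr(self, "joints_"):
            self.build()
        for j in self.joints_:
            for p in j.parameters():
                if p.name not in params:
                    raise KeyError(f"checkpoint missing parameter {p.name}")
                p.data = np.asarray(params[p.name], dtype=float).reshape(p.shape).copy()
        return self


def _validate_frames(X) -> np.ndarray:
    """Accept (n, 7, 3, 3) or flattened (n, 63); validate rotations loosely."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 63:
        X = X.reshape(-1, 7, 3, 3)
    if X.ndim == 3 and X.shape == (7, 3, 3):
        X = X[None]
    if X.ndim != 4 or X.shape[1:] != (7, 3, 3):
        raise ValueError(
            f"X must be (n, 7, 3, 3) sensor orientations or (n, 63), got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("sensor orientations contain non-finite entries")
    return X
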