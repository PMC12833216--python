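"""Synthetic treadmill-gait generator.

Produces paired streams of (7 body-segment/sensor orientations, 12 reference
joint-angle channels) with the statistical structure of treadmill walking
recorded by a 7-sensor lower-limb IMU set at 60 Hz: periodic joint
trajectories, a kinematic chain (pelvis -> thighs -> shanks -> feet), hidden
static sensor-mounting offsets, low-frequency soft-tissue artifact and white
orientation noise.

Orientation convention: all segment/sensor orientations are stored as
world-to-segment direction-cosine matrices, so that for a parent segment A
and child segment B the relative joint rotation is exactly ``R_A @ R_B.T``.

The hidden corruption parameters (per-sensor static offsets) are returned
with each trial so calibration-recovery experiments can compare learned
against true quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from . import so3

__all__ = [
    "SENSORS",
    "CHANNELS",
    "JOINTS",
    "GaitSimConfig",
    "SyntheticTrial",
    "generate_joint_trajectories",
    "forward_kinematics",
    "corrupt_to_sensors",
    "generate_trial",
]

#: Canonical sensor order (pelvis/lower-back first, then right before left).
SENSORS = ("pelvis", "thighR", "thighL", "shankR", "shankL", "footR", "footL")

#: Canonical 12 joint-angle channels, degrees.
CHANNELS = (
    "HipFlexR", "HipAddR", "HipRotR", "KneeFlexR", "AnkleFlexR", "AnkleInvR",
    "HipFlexL", "HipAddL", "HipRotL", "KneeFlexL", "AnkleFlexL", "AnkleInvL",
)

#: (name, parent sensor index, child sensor index, output channel indices).
JOINTS = (
    ("hipR", 0, 1, (0, 1, 2)),
    ("hipL", 0, 2, (6, 7, 8)),
    ("kneeR", 1, 3, (3,)),
    ("kneeL", 2, 4, (9,)),
    ("ankleR", 3, 5, (4, 5)),
    ("ankleL", 4, 6, (10, 11)),
)

#: Representative peak-to-peak walking ranges, degrees, for the six
#: right-side channels (hip flex/add/rot, knee flex, ankle flex/inv).
DEFAULT_RANGES_ONE_SIDE = (45.0, 12.0, 12.0, 65.0, 25.0, 12.0)


@dataclass
class GaitSimConfig:
    """Parameters of the synthetic gait generator.

    All amplitude-like fields are degrees. The sample rate is fixed at 60 Hz,
    matching the wearable-sensor streams the package consumes.
    """

    duration_s: float = 420.0
    sample_rate_hz: float = 60.0
    cadence_hz: float = 0.9
    channel_ranges: tuple = field(
        default=DEFAULT_RANGES_ONE_SIDE + DEFAULT_RANGES_ONE_SIDE
    )
    n_harmonics: int = 3
    mounting_offset_deg: float = 15.0
    soft_tissue_amp_deg: float = 3.0
    soft_tissue_cutoff_hz: float = 2.0
    meas_noise_deg: float = 0.5
    pelvis_sway_deg: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz != 60.0:
            raise ValueError("sample_rate_hz is fixed at 60 Hz")
        if len(self.channel_ranges) != 12:
            raise ValueError("channel_ranges must have 12 entries")
        for name in ("mounting_offset_deg", "soft_tissue_amp_deg",
                     "meas_noise_deg", "pelvis_sway_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(r < 0 for r in self.channel_ranges):
            raise ValueError("channel_ranges must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_ranges"] = list(self.channel_ranges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaitSimConfig":
        d = dict(d)
        if "channel_ranges" in d:
            d["channel_ranges"] = tuple(d["channel_ranges"])
        return cls(**d)


@dataclass
class SyntheticTrial:
    """A paired sensor/ground-truth stream plus its hidden simulation state."""

    sensor_stream: np.ndarray   # (T, 7, 3, 3) world-to-sensor rotations
    angle_stream: np.ndarray    # (T, 12) degrees
    true_offsets: np.ndarray    # (7, 3, 3) static mounting offsets O_k
    phase: np.ndarray           # (T,) gait-cycle fraction in [0, 1)
    config: GaitSimConfig

    @property
    def n_frames(self) -> int:
        return self.sensor_stream.shape[0]


def _fourier_pattern(rng: np.random.Generator, n_harmonics: int):
    """Random truncated Fourier series on gait phase, 1/h amplitude decay."""
    amp = rng.standard_normal(n_harmonics) / np.arange(1, n_harmonics + 1)
    pha = rng.uniform(0, 2 * np.pi, n_harmonics)
    harmonics = np.arange(1, n_harmonics + 1)

    def evaluate(phi: np.ndarray) -> np.ndarray:
        return np.sum(
            amp * np.cos(2 * np.pi * np.outer(phi, harmonics) + pha), axis=-1
        )

    return evaluate


def generate_joint_trajectories(cfg: GaitSimConfig):
    """Generate the 12-channel reference angle stream and the gait phase.

    Each right-side channel is a seeded truncated Fourier series in gait
    phase, rescaled so its peak-to-peak amplitude over the cycle equals
    ``cfg.channel_ranges[j]`` exactly (measured on a dense phase grid). The
    left-side channels are the right-side patterns shifted by half a cycle.
    Heel strike of the right leg defines phase 0 by construction.

    Returns
    -------
    angles : (T, 12) ndarray, degrees
    phase : (T,) ndarray in [0, 1)
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_frames
    t = np.arange(T) / cfg.sample_rate_hz
    phase = np.mod(cfg.cadence_hz * t, 1.0)
    dense = np.linspace(0.0, 1.0, 2048, endpoint=False)

    angles = np.zeros((T, 12))
    for j in range(6):
        pattern = _fourier_pattern(rng, cfg.n_harmonics)
        ref = pattern(dense)
        span = ref.max() - ref.min()
        for side, shift in ((0, 0.0), (6, 0.5)):
            rng_j = cfg.channel_ranges[j + side]
            if rng_j == 0 or span == 0:
                continue
            scale = rng_j / span
            centre = 0.5 * (ref.max() + ref.min())
            angles[:, j + side] = (pattern(np.mod(phase + shift, 1.0)) - centre) * scale
    return angles, phase


def _pelvis_sway(phase: np.ndarray, cfg: GaitSimConfig) -> np.ndarray:
    """Small seeded sinusoidal pelvis orientation sway, world-to-pelvis."""
    if cfg.pelvis_sway_deg == 0:
        return np.broadcast_to(np.eye(3), (phase.shape[0], 3, 3)).copy()
    rng = np.random.default_rng(cfg.seed + 101)
    pha = rng.uniform(0, 2 * np.pi, 3)
    a = np.deg2rad(cfg.pelvis_sway_deg)
    eul = np.stack(
        [
            a * np.sin(2 * np.pi * phase + pha[0]),
            0.5 * a * np.sin(4 * np.pi * phase + pha[1]),
            0.5 * a * np.sin(2 * np.pi * phase + pha[2]),
        ],
        axis=-1,
    )
    return so3.euler_zyx_to_rot(eul)


def forward_kinematics(angle_stream: np.ndarray, phase: np.ndarray,
                       cfg: GaitSimConfig) -> np.ndarray:
    """Place the 7 segments of the kinematic chain from the 12 joint angles.

    With world-to-segment matrices, a child segment is
    ``S_child = R_joint.T @ S_parent`` where ``R_joint`` is the intrinsic
    Z-Y-X rotation built from that joint's angle channels (degrees). The
    inverse computation ``S_parent @ S_child.T`` therefore recovers
    ``R_joint`` — and hence the input angles — exactly.
    """
    angle_stream = np.asarray(angle_stream, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if angle_stream.ndim != 2 or angle_stream.shape[1] != 12:
        raise ValueError(f"angle stream must be (T, 12), got {angle_stream.shape}")
    if phase.shape[0] != angle_stream.shape[0]:
        raise ValueError("angle stream and phase length mismatch")

    T = angle_stream.shape[0]
    rad = np.deg2rad(angle_stream)
    seg = np.empty((T, 7, 3, 3))
    seg[:, 0] = _pelvis_sway(phase, cfg)
    for name, parent, child, chans in JOINTS:
        eul = np.zeros((T, 3))
        eul[:, : len(chans)] = rad[:, list(chans)]
        Rj = so3.euler_zyx_to_rot(eul)
        seg[:, child] = np.swapaxes(Rj, -1, -2) @ seg[:, parent]
    return seg


def _lowpass_rotnoise(rng, T, sd_deg, cutoff_hz, fs):
    """Low-pass-filtered per-axis Gaussian rotation-vector noise (radians)."""
    white = rng.standard_normal((T, 3))
    b, a = signal.butter(4, cutoff_hz / (fs / 2.0))
    filt = signal.filtfilt(b, a, white, axis=0)
    std = filt.std(axis=0)
    std[std == 0] = 1.0
    return np.deg2rad(sd_deg) * filt / std


def corrupt_to_sensors(segment_stream: np.ndarray, cfg: GaitSimConfig):
    """Corrupt segment orientations into sensor orientations.

    Three seeded mechanisms, all composed multiplicatively (so every output
    is exactly a rotation, no reprojection needed):

    * a static per-sensor mounting offset ``O_k`` (rotation vector with
      magnitude drawn uniformly in [0, mounting_offset_deg]), applied as
      ``sensor = O_k @ segment`` — the left factor in the world-to-segment
      convention, which is what a fixed sensor-on-segment mounting produces;
    * soft-tissue artifact: per-axis Gaussian rotation-vector noise low-pass
      filtered at ``soft_tissue_cutoff_hz`` and scaled to a per-axis SD of
      ``soft_tissue_amp_deg / sqrt(3)`` (so the mean perturbation angle is
      close to ``soft_tissue_amp_deg``);
    * white orientation noise with per-axis SD ``meas_noise_deg``.

    Returns ``(sensor_stream, true_offsets)``.
    """
    S = np.asarray(segment_stream, dtype=float)
    T = S.shape[0]
    rng = np.random.default_rng(cfg.seed + 202)

    offsets = np.empty((7, 3, 3))
    sensors = np.empty_like(S)
    for k in range(7):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        mag = np.deg2rad(rng.uniform(0, cfg.mounting_offset_deg))
        offsets[k] = so3.exp_map(axis * mag)

    for k in range(7):
        out = offsets[k] @ S[:, k]
        if cfg.soft_tissue_amp_deg > 0:
            st = _lowpass_rotnoise(
                rng, T, cfg.soft_tissue_amp_deg / np.sqrt(3.0),
                cfg.soft_tissue_cutoff_hz, cfg.sample_rate_hz,
            )
            out = so3.exp_map(st) @ out
        if cfg.meas_noise_deg > 0:
            wn = np.deg2rad(cfg.meas_noise_deg) * rng.standard_normal((T, 3))
            out = so3.exp_map(wn) @ out
        sensors[:, k] = out
    return sensors, offsets


def generate_trial(cfg: GaitSimConfig | None = None, **kwargs) -> SyntheticTrial:
    """Generate a complete synthetic trial; bit-identical for equal configs."""
    if cfg is None:
        cfg = GaitSimConfig(**kwargs)
    angles, phase = generate_joint_trajectories(cfg)
    segments = forward_kinematics(angles, phase, cfg)
    sensors, offsets = corrupt_to_sensors(segments, cfg)
    return SyntheticTrial(
        sensor_stream=sensors,
        angle_stream=angles,
        true_offsets=offsets,
        phase=phase,
        config=cfg,
    )
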