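"""File interchange: sensor/angle CSV streams, configs, checkpoints, reports.

On-disk conventions
-------------------
* Sensor stream CSV: ``time_s`` column plus, per sensor in canonical order
  (pelvis, thighR, thighL, shankR, shankL, footR, footL), four columns
  ``<sensor>_w/x/y/z`` holding a Hamilton scalar-first unit quaternion.
  A rotation-matrix dialect (``<sensor>_r11`` ... ``_r33``, row-major) is
  also accepted on read.
* Angle stream CSV: ``time_s`` plus the 12 named channels in degrees.
  Column order on disk is irrelevant; headers are authoritative.
* Configs are YAML key/value echoes sufficient to regenerate the artifact.
* Checkpoints are a ``.npz`` of float32 parameter arrays plus a JSON
  manifest (model kind, sensor/channel orders, seed); the float32 payload
  size is the storage metric.

All numeric I/O is locale-independent ('.' decimal separator, UTF-8).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import so3
from .simulate import CHANNELS, SENSORS, GaitSimConfig, SyntheticTrial

__all__ = [
    "write_sensor_csv",
    "read_sensor_csv",
    "write_angles_csv",
    "read_angles_csv",
    "write_trial",
    "read_trial",
    "save_checkpoint",
    "load_checkpoint",
    "write_metrics_json",
]

_QUAT_COMPONENTS = ("w", "x", "y", "z")
_MAT_COMPONENTS = tuple(f"r{i}{j}" for i in range(1, 4) for j in range(1, 4))


def _time_column(n: int, sample_rate_hz: float = 60.0) -> np.ndarray:
    return np.arange(n) / sample_rate_hz


def write_sensor_csv(stream: np.ndarray, path, sample_rate_hz: float = 60.0) -> None:
    """Write a (T, 7, 3, 3) orientation stream as quaternion columns."""
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 4 or stream.shape[1:] != (7, 3, 3):
        raise ValueError(f"expected (T, 7, 3, 3), got {stream.shape}")
    cols = {"time_s": _time_column(stream.shape[0], sample_rate_hz)}
    for k, name in enumerate(SENSORS):
        q = so3.rot_to_quat(stream[:, k])
        for c, comp in enumerate(_QUAT_COMPONENTS):
            cols[f"{name}_{comp}"] = q[:, c]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_sensor_csv(path) -> np.ndarray:
    """Read a sensor stream CSV (quaternion or matrix dialect) -> (T, 7, 3, 3)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based CSV data row
        raise ValueError(f"{path}: non-monotone time_s at data row {bad}")

    quat_cols = [f"{s}_{c}" for s in SENSORS for c in _QUAT_COMPONENTS]
    mat_cols = [f"{s}_{c}" for s in SENSORS for c in _MAT_COMPONENTS]
    T = len(df)
    stream = np.empty((T, 7, 3, 3))
    if all(c in df.columns for c in quat_cols):
        for k, name in enumerate(SENSORS):
            q = df[[f"{name}_{c}" for c in _QUAT_COMPONENTS]].to_numpy()
            norms = np.linalg.norm(q, axis=1)
            bad = np.abs(norms - 1.0) > 1e-3
            if np.any(bad):
                row = int(np.argmax(bad)) + 2
                raise ValueError(
                    f"{path}: non-unit quaternion for sensor '{name}' at data "
                    f"row {row} (|q| = {norms[bad][0]:.6f})"
                )
            stream[:, k] = so3.quat_to_rot(q)
    elif all(c in df.columns for c in mat_cols):
        for k, name in enumerate(SENSORS):
            M = df[[f"{name}_{c}" for c in _MAT_COMPONENTS]].to_numpy().reshape(T, 3, 3)
            stream[:, k] = so3.project_to_rotation(M)
    else:
        missing = [c for c in quat_cols if c not in df.columns][:4]
        raise ValueError(
            f"{path}: expected quaternion columns like {missing} (or the "
            f"matrix dialect '<sensor>_r11'..'_r33') for sensors {SENSORS}"
        )
    return stream


def write_angles_csv(angles: np.ndarray, path, sample_rate_hz: float = 60.0) -> None:
    """Write a (T, 12) angle stream (degrees) with canonical channel names."""
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 12:
        raise ValueError(f"expected (T, 12), got {angles.shape}")
    cols = {"time_s": _time_column(angles.shape[0], sample_rate_hz)}
    for j, name in enumerate(CHANNELS):
        cols[name] = angles[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_angles_csv(path) -> np.ndarray:
    """Read an angle stream CSV -> (T, 12) degrees, order-normalised."""
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in CHANNELS and c != "time_s"]
    if unknown:
        raise ValueError(
            f"{path}: unknown channel column(s) {unknown}; expected "
            f"{list(CHANNELS)}"
        )
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    return df[list(CHANNELS)].to_numpy(dtype=float)


def write_trial(trial: SyntheticTrial, out_dir) -> dict:
    """Write a trial as sensors.csv + angles.csv + config.yaml (+ offsets)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sensor_csv(trial.sensor_stream, out / "sensors.csv",
                     trial.config.sample_rate_hz)
    write_angles_csv(trial.angle_stream, out / "angles.csv",
                     trial.config.sample_rate_hz)
    meta = {
        "config": trial.config.to_dict(),
        "true_offsets_quat": {
            name: [float(v) for v in so3.rot_to_quat(trial.true_offsets[k])]
            for k, name in enumerate(SENSORS)
        },
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return {"sensors": out / "sensors.csv", "angles": out / "angles.csv",
            "config": out / "config.yaml"}


def read_trial(in_dir) -> SyntheticTrial:
    """Read back a trial written by :func:`write_trial`."""
    d = Path(in_dir)
    with open(d / "config.yaml", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    cfg = GaitSimConfig.from_dict(meta["config"])
    sensors = read_sensor_csv(d / "sensors.csv")
    angles = read_angles_csv(d / "angles.csv")
    offsets = np.stack([
        so3.quat_to_rot(np.asarray(meta["true_offsets_quat"][name]))
        for name in SENSORS
    ])
    t = np.arange(sensors.shape[0]) / cfg.sample_rate_hz
    phase = np.mod(cfg.cadence_hz * t, 1.0)
    return SyntheticTrial(sensor_stream=sensors, angle_stream=angles,
                          true_offsets=offsets, phase=phase, config=cfg)


def save_checkpoint(model, path, seed=None, extra: dict | None = None) -> None:
    """Serialise a fitted estimator: float32 .npz + JSON manifest."""
    path = Path(path)
    params = model.params_dict()
    np.savez(path.with_suffix(".npz"),
             **{k: v.astype(np.float32) for k, v in params.items()})
    kind = getattr(model, "kind", "orientationnn")
    manifest = {
        "kind": kind,
        "sensor_order": list(SENSORS),
        "channel_order": list(CHANNELS),
        "seed": seed,
        "param_count": int(sum(v.size for v in params.values())),
        "storage_bytes": int(sum(v.size for v in params.values()) * 4),
    }
    if kind == "orientationnn":
        manifest["channel_weights"] = [float(w) for w in model.channel_weights_]
    if extra:
        manifest.update(extra)
    with open(path.with_suffix(".manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path):
    """Rebuild the estimator named in a checkpoint manifest."""
    from .training import make_model  # local import to avoid a cycle

    path = Path(path)
    with open(path.with_suffix(".manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    model = make_model(manifest["kind"], seed=manifest.get("seed"))
    with np.load(path.with_suffix(".npz")) as npz:
        params = {k: npz[k].astype(float) for k in npz.files}
    model.build()
    model.load_params(params)
    return model, manifest


def write_metrics_json(report, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict() if hasattr(report, "to_dict") else report,
                  fh, indent=2)
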