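"""File formats: HDF5 raw recordings, columnar CSVs, YAML run configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .gait import CourseMap
from .tensiometry import AccelRecording, WaveSpeedSeries


# --- raw recordings: one HDF5 group per trial --------------------------------

def save_recordings(path, recordings: dict) -> None:
    """Write ``{trial_id: AccelRecording}`` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for trial_id, rec in recordings.items():
            g = f.create_group(str(trial_id))
            g.create_dataset("ch1", data=rec.ch1, compression="gzip")
            g.create_dataset("ch2", data=rec.ch2, compression="gzip")
            g.attrs["fs"] = rec.fs
            g.attrs["start_time"] = rec.start_time


def load_recordings(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for trial_id, g in f.items():
            out[trial_id] = AccelRecording(
                ch1=g["ch1"][:], ch2=g["ch2"][:],
                fs=float(g.attrs["fs"]),
                start_time=float(g.attrs["start_time"]))
    return out


# --- CSV formats --------------------------------------------------------------

def save_kinematics(path, kin) -> None:
    df = pd.DataFrame({"time_s": kin.times, "ankle_deg": kin.ankle_deg,
                       "knee_deg": kin.knee_deg, "pelvis_x_m": kin.pelvis_x})
    if kin.foot_accel is not None:
        df["foot_accel"] = kin.foot_accel
    df.to_csv(path, index=False)


def load_kinematics(path):
    from .synthetic import JointKinematicsSeries
    df = pd.read_csv(path)
    fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return JointKinematicsSeries(
        times=df["time_s"].to_numpy(), ankle_deg=df["ankle_deg"].to_numpy(),
        knee_deg=df["knee_deg"].to_numpy(),
        pelvis_x=df["pelvis_x_m"].to_numpy(), fs=fs,
        foot_accel=df["foot_accel"].to_numpy() if "foot_accel" in df else None)


def save_wave_speed(path, ws: WaveSpeedSeries) -> None:
    pd.DataFrame({"time_s": ws.times, "speed_mps": ws.speeds,
                  "quality": ws.quality,
                  "valid": ws.valid.astype(int)}).to_csv(path, index=False)


def load_wave_speed(path) -> WaveSpeedSeries:
    df = pd.read_csv(path)
    return WaveSpeedSeries(times=df["time_s"].to_numpy(),
                           speeds=df["speed_mps"].to_numpy(),
                           quality=df["quality"].to_numpy(),
                           valid=df["valid"].to_numpy().astype(bool))


def save_course_map(path, course: CourseMap) -> None:
    course.to_frame().to_csv(path, index=False)


def load_course_map(path) -> CourseMap:
    df = pd.read_csv(path)
    return CourseMap(positions=df["position_m"].to_numpy(),
                     inclines=df["incline_deg"].to_numpy())


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# --- run configuration --------------------------------------------------------

def load_config(path) -> dict:
    """Load and validate a YAML run config (one document; seed mandatory)."""
    cfg = yaml.safe_load(Path(path).read_text())
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit integer seed")
    merged = default_config()
    merged["seed"] = int(cfg["seed"])
    for section in ("generator", "processing", "stats"):
        user = cfg.get(section, {}) or {}
        unknown = set(user) - set(merged[section])
        if unknown:
            raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
        merged[section].update(user)
    if "output_dir" in cfg:
        merged["output_dir"] = str(cfg["output_dir"])
    return merged


def default_config() -> dict:
    """Every pipeline tunable with its default, ready to serialize."""
    return {
        "seed": 0,
        "output_dir": "run",
        "generator": {
            "n_participants": 2,
            "strides_per_participant": 40,
            "course_length": 100.0,
            "course_section_length": 10.0,
            "course_max_slope": 10.0,
            "course_blend_length": 2.0,
            "noise_scale": 0.01,
            "sync_delay_range": [0.01, 0.1],
            "sway_duration": 20.0,
            "sway_noise_scale": 0.01,
            "mode": "fast",          # fast: direct wave-speed series;
                                      # full: render + process 50 kHz taps
        },
        "processing": {
            "bandpass_low": 150.0,
            "bandpass_high": 1500.0,
            "quality_floor": 0.5,
            "speed_bounds": [2.0, 150.0],
            "heel_strike_band": [10.0, 50.0],
            "min_stride_time": 0.4,
            "heel_strike_prominence_mads": 2.0,
            "max_stride_length": 3.0,
            "level_slope_max": 1.0,
            "sync_window_fraction": 0.10,
            "sync_max_lag": 0.15,
            "sync_min_strides": 5,
            "drift_threshold": 0.15,
        },
        "stats": {
            "bin_width": 2.0,
            "gait_grid_points": 101,
            "min_strides_per_segment": 10,
            "include_level_in_both": True,
        },
    }
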