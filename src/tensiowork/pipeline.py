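"""End-to-end pipeline: generate -> calibrate -> process -> analyze -> report.

Each stage reads and writes files under one run directory so stages can be
run independently (and from the CLI); :func:`run_pipeline` chains them.
All randomness flows from the single config seed through named substreams,
so a rerun with the same config is byte-identical.

Run directory layout::

    config.yaml                   resolved configuration
    dataset/course_map.csv        ground-truth course map
    dataset/truth.json            generator ground truth (per participant)
    dataset/<pid>/kinematics.csv  time_s, ankle_deg, knee_deg, pelvis_x_m, foot_accel
    dataset/<pid>/wave_speed_raw.csv   tensiometry clock (uncorrected)
    dataset/<pid>/sway_pre.csv, sway_post.csv
    dataset/<pid>/taps.h5         raw two-channel recording (full mode only)
    calibration/<pid>.json        fitted calibration + drift check
    processed/stride_table.csv    one row per stride incl. exclusions
    processed/curves.csv          per-stride wave-speed curves (101-pt grid)
    processed/mechanics/<pid>_stride<k>.csv
    analysis/regressions.json, bin_curves.csv
    report.json
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .calibration import (CalibrationModel, align_plate_to_accel,
                          ankle_moment_from_plate, BalancePlateRecording,
                          compare_calibrations, fit_calibration)
from .gait import (assign_and_bin_slope, detect_heel_strikes, stride_metrics,
                   strides_to_frame)
from .mechanics import stride_mechanics, work_against_gravity
from .slope_stats import (bin_average_curves, fit_slope_sensitivity,
                          normalize_wave_speed_curves, resample_to_gait_cycle,
                          zero_reference_work)
from .sync import apply_offset, estimate_sync_offset
from .synthetic import (default_gait_pattern, make_cohort_profiles,
                        make_course, make_sway_trial, make_trial,
                        render_tap_recording, TrialSpec)
from .tensiometry import bandpass_filter, wave_speed_series

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and trial identity."""

    def __init__(self, stage: str, trial: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {trial!r}: {cause}")
        self.stage = stage
        self.trial = trial
        self.cause = cause


@dataclass
class RunReport:
    """Bookkeeping for one pipeline run."""

    strides_total: int = 0
    strides_included: int = 0
    exclusions: dict = field(default_factory=dict)
    sync_offsets: dict = field(default_factory=dict)
    calibrations: dict = field(default_factory=dict)
    per_bin_counts: dict = field(default_factory=dict)
    regressions: list = field(default_factory=list)

    def validate(self) -> None:
        if self.strides_total != self.strides_included + sum(
                self.exclusions.values()):
            raise ValueError("report arithmetic is inconsistent")

    def to_dict(self) -> dict:
        return {
            "strides_total": self.strides_total,
            "strides_included": self.strides_included,
            "exclusions": self.exclusions,
            "sync_offsets": self.sync_offsets,
            "calibrations": self.calibrations,
            "per_bin_counts": self.per_bin_counts,
            "regressions": self.regressions,
        }


def _participant_ids(cfg) -> list[str]:
    return [f"P{i:02d}" for i in range(cfg["generator"]["n_participants"])]


def _substream(seed: int, label: str) -> int:
    # stable named substream below 2**31
    import zlib
    return (seed * 1_000_003 + zlib.adler32(label.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stage: generate

def stage_generate(cfg: dict, outdir: Path) -> None:
    """Synthesize the course, cohort profiles, sway trials and walking trials."""
    gen = cfg["generator"]
    outdir = Path(outdir)
    ds = outdir / "dataset"
    ds.mkdir(parents=True, exist_ok=True)
    course, course_truth = make_course(
        total_length=gen["course_length"],
        max_slope=gen["course_max_slope"],
        section_length=gen["course_section_length"],
        blend_length=gen["course_blend_length"],
        seed=_substream(cfg["seed"], "course"))
    tio.save_course_map(ds / "course_map.csv", course)
    pattern = default_gait_pattern()
    profiles = make_cohort_profiles(gen["n_participants"],
                                    seed=_substream(cfg["seed"], "cohort"))
    rng = np.random.default_rng(_substream(cfg["seed"], "trials"))
    truth_all = {"course_sections": course_truth["section_inclines"].tolist(),
                 "participants": {}}
    for prof in profiles:
        pdir = ds / prof.id
        pdir.mkdir(exist_ok=True)
        # walk the course (with laps if it is shorter than the trial)
        n_strides = gen["strides_per_participant"]
        pos, slopes = 0.0, []
        for _ in range(n_strides):
            lookup = (pos + prof.level_stride_length / 2.0) % course.length
            s = float(np.clip(course.incline_at(lookup), -10.0, 10.0))
            slopes.append(s)
            length, _t = pattern.stride_geometry(s, prof)
            pos += length
        sync_delay = float(rng.uniform(*gen["sync_delay_range"]))
        spec = TrialSpec(n_strides=n_strides, slope_sequence=np.array(slopes),
                         sync_delay=sync_delay,
                         noise_scale=gen["noise_scale"],
                         seed=_substream(cfg["seed"], f"trial-{prof.id}"))
        trial = make_trial(prof, pattern, spec)
        tio.save_kinematics(pdir / "kinematics.csv", trial.kinematics)
        tio.save_wave_speed(pdir / "wave_speed_raw.csv", trial.wave_speed_stream)
        if gen["mode"] == "full":
            rec = render_tap_recording(
                trial.wave_speed_stream,
                seed=_substream(cfg["seed"], f"taps-{prof.id}"))
            tio.save_recordings(pdir / "taps.h5", {"walk": rec})
        for tag in ("pre", "post"):
            sway = make_sway_trial(
                prof, duration=gen["sway_duration"],
                noise_scale=gen["sway_noise_scale"],
                seed=_substream(cfg["seed"], f"sway-{tag}-{prof.id}"))
            pd.DataFrame({
                "time_s": np.arange(sway.Fz.size) / sway.fs,
                "fz_n": sway.Fz, "cop_ap_m": sway.COP_ap,
                "accel": sway.accel_stream,
                "wave_speed_mps": sway.wave_speed.speeds,
            }).to_csv(pdir / f"sway_{tag}.csv", index=False)
        truth_all["participants"][prof.id] = {
            "mass": prof.mass, "calib_slope": prof.calib_slope,
            "calib_intercept": prof.calib_intercept,
            "ankle_axis_ap": 0.08,
            "sway_fs": 1000.0,
            "sync_delay": sync_delay,
            "heel_strikes": trial.truth["heel_strikes"].tolist(),
            "slopes": list(map(float, slopes)),
            "stride_lengths": trial.truth["stride_lengths"].tolist(),
        }
    tio.save_json(ds / "truth.json", truth_all)


# ---------------------------------------------------------------------------
# stage: calibrate

def stage_calibrate(cfg: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    ds = outdir / "dataset"
    cal_dir = outdir / "calibration"
    cal_dir.mkdir(parents=True, exist_ok=True)
    truth = json.loads((ds / "truth.json").read_text())["participants"]
    for pid in _participant_ids(cfg):
        try:
            models = {}
            for tag in ("pre", "post"):
                df = pd.read_csv(ds / pid / f"sway_{tag}.csv")
                fs = truth[pid]["sway_fs"]
                plate = BalancePlateRecording(
                    Fz=df["fz_n"].to_numpy(), COP_ap=df["cop_ap_m"].to_numpy(),
                    ankle_axis_ap=truth[pid]["ankle_axis_ap"], fs=fs)
                offset = align_plate_to_accel(plate.Fz, df["accel"].to_numpy(),
                                              fs=fs)
                t = df["time_s"].to_numpy()
                ts, ss = apply_offset(t, df["wave_speed_mps"].to_numpy(),
                                      -offset)
                s_on_plate = np.interp(t, ts, ss)
                moment = ankle_moment_from_plate(plate)
                keep = np.abs(t - t[np.argmax(plate.Fz)]) > 0.1  # drop strike
                models[tag] = fit_calibration(s_on_plate[keep], moment[keep],
                                              participant_id=pid)
            drift = compare_calibrations(
                models["pre"], models["post"],
                drift_threshold=cfg["processing"]["drift_threshold"])
            record = json.loads(models["pre"].to_json())
            record["post"] = json.loads(models["post"].to_json())
            record["drift_check"] = drift
            (cal_dir / f"{pid}.json").write_text(json.dumps(record, indent=2))
        except Exception as e:  # noqa: BLE001
            raise StageError("calibrate", pid, e) from e


# ---------------------------------------------------------------------------
# stage: process

def _load_wave_speed_for(cfg, pdir: Path):
    """Fast mode reads the direct series; full mode processes the raw taps."""
    if cfg["generator"]["mode"] == "full" and (pdir / "taps.h5").exists():
        proc = cfg["processing"]
        rec = tio.load_recordings(pdir / "taps.h5")["walk"]
        rec = bandpass_filter(rec, proc["bandpass_low"], proc["bandpass_high"])
        return wave_speed_series(rec, quality_floor=proc["quality_floor"],
                                 speed_bounds=tuple(proc["speed_bounds"]),
                                 trial_id=pdir.name)
    return tio.load_wave_speed(pdir / "wave_speed_raw.csv")


def stage_process(cfg: dict, outdir: Path) -> None:
    """Heel strikes, strides, slopes, sync correction, per-stride mechanics."""
    outdir = Path(outdir)
    ds = outdir / "dataset"
    proc = cfg["processing"]
    stats = cfg["stats"]
    course = tio.load_course_map(ds / "course_map.csv")
    mech_dir = outdir / "processed" / "mechanics"
    mech_dir.mkdir(parents=True, exist_ok=True)
    all_strides, curve_rows, sync_log = [], [], {}
    for pid in _participant_ids(cfg):
        pdir = ds / pid
        try:
            kin = tio.load_kinematics(pdir / "kinematics.csv")
            ws = _load_wave_speed_for(cfg, pdir)
            cal_path = outdir / "calibration" / f"{pid}.json"
            if cal_path.exists():
                rec = json.loads(cal_path.read_text())
                cal = CalibrationModel(c1=rec["c1"], c0=rec["c0"],
                                       r_squared=rec["r_squared"],
                                       participant_id=rec["participant_id"])
            else:
                cal = CalibrationModel()
            mass = json.loads((ds / "truth.json").read_text())[
                "participants"][pid]["mass"]
            hs = detect_heel_strikes(
                kin.foot_accel, kin.fs, band=tuple(proc["heel_strike_band"]),
                min_stride=proc["min_stride_time"],
                prominence_mads=proc["heel_strike_prominence_mads"])
            strides = stride_metrics(kin.times, kin.pelvis_x, hs,
                                     max_length=proc["max_stride_length"],
                                     participant_id=pid)
            for s in strides:
                mid = float(np.interp((s.start + s.end) / 2.0, kin.times,
                                      kin.pelvis_x)) % course.length
                assign_and_bin_slope(s, mid, course,
                                     bin_width=stats["bin_width"])
            level = [(s.start, s.end) for s in strides
                     if s.included and np.isfinite(s.slope)
                     and abs(s.slope) <= proc["level_slope_max"]]
            est = estimate_sync_offset(
                kin.times, kin.ankle_deg, ws.times, ws.speeds, level,
                window_fraction=proc["sync_window_fraction"],
                max_lag=proc["sync_max_lag"],
                min_strides=proc["sync_min_strides"])
            ws_t, ws_s = apply_offset(ws.times, ws.speeds, est.mean_offset)
            sync_log[pid] = {"mean_offset_s": est.mean_offset,
                             "n_strides_used": est.n_strides_used}
            for k, s in enumerate(strides):
                if not s.included:
                    all_strides.append((s, None))
                    continue
                m = (kin.times >= s.start) & (kin.times <= s.end)
                if ws_t.size == 0 or s.start < ws_t[0] or s.end > ws_t[-1]:
                    s.exclude("no_wavespeed_coverage")
                    all_strides.append((s, None))
                    continue
                speeds = np.interp(kin.times[m], ws_t, ws_s)
                mech = stride_mechanics(kin.times[m], kin.ankle_deg[m],
                                        kin.knee_deg[m], speeds, mass,
                                        calibration=cal, fs=kin.fs)
                summ = mech.work_summary(s.stride_length, s.slope)
                all_strides.append((s, summ))
                pd.DataFrame({
                    "time_s": mech.times, "VS_mps": mech.VS, "VG_mps": mech.VG,
                    "excS_m": mech.excursion_S, "excG_m": mech.excursion_G,
                    "FS_Nkg": mech.FS, "FG_Nkg": mech.FG,
                    "PS_Wkg": mech.PS, "PG_Wkg": mech.PG,
                }).to_csv(mech_dir / f"{pid}_stride{k:03d}.csv", index=False)
                curve_rows.append({
                    "participant_id": pid, "stride_index": k,
                    "slope_deg": s.slope, "slope_bin_deg": s.slope_bin,
                    "curve": resample_to_gait_cycle(
                        kin.times[m], speeds, stats["gait_grid_points"]),
                })
        except Exception as e:  # noqa: BLE001
            raise StageError("process", pid, e) from e

    table = strides_to_frame([s for s, _ in all_strides])
    summaries = [w for _, w in all_strides]
    for col in ("WS_net", "WS_pos", "WS_neg", "WG_net", "WG_pos", "WG_neg",
                "W_gravity"):
        table[col] = [getattr(w, col) if w is not None else np.nan
                      for w in summaries]
    table.to_csv(outdir / "processed" / "stride_table.csv", index=False)
    curves = pd.DataFrame(curve_rows)
    if len(curves):
        flat = pd.DataFrame(np.vstack(curves.pop("curve").to_numpy()))
        flat.columns = [f"c{j:03d}" for j in range(flat.shape[1])]
        curves = pd.concat([curves.reset_index(drop=True), flat], axis=1)
    curves.to_csv(outdir / "processed" / "curves.csv", index=False)
    tio.save_json(outdir / "processed" / "sync.json", sync_log)


# ---------------------------------------------------------------------------
# stage: analyze

def stage_analyze(cfg: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    stats = cfg["stats"]
    proc = cfg["processing"]
    adir = outdir / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(outdir / "processed" / "stride_table.csv")
    curves = pd.read_csv(outdir / "processed" / "curves.csv")
    ccols = [c for c in curves.columns if c.startswith("c")
             and c[1:].isdigit()]
    curves_long = curves[["participant_id", "slope_deg",
                          "slope_bin_deg"]].copy()
    curves_long["curve"] = list(curves[ccols].to_numpy())
    normalized = normalize_wave_speed_curves(curves_long,
                                             level_max=proc["level_slope_max"])
    bin_means = bin_average_curves(normalized,
                                   n_points=stats["gait_grid_points"])
    bin_means.to_csv(adir / "bin_curves.csv", index=False)

    inc = table[table["included"] == True].copy()  # noqa: E712
    level_mask = np.abs(inc["slope_deg"].to_numpy()) <= proc["level_slope_max"]
    results = []
    for muscle, col in (("soleus", "WS_net"), ("gastrocnemius", "WG_net")):
        dw = zero_reference_work(inc[col].to_numpy(),
                                 inc["participant_id"].to_numpy(), level_mask)
        decline, incline = fit_slope_sensitivity(
            dw, inc["slope_deg"].to_numpy(), muscle,
            min_strides=stats["min_strides_per_segment"],
            include_level_in_both=stats["include_level_in_both"])
        results += [decline.to_dict(), incline.to_dict()]
    tio.save_json(adir / "regressions.json", results)


# ---------------------------------------------------------------------------
# stage: report

def stage_report(cfg: dict, outdir: Path) -> RunReport:
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "processed" / "stride_table.csv")
    table["exclusion_reason"] = table["exclusion_reason"].fillna("")
    table["included"] = table["included"].astype(bool)
    report = RunReport()
    report.strides_total = int(len(table))
    report.strides_included = int((table["included"] == True).sum())  # noqa: E712
    excluded = table[table["included"] == False]  # noqa: E712
    report.exclusions = {k: int(v) for k, v in
                         excluded["exclusion_reason"].value_counts().items()}
    report.sync_offsets = json.loads(
        (outdir / "processed" / "sync.json").read_text())
    for p in (outdir / "calibration").glob("*.json"):
        rec = json.loads(p.read_text())
        report.calibrations[p.stem] = {
            "c1": rec["c1"], "c0": rec["c0"], "r_squared": rec["r_squared"],
            "drift": rec.get("drift_check", {}).get("drift")}
    inc = table[table["included"] == True]  # noqa: E712
    counts = inc["slope_bin_deg"].value_counts().sort_index()
    report.per_bin_counts = {str(int(float(k))): int(v)
                             for k, v in counts.items() if k != ""}
    reg_path = outdir / "analysis" / "regressions.json"
    if reg_path.exists():
        report.regressions = json.loads(reg_path.read_text())
    report.validate()
    tio.save_json(outdir / "report.json", report.to_dict())
    return report


# ---------------------------------------------------------------------------

STAGES = ("generate", "calibrate", "process", "analyze", "report")


def run_pipeline(cfg: dict, outdir=None) -> RunReport:
    """Run every stage in order; deterministic given the config seed."""
    outdir = Path(outdir if outdir is not None else cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        __import__("yaml").safe_dump(cfg, sort_keys=False))
    stage_generate(cfg, outdir)
    stage_calibrate(cfg, outdir)
    stage_process(cfg, outdir)
    stage_analyze(cfg, outdir)
    return stage_report(cfg, outdir)
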