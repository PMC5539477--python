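"""Per-minute sample assembly and delimited-text dataset IO.

The analysis consumes one labelled record per minute: four movement
features, 31 HRV features, anthropometrics and (for energy-expenditure
work) the reference EE in kcal/min.  This module turns raw cohort signals
into that table via the detection/windowing/feature stages, and reads and
writes the on-disk text layout:

* ``<subject>_<session>_<activity>_ecg.csv`` — columns ``time_s,value``
* ``<subject>_<session>_<activity>_accel.csv`` — ``time_s,ax,ay,az`` (g)
* ``labels.csv`` — ``subject_id,minute_index,activity,ee_kcal_min``
* ``manifest.json`` — subjects, files, anthropometrics, seed, config
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activities import Activity, RECOGNITION_ACTIVITIES, as_activity
from .ecg import ECGSignal, build_rr, detect_r_peaks, window_rr
from .generate import RawCohort
from .hrv import HRV_NAMES, HRVParams, compute_all
from .imu import IMU_NAMES, AccelSignal, minute_features

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "extract_minute_table",
    "write_cohort",
    "load_minute_table",
    "save_minute_table",
    "read_ecg_csv",
    "read_accel_csv",
    "validate_dataset",
    "recognition_view",
]

META_COLUMNS = ("subject_id", "minute_index", "activity")
FEATURE_COLUMNS = ("height", "weight", *IMU_NAMES, *HRV_NAMES)


def extract_minute_table(
    cohort: RawCohort,
    hrv_params: HRVParams | None = None,
    use_true_peaks: bool = False,
) -> pd.DataFrame:
    """Run detection, windowing and both feature stages over a raw cohort.

    ``use_true_peaks`` bypasses the R-peak detector with the generator's
    stored truth (useful to isolate downstream stages).
    """
    hrv_params = hrv_params or HRVParams()
    rows: list[dict] = []
    for subj in cohort.subjects:
        prof = subj.profile
        minute0 = 0
        for ses in subj.sessions:
            peaks = (ses.true_peak_times if use_true_peaks
                     else detect_r_peaks(ses.ecg))
            rr = build_rr(peaks)
            wins = window_rr(rr, 60.0, t0=0.0, span_s=60.0 * ses.minutes)
            imu_min = minute_features(ses.accel)
            ee = ses.minute_truth.set_index("minute_index")["ee_kcal_min"]
            for k in range(ses.minutes):
                row: dict = {
                    "subject_id": prof.subject_id,
                    "minute_index": minute0 + k,
                    "activity": ses.activity.value,
                    "height": prof.height_cm,
                    "weight": prof.weight_kg,
                    "ee_kcal_min": float(ee.get(k, np.nan)),
                }
                if k < len(imu_min) and imu_min[k] is not None:
                    for name, val in zip(IMU_NAMES, imu_min[k].to_array()):
                        row[name] = float(val)
                else:
                    row.update({name: np.nan for name in IMU_NAMES})
                if k < len(wins) and len(wins[k]) > 0:
                    feats = compute_all(wins[k], hrv_params)
                    row.update(feats.values)
                else:
                    row.update({name: np.nan for name in HRV_NAMES})
                rows.append(row)
            minute0 += ses.minutes
    cols = list(META_COLUMNS) + list(FEATURE_COLUMNS) + ["ee_kcal_min"]
    return pd.DataFrame(rows)[cols]


def recognition_view(table: pd.DataFrame) -> pd.DataFrame:
    """Drop REST minutes: recognition is a five-class problem."""
    keep = {a.value for a in RECOGNITION_ACTIVITIES}
    return table[table["activity"].isin(keep)].reset_index(drop=True)


# ------------------------------------------------------------------------ IO

def write_cohort(cohort: RawCohort, outdir: "str | Path") -> Path:
    """Write raw signals, labels and manifest as delimited text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    label_frames = []
    for subj, sub_manifest in zip(cohort.subjects, manifest["subjects"]):
        sid = subj.profile.subject_id
        files = []
        for si, ses in enumerate(subj.sessions):
            stem = f"{sid}_{si:02d}_{ses.activity.value}"
            ecg_path = outdir / f"{stem}_ecg.csv"
            t = ses.ecg.times
            pd.DataFrame({"time_s": t, "value": ses.ecg.samples}).to_csv(
                ecg_path, index=False, float_format="%.5f"
            )
            acc_path = outdir / f"{stem}_accel.csv"
            ta = ses.accel.start_time + np.arange(ses.accel.samples.shape[0]) / ses.accel.fs
            pd.DataFrame({
                "time_s": ta,
                "ax": ses.accel.samples[:, 0],
                "ay": ses.accel.samples[:, 1],
                "az": ses.accel.samples[:, 2],
            }).to_csv(acc_path, index=False, float_format="%.5f")
            files.append({"activity": ses.activity.value,
                          "ecg": ecg_path.name, "accel": acc_path.name,
                          "minutes": ses.minutes,
                          "ecg_fs": ses.ecg.fs, "accel_fs": ses.accel.fs})
        sub_manifest["files"] = files
        lab = subj.labels()
        ee = pd.concat(
            [s.minute_truth["ee_kcal_min"] for s in subj.sessions],
            ignore_index=True,
        )
        lab["ee_kcal_min"] = ee
        label_frames.append(lab)
    pd.concat(label_frames, ignore_index=True).to_csv(
        outdir / "labels.csv", index=False, float_format="%.6f"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_ecg_csv(path: "str | Path", fs: float | None = None) -> ECGSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return ECGSignal(samples=df["value"].to_numpy(), fs=fs,
                     start_time=float(t[0]))


def read_accel_csv(path: "str | Path", fs: float | None = None) -> AccelSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return AccelSignal(samples=df[["ax", "ay", "az"]].to_numpy(), fs=fs,
                       start_time=float(t[0]))


def save_minute_table(table: pd.DataFrame, path: "str | Path") -> None:
    table.to_csv(path, index=False, float_format="%.8g")


def load_minute_table(path: "str | Path") -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"minute table missing required columns {missing}")
    return table


# ---------------------------------------------------------------- validation

def validate_dataset(cohort_dir: "str | Path") -> dict:
    """Schema and sanity checks on an on-disk cohort.

    Returns ``{"errors": [...], "warnings": [...], "summary": {...}}``;
    hard schema violations go to ``errors``, oddities to ``warnings``.
    """
    cohort_dir = Path(cohort_dir)
    errors: list[str] = []
    warnings_: list[str] = []
    summary: dict = {}
    man_path = cohort_dir / "manifest.json"
    if not man_path.exists():
        return {"errors": [f"manifest.json not found in {cohort_dir}"],
                "warnings": [], "summary": {}}
    manifest = json.loads(man_path.read_text())
    vocab = {a.value for a in Activity}

    lab_path = cohort_dir / "labels.csv"
    if not lab_path.exists():
        errors.append("labels.csv not found")
    else:
        lab = pd.read_csv(lab_path)
        need = {"subject_id", "minute_index", "activity", "ee_kcal_min"}
        missing = need - set(lab.columns)
        if missing:
            errors.append(f"labels.csv missing columns {sorted(missing)}")
        else:
            bad = sorted(set(lab["activity"]) - vocab)
            if bad:
                errors.append(f"labels.csv contains unknown activities {bad}")
            summary["minutes_per_subject"] = (
                lab.groupby("subject_id").size().to_dict()
            )
            summary["minutes_per_activity"] = (
                lab.groupby("activity").size().to_dict()
            )

    for sub in manifest.get("subjects", []):
        if sub.get("height_cm", 0) <= 0 or sub.get("weight_kg", 0) <= 0:
            errors.append(f"{sub.get('subject_id')}: non-positive anthropometrics")
        for f in sub.get("files", []):
            for key in ("ecg", "accel"):
                p = cohort_dir / f[key]
                if not p.exists():
                    errors.append(f"missing file {f[key]}")
                    continue
                df = pd.read_csv(p)
                if "time_s" not in df.columns:
                    errors.append(f"{f[key]}: no time_s column")
                    continue
                dt = np.diff(df["time_s"].to_numpy())
                if np.any(dt <= 0):
                    idx = int(np.argmax(dt <= 0)) + 1
                    errors.append(
                        f"{f[key]}: non-monotone timestamps at row {idx}"
                    )
    summary["n_subjects"] = len(manifest.get("subjects", []))
    return {"errors": errors, "warnings": warnings_, "summary": summary}
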