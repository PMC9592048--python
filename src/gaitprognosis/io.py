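"""Plain-CSV persistence for cohorts and sensor recordings.

One CSV per recording (columns ``t_s, ax_g, ay_g, az_g, gx_dps, gy_dps,
gz_dps``, filename ``<patient>_<assessment>_<placement>.csv``) plus a
``cohort.csv`` with one row per patient.  Real device exports that match this
schema can be ingested the same way.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import SensorRecording, PLACEMENTS

RECORDING_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")


def write_recording_csv(recording: SensorRecording, path: str | Path) -> None:
    t = np.arange(recording.n_samples) / recording.fs_hz
    frame = pd.DataFrame(
        np.column_stack([t, recording.acc, recording.gyro]), columns=list(RECORDING_COLUMNS)
    )
    # %.17g round-trips float64 exactly through text
    frame.to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(path: str | Path, placement: str) -> SensorRecording:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(RECORDING_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = frame["t_s"].to_numpy(dtype=float)
    if len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 31.25
    return SensorRecording(
        placement=placement,
        fs_hz=fs,
        acc=frame[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        gyro=frame[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float),
    )


def write_cohort_dir(cohort: pd.DataFrame, recordings: dict, out_dir: str | Path) -> None:
    """Write ``cohort.csv`` and one CSV per recording into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", float_format="%.17g")
    for pid, assessments in recordings.items():
        for assessment, placements in assessments.items():
            for placement, rec in placements.items():
                write_recording_csv(rec, out / f"{pid}_{assessment}_{placement}.csv")


def read_cohort_dir(in_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a directory produced by :func:`write_cohort_dir` (or real exports
    in the same layout)."""
    src = Path(in_dir)
    cohort_path = src / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"no cohort.csv in {src}")
    cohort = pd.read_csv(cohort_path, index_col="patient_id", float_precision="round_trip")
    recordings: dict = {}
    for path in sorted(src.glob("*_*_*.csv")):
        pid, assessment, placement = path.stem.split("_", 2)
        if placement not in PLACEMENTS:
            continue
        recordings.setdefault(pid, {}).setdefault(assessment, {})[placement] = read_recording_csv(
            path, placement
        )
    return cohort, recordings
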