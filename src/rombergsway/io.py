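"""CSV input/output for trials, cohorts and parameter tables.

Per-trial files carry ``t_s, ax, ay, az`` columns (seconds and m/s^2); a
cohort manifest maps each file to its subject, group, test, eye condition
and sensor site.  Floats are written with enough digits to round-trip
exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .records import TrialRecording
from .simulate import Cohort

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_cohort",
    "read_cohort",
    "write_parameter_table",
    "read_parameter_table",
]

_FLOAT_FMT = "%.17g"
_TRIAL_COLUMNS = ["t_s", "ax", "ay", "az"]
MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "test",
    "eye_condition",
    "sensor_site",
    "path",
    "fs_hz",
    "truncated",
]


def write_trial_csv(recording: TrialRecording, path) -> None:
    frame = pd.DataFrame(
        {
            "t_s": recording.t,
            "ax": recording.samples[:, 0],
            "ay": recording.samples[:, 1],
            "az": recording.samples[:, 2],
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_csv(
    path,
    *,
    subject_id: str,
    group: str,
    test: str,
    eye_condition: str,
    sensor_site: str,
    fs: float | None = None,
    truncated: bool = False,
) -> TrialRecording:
    """Read one trial CSV, verifying schema and uniform sampling.

    ``fs`` normally comes from the cohort manifest; if omitted it is
    inferred from the median timestamp spacing.  Non-numeric cells and
    non-uniform timestamps are rejected with the offending data row number
    (1-based, excluding the header).
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(raw) == 0:
        raise ValueError(f"{path}: empty data section")
    numeric = raw[_TRIAL_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: non-numeric cell at data row {row}")

    t = numeric["t_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if fs is None:
            fs = 1.0 / float(np.median(dt))
        dev = np.abs(dt - 1.0 / fs)
        worst = int(np.argmax(dev))
        if dev[worst] >= 1e-6:
            raise ValueError(
                f"{path}: non-uniform sampling at data row {worst + 2} "
                f"(|dt - 1/fs| = {dev[worst]:.3g} s)"
            )
    elif fs is None:
        raise ValueError(f"{path}: cannot infer fs from a single sample")

    return TrialRecording(
        subject_id=subject_id,
        group=group,
        test=test,
        eye_condition=eye_condition,
        sensor_site=sensor_site,
        fs=float(fs),
        samples=numeric[["ax", "ay", "az"]].to_numpy(),
        truncated=truncated,
    )


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a cohort directory: trial CSVs, manifest, subject table, config.

    Returns the manifest path.  Layout::

        outdir/
          config.yaml
          manifest.csv
          subjects.csv
          trials/<subject>_<test>_<eye>_<site>.csv
    """
    outdir = Path(outdir)
    trials_dir = outdir / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        rel = os.path.join(
            "trials",
            f"{rec.subject_id}_{rec.test}_{rec.eye_condition}_{rec.sensor_site}.csv",
        )
        write_trial_csv(rec, outdir / rel)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "test": rec.test,
                "eye_condition": rec.eye_condition,
                "sensor_site": rec.sensor_site,
                "path": rel,
                "fs_hz": rec.fs,
                "truncated": rec.truncated,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    cohort.config.to_yaml(outdir / "config.yaml")
    return manifest_path


def read_cohort(manifest_path) -> list[TrialRecording]:
    """Load every trial listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {missing}")
    base = manifest_path.parent
    recordings = []
    for row in manifest.itertuples(index=False):
        recordings.append(
            read_trial_csv(
                base / row.path,
                subject_id=row.subject_id,
                group=row.group,
                test=row.test,
                eye_condition=row.eye_condition,
                sensor_site=row.sensor_site,
                fs=float(row.fs_hz),
                truncated=bool(row.truncated),
            )
        )
    return recordings


_PARAM_KEYS = [
    "subject_id",
    "group",
    "test",
    "eye_condition",
    "body_part",
    "axis",
    "metric",
]


def write_parameter_table(table: pd.DataFrame, path) -> None:
    """Long-format parameter CSV with a deterministic (sorted) row order."""
    missing = [c for c in _PARAM_KEYS + ["value"] if c not in table.columns]
    if missing:
        raise ValueError(f"parameter table missing columns {missing}")
    out = table.sort_values(_PARAM_KEYS, ignore_index=True) if len(table) else table
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_parameter_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PARAM_KEYS + ["value"] if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: parameter table missing columns {missing}")
    return table
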