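"""The four kinematic sway parameters and the per-subject parameter table.

All four summaries operate on a baseline-removed (zero-mean) anatomical-axis
acceleration series:

* maximum ACC — max |a(t)|, m/s^2 (sway is bidirectional, so the absolute
  maximum is used);
* mean ACC — mean |a(t)| (rectified mean), m/s^2: the plain mean is ~0 by
  construction after baseline removal, so the informative reading is the
  mean magnitude;
* RMS of ACC — sqrt(mean a(t)^2), m/s^2, equal to the population SD of the
  zero-mean signal;
* MV (mean sway velocity) — mean |v(t)| in m/s, where v is the cumulative
  trapezoidal integral of a(t) with v(0) = 0.

Per subject and condition the table holds 4 metrics x 3 axes x 3 body
parts = 36 parameters; the two ankle sensors are summarised at the metric
level (the two ankles' metric values are averaged).
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .config import AXES, METRICS
from .records import AnatomicalSignal

logger = logging.getLogger(__name__)

__all__ = [
    "max_acc",
    "mean_acc",
    "rms_acc",
    "mean_sway_velocity",
    "METRIC_FUNCTIONS",
    "extract_parameters",
]


def _validate(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return x


def max_acc(axis_series) -> float:
    """Maximum absolute acceleration, m/s^2."""
    return float(np.max(np.abs(_validate(axis_series))))


def mean_acc(axis_series) -> float:
    """Rectified mean acceleration (mean of |a|), m/s^2."""
    return float(np.mean(np.abs(_validate(axis_series))))


def rms_acc(axis_series) -> float:
    """Root-mean-square acceleration, m/s^2."""
    x = _validate(axis_series)
    return float(np.sqrt(np.mean(x * x)))


def mean_sway_velocity(axis_series, fs: float) -> float:
    """Mean absolute sway velocity from integrated acceleration, m/s."""
    x = _validate(axis_series)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if x.size == 1:
        return 0.0  # v(0) = 0
    v = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    return float(np.mean(np.abs(v)))


METRIC_FUNCTIONS: dict[str, Callable] = {
    "max_acc": lambda s, fs: max_acc(s),
    "mean_acc": lambda s, fs: mean_acc(s),
    "rms_acc": lambda s, fs: rms_acc(s),
    "mv": mean_sway_velocity,
}

_PARAM_COLUMNS = [
    "subject_id",
    "group",
    "test",
    "eye_condition",
    "body_part",
    "axis",
    "metric",
    "value",
]


def _metrics_for_signal(signal: AnatomicalSignal) -> dict[tuple[str, str], float]:
    out = {}
    for j, axis in enumerate(AXES):
        series = signal.samples[:, j]
        for metric in METRICS:
            out[(axis, metric)] = METRIC_FUNCTIONS[metric](series, signal.fs)
    return out


def extract_parameters(signals: Iterable[AnatomicalSignal]) -> pd.DataFrame:
    """Kinematic parameter table from preprocessed anatomical signals.

    For every (subject, test, eye condition) with all four sensors present,
    emits 36 rows: 4 metrics x 3 axes for head, pelvis and the averaged
    ankles.  Conditions missing a sensor are skipped with a warning;
    truncated trials are summarised over their actual length.
    """
    by_condition: dict[tuple[str, str, str], dict[str, AnatomicalSignal]] = {}
    groups: dict[str, str] = {}
    for sig in signals:
        key = (sig.subject_id, sig.test, sig.eye_condition)
        by_condition.setdefault(key, {})[sig.sensor_site] = sig
        groups[sig.subject_id] = sig.group

    rows = []
    for (subject_id, test, eye), sensors in sorted(by_condition.items()):
        missing = {"head", "pelvis", "ankle_left", "ankle_right"} - set(sensors)
        if missing:
            logger.warning(
                "subject %s %s/%s: missing sensors %s; condition skipped",
                subject_id,
                test,
                eye,
                sorted(missing),
            )
            continue
        per_part = {
            "head": _metrics_for_signal(sensors["head"]),
            "pelvis": _metrics_for_signal(sensors["pelvis"]),
        }
        left = _metrics_for_signal(sensors["ankle_left"])
        right = _metrics_for_signal(sensors["ankle_right"])
        per_part["ankles"] = {k: 0.5 * (left[k] + right[k]) for k in left}
        group = groups[subject_id]
        for body_part, values in per_part.items():
            for (axis, metric), value in values.items():
                rows.append(
                    (subject_id, group, test, eye, body_part, axis, metric, value)
                )
    table = pd.DataFrame(rows, columns=_PARAM_COLUMNS)
    if len(table):
        table = table.sort_values(_PARAM_COLUMNS[:-1], ignore_index=True)
    return table
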