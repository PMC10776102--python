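"""Smoothing, baseline calibration and the gravity-aligned anatomical frame.

Preprocessing follows the instrumented-test protocol: a centred 5-point
moving average suppresses muscle-vibration noise; the mean acceleration
vector over the whole trial estimates the gravity direction, which defines
the cranio-caudal (CC) axis of a verticalized reference frame; the
shortest-arc rotation restoring the vertical carries the sensor's nominal
forward axis onto antero-posterior (AP), and ML = CC x AP completes a
right-handed frame.
Samples are rotated into (AP, ML, CC) and the whole-trial mean is then
subtracted per anatomical axis, removing both the projected gravity
constant and any residual static offset in one step.
"""

from __future__ import annotations

import logging

import numpy as np

from .records import AnatomicalSignal, TrialRecording

logger = logging.getLogger(__name__)

__all__ = [
    "moving_average",
    "remove_baseline",
    "estimate_gravity",
    "to_anatomical_frame",
    "preprocess_recording",
    "DEFAULT_PLACEMENT",
]

#: nominal forward (antero-posterior) axis of each sensor, in its own frame
DEFAULT_PLACEMENT: dict[str, tuple[float, float, float]] = {
    "head": (1.0, 0.0, 0.0),
    "pelvis": (1.0, 0.0, 0.0),
    "ankle_left": (1.0, 0.0, 0.0),
    "ankle_right": (1.0, 0.0, 0.0),
}

#: plausible window for the mean acceleration norm of a correctly scaled
#: trial; outside it the recording is flagged unit-suspect
GRAVITY_NORM_WINDOW = (7.0, 13.0)


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc rotation matrix taking unit vector ``a`` onto ``b``."""
    c = float(a @ b)
    if c < -1.0 + 1e-12:
        raise ValueError(
            "gravity direction is antiparallel to the nominal vertical "
            "(sensor mounted upside down?); the verticalizing rotation is undefined"
        )
    v = np.cross(a, b)
    K = np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )
    return np.eye(3) + K + (K @ K) / (1.0 + c)


def anatomical_basis(cc: np.ndarray, forward) -> tuple[np.ndarray, np.ndarray]:
    """AP and ML unit vectors completing the verticalized frame.

    The nominal vertical is carried onto the measured gravity direction
    ``cc`` by the shortest-arc rotation; the sensor's nominal ``forward``
    axis rotated the same way (and re-orthogonalised against CC) gives AP,
    and ML = CC x AP completes a right-handed (AP, ML, CC) triad.  For a
    mounting tilt about any horizontal axis the shortest-arc rotation
    recovers the tilt exactly, so the anatomical azimuth is stable across
    tilt angles.  A forward axis parallel to gravity leaves the azimuth
    undefined and is rejected.
    """
    fwd = np.asarray(forward, dtype=float)
    fwd = fwd / np.linalg.norm(fwd)
    if abs(float(fwd @ cc)) > 1.0 - 1e-8:
        raise ValueError(
            "nominal forward axis is parallel to gravity; the anatomical "
            "azimuth is undefined — check the placement convention"
        )
    ap = _minimal_rotation(np.array([0.0, 0.0, 1.0]), cc) @ fwd
    ap = ap - (ap @ cc) * cc  # exact orthogonality for non-horizontal forward axes
    ap = ap / np.linalg.norm(ap)
    ml = np.cross(cc, ap)  # right-handed: AP x ML = CC
    return ap, ml


def moving_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with symmetric edge shrinkage.

    ``output[i]`` is the arithmetic mean of the input over a window of
    ``window`` points centred on i; near the edges the half-width shrinks
    symmetrically (index 0 keeps its own value, index 1 averages 3 points,
    and so on).  Output length equals input length; an even window is
    rejected because centring would be ambiguous.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    n = x.size
    if n < 1:
        raise ValueError("series must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    k = window // 2
    if k == 0 or n == 1:
        return x.copy()
    out = np.empty(n)
    if n >= window:
        csum = np.concatenate(([0.0], np.cumsum(x)))
        out[k : n - k] = (csum[window:] - csum[: n - window + 1]) / window
    for i in range(min(k, n)):
        h = min(i, n - 1 - i, k)
        out[i] = x[i - h : i + h + 1].mean()
    for i in range(max(n - k, 0), n):
        h = min(i, n - 1 - i, k)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def remove_baseline(series: np.ndarray) -> np.ndarray:
    """Subtract the whole-trial mean (static baseline-offset calibration)."""
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("series must be non-empty")
    # iterate so the residual mean falls below numerical resolution: a
    # second application is then a no-op (idempotence holds in floating
    # point, not just in exact arithmetic)
    out = x.copy()
    eps = np.finfo(float).eps
    for _ in range(8):
        m = out.mean()
        if abs(m) <= 4.0 * eps * float(np.max(np.abs(out), initial=0.0)):
            break
        out = out - m
    return out


def estimate_gravity(filtered_samples: np.ndarray) -> np.ndarray:
    """Unit gravity-reaction direction from the mean of a filtered trial.

    The input must still contain the gravity component (i.e. be the
    smoothed signal *before* baseline removal); a mean-vector norm at or
    below 1 m/s^2 indicates the offset was already removed and is rejected.
    """
    samples = np.asarray(filtered_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError(f"samples must be (n, 3), got shape {samples.shape}")
    mean_vec = samples.mean(axis=0)
    norm = float(np.linalg.norm(mean_vec))
    if norm <= 1.0:
        raise ValueError(
            f"mean acceleration norm {norm:.3g} m/s^2 carries no gravity "
            "information; was the baseline removed before frame estimation?"
        )
    return mean_vec / norm


def to_anatomical_frame(
    recording: TrialRecording,
    placement_convention: dict | None = None,
) -> AnatomicalSignal:
    """Rotate a smoothed recording into the verticalized (AP, ML, CC) frame.

    The recording's samples are assumed already smoothed (``moving_average``
    per channel).  CC is the estimated gravity-reaction direction (pointing
    cranially), AP the sensor's nominal forward axis carried by the
    verticalizing rotation (see ``anatomical_basis``), ML = CC x AP.  After
    rotation the whole-trial mean is
    subtracted per anatomical axis.  The rotation preserves per-sample
    vector norms.
    """
    placement = dict(DEFAULT_PLACEMENT)
    if placement_convention:
        placement.update(placement_convention)

    samples = recording.samples
    mean_vec = samples.mean(axis=0)
    mean_norm = float(np.linalg.norm(mean_vec))
    cc = estimate_gravity(samples)

    lo, hi = GRAVITY_NORM_WINDOW
    unit_suspect = not (lo <= mean_norm <= hi)
    if unit_suspect:
        logger.warning(
            "trial %s/%s/%s/%s: mean acceleration norm %.3g m/s^2 outside "
            "[%g, %g]; units suspect",
            recording.subject_id,
            recording.test,
            recording.eye_condition,
            recording.sensor_site,
            mean_norm,
            lo,
            hi,
        )

    try:
        ap, ml = anatomical_basis(cc, placement[recording.sensor_site])
    except ValueError as err:
        raise ValueError(f"sensor {recording.sensor_site!r}: {err}") from None

    rotated = samples @ np.column_stack([ap, ml, cc])
    rotated = rotated - rotated.mean(axis=0)

    return AnatomicalSignal(
        subject_id=recording.subject_id,
        group=recording.group,
        test=recording.test,
        eye_condition=recording.eye_condition,
        sensor_site=recording.sensor_site,
        fs=recording.fs,
        samples=rotated,
        truncated=recording.truncated,
        unit_suspect=unit_suspect,
    )


def preprocess_recording(
    recording: TrialRecording,
    window: int = 5,
    placement_convention: dict | None = None,
) -> AnatomicalSignal:
    """Full preprocessing chain: smooth, verticalize, remove baseline."""
    smoothed = np.column_stack(
        [moving_average(recording.samples[:, j], window) for j in range(3)]
    )
    filtered = TrialRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        test=recording.test,
        eye_condition=recording.eye_condition,
        sensor_site=recording.sensor_site,
        fs=recording.fs,
        samples=smoothed,
        truncated=recording.truncated,
    )
    return to_anatomical_frame(filtered, placement_convention)
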