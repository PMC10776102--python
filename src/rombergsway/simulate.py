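"""Synthetic quiet-standing accelerometer cohorts.

The generator emulates the study's recording setup: for every subject,
four body-worn tri-axial accelerometers (head, pelvis, both ankles) record
30 s at 128 Hz in each of the four conditions (Romberg / tandem Romberg,
eyes open / closed).  Each trial is built as

    sensor sample = R(tilt) . (sway_AP, sway_ML, sway_CC + g) + noise

where sway along each anatomical axis is a zero-mean band-limited Gaussian
process whose RMS is ``base_amplitude[axis] x group/condition multiplier x
subject factor``, g = 9.81 m/s^2 lies along the true vertical, R(tilt) is a
fixed per-subject, per-sensor mounting rotation, and the noise term is
white (muscle vibration and sensor noise).

Everything is driven by :class:`numpy.random.SeedSequence` streams derived
from the config seed, so identical (config, seed) pairs yield bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AXES,
    EYE_CONDITIONS,
    GRAVITY,
    GROUPS,
    SENSOR_SITES,
    SENSOR_TO_BODY_PART,
    TESTS,
    CohortConfig,
)
from .records import TrialRecording

__all__ = [
    "simulate_sway_track",
    "simulate_trial",
    "simulate_cohort",
    "draw_tilt_rotation",
    "assign_vng_label",
    "Cohort",
]


def _as_seedseq(seed_stream) -> np.random.SeedSequence:
    if isinstance(seed_stream, np.random.SeedSequence):
        return seed_stream
    if isinstance(seed_stream, (int, np.integer)):
        return np.random.SeedSequence(int(seed_stream))
    raise TypeError(f"seed_stream must be an int or SeedSequence, got {type(seed_stream)}")


def simulate_sway_track(config: CohortConfig, amplitude: float, seed_stream) -> np.ndarray:
    """One scalar sway-acceleration track: zero-mean, band-limited Gaussian.

    White Gaussian noise is restricted to ``config.sway_band`` in the
    frequency domain, re-centred, and rescaled so the sample RMS equals
    ``amplitude`` exactly.  Returns round(fs * duration) samples in m/s^2.
    """
    if not np.isfinite(amplitude):
        raise ValueError(f"amplitude must be finite, got {amplitude}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    n = config.n_samples
    rng = np.random.default_rng(_as_seedseq(seed_stream))
    white = rng.standard_normal(n)
    if amplitude == 0:
        return np.zeros(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    low, high = config.sway_band
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    rms = float(np.sqrt(np.mean(x * x)))
    if rms == 0.0:  # band contained no FFT bin
        raise ValueError(f"sway_band {config.sway_band} contains no frequency bin at n={n}")
    return x * (amplitude / rms)


def draw_tilt_rotation(tilt_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed mounting-tilt rotation: a random horizontal axis, angle uniform
    in +/- ``tilt_deg``.

    The azimuth and the signed angle fraction are drawn regardless of
    ``tilt_deg`` so that sweeping the tilt magnitude with the same stream
    scales the same rotation.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    u = rng.uniform(-1.0, 1.0)
    angle = np.deg2rad(u * tilt_deg)
    axis = np.array([np.cos(phi), np.sin(phi), 0.0])
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def simulate_trial(
    config: CohortConfig,
    group: str,
    test: str,
    eye_condition: str,
    sensor_site: str,
    seed_stream,
    *,
    subject_id: str = "sim001",
    subject_factor: float = 1.0,
    tilt_rotation: np.ndarray | None = None,
) -> TrialRecording:
    """Simulate one 30 s sensor recording for one subject/test/condition.

    ``subject_factor`` is the between-subject amplitude factor (1.0 for a
    nominal subject); ``tilt_rotation`` overrides the per-trial tilt draw so
    a cohort can hold each subject's sensor mounting fixed across
    conditions.
    """
    for name, value, allowed in (
        ("group", group, GROUPS),
        ("test", test, TESTS),
        ("eye_condition", eye_condition, EYE_CONDITIONS),
        ("sensor_site", sensor_site, SENSOR_SITES),
    ):
        if value not in allowed:
            raise ValueError(f"unknown {name} {value!r}; expected one of {allowed}")

    body_part = SENSOR_TO_BODY_PART[sensor_site]
    ss = _as_seedseq(seed_stream)
    tilt_ss, ap_ss, ml_ss, cc_ss, noise_ss, trunc_ss = ss.spawn(6)

    if tilt_rotation is None:
        tilt_rotation = draw_tilt_rotation(config.tilt_deg, np.random.default_rng(tilt_ss))

    n = config.n_samples
    sway = np.empty((n, 3))
    for j, (axis, axis_ss) in enumerate(zip(AXES, (ap_ss, ml_ss, cc_ss))):
        amplitude = (
            config.base_amplitude[axis]
            * config.multiplier(group, test, eye_condition, axis, body_part)
            * subject_factor
        )
        sway[:, j] = simulate_sway_track(config, amplitude, axis_ss)

    sway[:, 2] += GRAVITY  # accelerometer reads +g along the upward vertical
    if config.hf_noise_rms > 0:
        # muscle vibration is body-generated, so it rides in the anatomical
        # frame and is tilted together with the sway
        sway += config.hf_noise_rms * np.random.default_rng(
            noise_ss
        ).standard_normal((n, 3))
    sensor = sway @ tilt_rotation.T

    truncated = False
    if config.truncate_prob > 0:
        if np.random.default_rng(trunc_ss).uniform() < config.truncate_prob:
            keep = max(2, int(round(n * config.truncate_fraction)))
            sensor = sensor[:keep]
            truncated = True

    return TrialRecording(
        subject_id=subject_id,
        group=group,
        test=test,
        eye_condition=eye_condition,
        sensor_site=sensor_site,
        fs=config.fs,
        samples=sensor,
        truncated=truncated,
    )


def assign_vng_label(caloric_weakness_pct: float, spv_sum_dps: float) -> str:
    """Apply the clinical labeling rule to simulated VNG metadata.

    Bilateral hypofunction: summed bithermal peak slow-phase velocity below
    6 deg/s on each side; unilateral: caloric weakness of at least 25%;
    otherwise healthy.  This is a metadata label only — no eye-movement
    signal is analysed.
    """
    if spv_sum_dps < 6.0:
        return "BVH"
    if caloric_weakness_pct >= 25.0:
        return "UVH"
    return "HC"


@dataclass
class Cohort:
    """A simulated cohort: all trial recordings plus the subject table."""

    config: CohortConfig
    recordings: list[TrialRecording]
    subjects: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_recordings(self) -> int:
        return len(self.recordings)


# draws per group consistent with the labeling rule above
_VNG_RANGES = {
    "HC": ((0.0, 20.0), (10.0, 40.0)),
    "UVH": ((25.0, 80.0), (10.0, 40.0)),
    "BVH": ((0.0, 80.0), (1.0, 5.5)),
}


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full cohort: 4 sensors x 2 tests x 2 eye conditions per subject.

    Per subject, one amplitude factor (lognormal, sigma ``subject_sigma``)
    and one mounting tilt per sensor are drawn once and shared across all
    that subject's trials.
    """
    if config.n_per_group < 2:
        raise ValueError(
            f"n_per_group must be >= 2 (group statistics undefined below that), "
            f"got {config.n_per_group}"
        )
    conditions = [(t, e) for t in TESTS for e in EYE_CONDITIONS]
    recordings: list[TrialRecording] = []
    subject_rows = []
    subj_idx = 0
    for group in config.group_labels:
        for i in range(config.n_per_group):
            subject_id = f"{group}{i + 1:03d}"
            subj_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(subj_idx, 1))
            )
            factor = float(np.exp(subj_rng.normal(0.0, config.subject_sigma)))
            tilts = {
                site: draw_tilt_rotation(config.tilt_deg, subj_rng)
                for site in SENSOR_SITES
            }
            (wk_lo, wk_hi), (spv_lo, spv_hi) = _VNG_RANGES[group]
            weakness = float(subj_rng.uniform(wk_lo, wk_hi))
            spv = float(subj_rng.uniform(spv_lo, spv_hi))
            subject_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "caloric_weakness_pct": round(weakness, 1),
                    "spv_sum_dps": round(spv, 1),
                    "vng_label": assign_vng_label(weakness, spv),
                }
            )
            trial_idx = 0
            for site in SENSOR_SITES:
                for test, eye in conditions:
                    trial_ss = np.random.SeedSequence(
                        config.seed, spawn_key=(subj_idx, 0, trial_idx)
                    )
                    recordings.append(
                        simulate_trial(
                            config,
                            group,
                            test,
                            eye,
                            site,
                            trial_ss,
                            subject_id=subject_id,
                            subject_factor=factor,
                            tilt_rotation=tilts[site],
                        )
                    )
                    trial_idx += 1
            subj_idx += 1
    subjects = pd.DataFrame(subject_rows)
    return Cohort(config=config, recordings=recordings, subjects=subjects)
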