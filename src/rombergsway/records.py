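"""In-memory containers for raw and preprocessed trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EYE_CONDITIONS, GROUPS, SENSOR_SITES, TESTS


def _check_enum(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValueError(f"unknown {name} {value!r}; expected one of {allowed}")


@dataclass
class TrialRecording:
    """One sensor's tri-axial acceleration series for one subject/test/condition.

    ``samples`` is an (n, 3) array of sensor-frame (x, y, z) accelerations in
    m/s^2, gravity included.  ``truncated`` marks a trial the protocol cut
    short (postural instability with fall risk).
    """

    subject_id: str
    group: str
    test: str
    eye_condition: str
    sensor_site: str
    fs: float
    samples: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        _check_enum("group", self.group, GROUPS)
        _check_enum("test", self.test, TESTS)
        _check_enum("eye_condition", self.eye_condition, EYE_CONDITIONS)
        _check_enum("sensor_site", self.sensor_site, SENSOR_SITES)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got shape {self.samples.shape}")
        if self.samples.shape[0] == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class AnatomicalSignal:
    """A trial expressed on baseline-removed anatomical axes.

    ``samples`` columns are (AP, ML, CC): antero-posterior, medio-lateral,
    cranio-caudal, with CC pointing cranially (opposite gravity).  Each axis
    has had the whole-trial mean subtracted, so per-axis means are ~0.
    ``unit_suspect`` flags trials whose mean acceleration norm fell outside
    the plausible gravity window [7, 13] m/s^2 (wrong units or pre-centred
    input).
    """

    subject_id: str
    group: str
    test: str
    eye_condition: str
    sensor_site: str
    fs: float
    samples: np.ndarray
    truncated: bool = False
    unit_suspect: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got shape {self.samples.shape}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def axis(self, name: str) -> np.ndarray:
        """Return the series for one anatomical axis ('AP', 'ML' or 'CC')."""
        idx = {"AP": 0, "ML": 1, "CC": 2}
        try:
            return self.samples[:, idx[name]]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected AP, ML or CC") from None
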