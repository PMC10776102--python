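"""Study-design vocabulary and simulator configuration.

The experimental grid is fixed by the protocol: two static balance tests
(feet-together Romberg, heel-to-toe tandem Romberg), each performed eyes
open and eyes closed for 30 s, recorded at 128 Hz by tri-axial
accelerometers on the head, pelvis and both ankles.  Ankle channels are
aggregated into a single ``ankles`` body part downstream, so the analysis
grid is 4 metrics x 3 anatomical axes x 3 body parts per condition.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import yaml

GRAVITY = 9.81  # m/s^2, accelerometer reads +g along the upward vertical at rest

GROUPS = ("HC", "UVH", "BVH")
TESTS = ("romberg", "tandem")
EYE_CONDITIONS = ("open", "closed")
SENSOR_SITES = ("head", "pelvis", "ankle_left", "ankle_right")
BODY_PARTS = ("head", "pelvis", "ankles")
AXES = ("AP", "ML", "CC")
METRICS = ("max_acc", "mean_acc", "rms_acc", "mv")

SENSOR_TO_BODY_PART = {
    "head": "head",
    "pelvis": "pelvis",
    "ankle_left": "ankles",
    "ankle_right": "ankles",
}

#: key into the group/condition amplitude table
MultiplierKey = tuple[str, str, str, str, str]  # (group, test, eye, axis, body_part)


def default_multipliers() -> dict[MultiplierKey, float]:
    """Amplitude scale factors encoding the qualitative group effects.

    Eyes-closed Romberg and eyes-open tandem inflate medio-lateral sway in
    bilateral hypofunction strongly (BVH/HC >= 2 on ML) and in unilateral
    hypofunction only negligibly, while the eyes-closed tandem condition
    destabilises every group about equally so no group difference survives
    correction.  The same factor is used for every body part.
    """
    # (test, eye) -> axis -> group -> factor
    base: dict[tuple[str, str], dict[str, dict[str, float]]] = {
        ("romberg", "open"): {
            "AP": {"HC": 1.0, "UVH": 1.0, "BVH": 1.0},
            "ML": {"HC": 1.0, "UVH": 1.0, "BVH": 1.0},
            "CC": {"HC": 1.0, "UVH": 1.0, "BVH": 1.0},
        },
        ("romberg", "closed"): {
            "AP": {"HC": 1.3, "UVH": 1.3, "BVH": 1.8},
            "ML": {"HC": 1.3, "UVH": 1.365, "BVH": 3.0},
            "CC": {"HC": 1.1, "UVH": 1.1, "BVH": 1.3},
        },
        ("tandem", "open"): {
            "AP": {"HC": 1.5, "UVH": 1.5, "BVH": 1.8},
            "ML": {"HC": 1.8, "UVH": 1.89, "BVH": 4.0},
            "CC": {"HC": 1.2, "UVH": 1.2, "BVH": 1.3},
        },
        ("tandem", "closed"): {
            "AP": {"HC": 3.0, "UVH": 3.0, "BVH": 3.0},
            "ML": {"HC": 3.5, "UVH": 3.5, "BVH": 3.5},
            "CC": {"HC": 1.5, "UVH": 1.5, "BVH": 1.5},
        },
    }
    table: dict[MultiplierKey, float] = {}
    for (test, eye), per_axis in base.items():
        for axis, per_group in per_axis.items():
            for group, factor in per_group.items():
                for part in BODY_PARTS:
                    table[(group, test, eye, axis, part)] = factor
    return table


def null_multipliers() -> dict[MultiplierKey, float]:
    """A no-effect table: every group scaled identically (all ones)."""
    return {
        (g, t, e, a, b): 1.0
        for g in GROUPS
        for t in TESTS
        for e in EYE_CONDITIONS
        for a in AXES
        for b in BODY_PARTS
    }


@dataclass
class CohortConfig:
    """Settings for one simulated cohort.

    Parameters
    ----------
    n_per_group : subjects per group label (>= 2; group statistics need it).
    group_labels : which of HC / UVH / BVH to simulate.
    fs : sampling rate, Hz.
    duration : trial length, seconds.
    sway_band : (low, high) Hz band of the quiet-standing sway process.
    base_amplitude : per-axis RMS sway acceleration, m/s^2, before group
        and subject scaling.
    group_condition_multiplier : (group, test, eye, axis, body_part) ->
        amplitude scale factor >= 0.
    tilt_deg : static sensor-mounting tilt magnitude bound, degrees; each
        subject x sensor draws a fixed tilt once, uniform in +/- tilt_deg
        about a random horizontal axis.
    hf_noise_rms : white muscle-vibration noise RMS per channel, m/s^2.
    subject_sigma : sigma of the lognormal between-subject amplitude factor
        (one draw per subject, shared across all that subject's trials).
    truncate_prob : per-trial probability that the trial is cut short
        (the protocol terminates a trial on postural instability); off by
        default.
    truncate_fraction : fraction of samples kept when a trial is truncated.
    seed : master seed; (config, seed) fully determines every sample.
    """

    n_per_group: int = 31
    group_labels: tuple[str, ...] = ("HC", "UVH", "BVH")
    fs: float = 128.0
    duration: float = 30.0
    sway_band: tuple[float, float] = (0.1, 2.0)
    base_amplitude: dict[str, float] = field(
        default_factory=lambda: {"AP": 0.04, "ML": 0.03, "CC": 0.02}
    )
    group_condition_multiplier: dict[MultiplierKey, float] = field(
        default_factory=default_multipliers
    )
    tilt_deg: float = 5.0
    hf_noise_rms: float = 0.01
    subject_sigma: float = 0.3
    truncate_prob: float = 0.0
    truncate_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        low, high = self.sway_band
        if not (0 <= low < high < self.fs / 2):
            raise ValueError(
                f"sway_band must satisfy 0 <= low < high < fs/2, got {self.sway_band}"
            )
        for g in self.group_labels:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
        for axis in AXES:
            if axis not in self.base_amplitude:
                raise ValueError(f"base_amplitude missing axis {axis!r}")
            if self.base_amplitude[axis] < 0:
                raise ValueError(f"base_amplitude[{axis!r}] must be >= 0")
        for key, value in self.group_condition_multiplier.items():
            if value < 0:
                raise ValueError(f"multiplier for {key} must be >= 0, got {value}")
        if self.hf_noise_rms < 0:
            raise ValueError("hf_noise_rms must be >= 0")
        if not 0 <= self.truncate_prob <= 1:
            raise ValueError("truncate_prob must be in [0, 1]")
        if not 0 < self.truncate_fraction <= 1:
            raise ValueError("truncate_fraction must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def multiplier(self, group: str, test: str, eye: str, axis: str, body_part: str) -> float:
        key = (group, test, eye, axis, body_part)
        try:
            return self.group_condition_multiplier[key]
        except KeyError:
            raise KeyError(
                f"no amplitude multiplier for (group={group!r}, test={test!r}, "
                f"eye_condition={eye!r}, axis={axis!r}, body_part={body_part!r})"
            ) from None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_labels"] = list(self.group_labels)
        d["sway_band"] = list(self.sway_band)
        d["group_condition_multiplier"] = {
            "/".join(key): value for key, value in self.group_condition_multiplier.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "group_labels" in d:
            d["group_labels"] = tuple(d["group_labels"])
        if "sway_band" in d:
            d["sway_band"] = tuple(d["sway_band"])
        if "group_condition_multiplier" in d:
            raw = d["group_condition_multiplier"]
            if raw and isinstance(next(iter(raw)), str):
                d["group_condition_multiplier"] = {
                    tuple(key.split("/")): float(v) for key, v in raw.items()
                }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
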