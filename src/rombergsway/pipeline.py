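"""End-to-end helpers chaining simulation, preprocessing, metrics and stats."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import CohortConfig
from .metrics import extract_parameters
from .preprocess import preprocess_recording
from .records import AnatomicalSignal, TrialRecording
from .simulate import Cohort, simulate_cohort
from .stats import ComparisonResult, compare_groups

__all__ = [
    "preprocess_cohort",
    "extract_cohort_parameters",
    "simulate_and_extract",
    "analyze_cohort",
]


def preprocess_cohort(
    recordings: Iterable[TrialRecording],
    window: int = 5,
    placement_convention: dict | None = None,
) -> list[AnatomicalSignal]:
    return [preprocess_recording(r, window, placement_convention) for r in recordings]


def extract_cohort_parameters(
    recordings: Iterable[TrialRecording],
    window: int = 5,
    placement_convention: dict | None = None,
) -> pd.DataFrame:
    """Raw recordings -> preprocessed signals -> long parameter table."""
    return extract_parameters(preprocess_cohort(recordings, window, placement_convention))


def simulate_and_extract(config: CohortConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort and return it with its kinematic parameter table."""
    cohort = simulate_cohort(config)
    return cohort, extract_cohort_parameters(cohort.recordings)


def analyze_cohort(
    config: CohortConfig,
    designs: Sequence[str] = ("two-group",),
    alpha: float = 0.05,
    bonferroni_factor: int = 12,
) -> dict[str, list[ComparisonResult]]:
    """Simulate, extract and compare in one call; keyed by design."""
    _, table = simulate_and_extract(config)
    return {
        design: compare_groups(table, design, alpha, bonferroni_factor)
        for design in designs
    }
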