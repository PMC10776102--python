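"""Group-comparison statistics for the kinematic parameter table.

The comparison scheme mirrors the study's analysis: the pooled VH group is
compared with healthy controls by pooled-variance Student t tests (with
Cohen's d); the HC/UVH/BVH subgroups by one-way ANOVA (with eta squared),
followed — only where the ANOVA survives correction — by Scheffé post hoc
pairwise tests.  Raw p-values are Bonferroni-corrected with a family factor
of 12, the number of hypotheses sharing one sensor placement and balance
test: 3 anatomical axes x 4 kinematic metrics.  Significance is judged at
alpha = 0.05 on the corrected p.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "AnovaResult",
    "two_sample_t",
    "one_way_anova",
    "bonferroni_correct",
    "scheffe_posthoc",
    "ComparisonResult",
    "compare_groups",
    "comparison_frame",
    "BONFERRONI_FACTOR",
]

#: 3 anatomical axes x 4 kinematic metrics per (test, condition, body part)
BONFERRONI_FACTOR = 12


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ms_within: float
    degenerate: bool = False


def _clean(values, name: str) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"group {name} needs n >= 2, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"group {name} contains non-finite values")
    return x


def two_sample_t(a, b) -> TTestResult:
    """Independent two-sample pooled-variance Student t test with Cohen's d.

    Returns the t statistic for mean(a) - mean(b), its two-sided p from the
    t distribution with n_a + n_b - 2 degrees of freedom, and Cohen's d
    using the pooled SD.  Identical constant groups give t = 0, p = 1;
    constant groups with different means have no valid t scale and are
    rejected.
    """
    xa, xb = _clean(a, "a"), _clean(b, "b")
    na, nb = xa.size, xb.size
    ma, mb = xa.mean(), xb.mean()
    df = na + nb - 2
    pooled_var = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df
    if pooled_var == 0.0:
        if ma == mb:
            return TTestResult(t=0.0, df=df, p=1.0, cohens_d=0.0)
        raise ValueError(
            "zero pooled variance with unequal group means: t undefined "
            "(degenerate constant groups)"
        )
    se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = (ma - mb) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    d = (ma - mb) / math.sqrt(pooled_var)
    return TTestResult(t=t, df=df, p=p, cohens_d=d)


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA with eta squared (SS_between / SS_total).

    ``groups`` is a sequence of >= 2 value arrays, each with n >= 2.  An
    all-equal input returns F = 0, p = 1, eta^2 = 0 by convention; zero
    within-group variance with distinct means is reported as a degenerate
    infinite F with p = 0.
    """
    xs = [_clean(g, str(i)) for i, g in enumerate(groups)]
    k = len(xs)
    if k < 2:
        raise ValueError(f"ANOVA needs >= 2 groups, got {k}")
    N = sum(x.size for x in xs)
    grand = sum(x.sum() for x in xs) / N
    ss_between = sum(x.size * (x.mean() - grand) ** 2 for x in xs)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in xs)
    ss_total = ss_between + ss_within
    df_between, df_within = k - 1, N - k
    if ss_total == 0.0:
        return AnovaResult(0.0, df_between, df_within, 1.0, 0.0, 0.0)
    if ss_within == 0.0:
        logger.warning("zero within-group variance with distinct means: degenerate ANOVA")
        return AnovaResult(
            math.inf, df_between, df_within, 0.0, 1.0, 0.0, degenerate=True
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F, df_between, df_within, p, ss_between / ss_total, ms_within)


def bonferroni_correct(p_raw: float, factor: int = BONFERRONI_FACTOR) -> float:
    """Bonferroni family correction: min(1, factor * p)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw must be in [0, 1], got {p_raw}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    return min(1.0, factor * p_raw)


def scheffe_posthoc(groups, labels=None) -> dict[tuple, float]:
    """Scheffé pairwise p-values after a one-way ANOVA.

    For each pair the pooled-within-MS t statistic is referred to the
    Scheffé criterion: p = Pr[F(k-1, N-k) >= t^2 / (k-1)].  At k = 2 this
    reduces exactly to the pooled t test; for k >= 3 it is conservative
    relative to unadjusted pairwise t tests.
    """
    xs = [_clean(g, str(i)) for i, g in enumerate(groups)]
    k = len(xs)
    if labels is None:
        labels = list(range(k))
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    anova = one_way_anova(xs)
    out: dict[tuple, float] = {}
    for i, j in itertools.combinations(range(k), 2):
        xi, xj = xs[i], xs[j]
        if anova.ms_within == 0.0:
            p = 1.0 if xi.mean() == xj.mean() else 0.0
        else:
            t_sq = (xi.mean() - xj.mean()) ** 2 / (
                anova.ms_within * (1.0 / xi.size + 1.0 / xj.size)
            )
            p = float(sps.f.sf(t_sq / (k - 1), k - 1, anova.df_within))
        out[(labels[i], labels[j])] = p
    return out


@dataclass
class ComparisonResult:
    """Statistics for one kinematic parameter across groups."""

    test: str
    eye_condition: str
    body_part: str
    axis: str
    metric: str
    group_stats: dict[str, tuple[int, float, float]]  # group -> (n, mean, sd)
    t_stat: float | None = None
    p_raw: float | None = None
    p_bonferroni: float | None = None
    cohens_d: float | None = None
    f_stat: float | None = None
    p_anova_raw: float | None = None
    p_anova_bonferroni: float | None = None
    eta_squared: float | None = None
    scheffe_pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    significant: bool = False

    @property
    def parameter_id(self) -> tuple[str, str, str, str, str]:
        return (self.test, self.eye_condition, self.body_part, self.axis, self.metric)


_KEYS = ["test", "eye_condition", "body_part", "axis", "metric"]


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "group", *_KEYS, "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns {sorted(missing)}")
    return table.pivot_table(
        index=["group", "subject_id"], columns=_KEYS, values="value"
    )


def compare_groups(
    table: pd.DataFrame,
    design: str = "two-group",
    alpha: float = 0.05,
    bonferroni_factor: int = BONFERRONI_FACTOR,
) -> list[ComparisonResult]:
    """Run the full comparison scheme over a long-format parameter table.

    ``design='two-group'`` pools UVH and BVH into VH and runs t tests per
    parameter; ``design='three-group'`` runs HC/UVH/BVH ANOVAs with Scheffé
    post hoc gated on the Bonferroni-corrected ANOVA p.  Parameters with
    incomplete group data are dropped with a warning.
    """
    if design not in ("two-group", "three-group"):
        raise ValueError(f"design must be 'two-group' or 'three-group', got {design!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    table = table.copy()
    if design == "two-group":
        table["group"] = table["group"].map(
            lambda g: "VH" if g in ("UVH", "BVH") else g
        )
        group_order = [g for g in ("VH", "HC") if g in set(table["group"])]
        if len(group_order) != 2:
            raise ValueError(
                f"two-group design needs both VH (UVH/BVH) and HC subjects, "
                f"found groups {sorted(set(table['group']))}"
            )
    else:
        group_order = [g for g in ("HC", "UVH", "BVH") if g in set(table["group"])]
        if len(group_order) < 3:
            raise ValueError(
                f"three-group design needs HC, UVH and BVH subjects, "
                f"found groups {sorted(set(table['group']))}"
            )

    wide = _pivot(table)
    results: list[ComparisonResult] = []
    for param in wide.columns:
        col = wide[param]
        per_group = []
        ok = True
        for g in group_order:
            vals = col.loc[g].dropna().to_numpy()
            if vals.size < 2:
                ok = False
                break
            per_group.append(vals)
        if not ok:
            logger.warning("parameter %s dropped: incomplete group data", param)
            continue

        group_stats = {
            g: (int(v.size), float(v.mean()), float(v.std(ddof=1)))
            for g, v in zip(group_order, per_group)
        }
        res = ComparisonResult(*param, group_stats=group_stats)
        if design == "two-group":
            tt = two_sample_t(per_group[0], per_group[1])
            res.t_stat, res.p_raw, res.cohens_d = tt.t, tt.p, tt.cohens_d
            res.p_bonferroni = bonferroni_correct(tt.p, bonferroni_factor)
            res.significant = res.p_bonferroni < alpha
        else:
            an = one_way_anova(per_group)
            res.f_stat, res.p_anova_raw = an.F, an.p
            res.eta_squared = an.eta_squared
            res.p_anova_bonferroni = bonferroni_correct(an.p, bonferroni_factor)
            res.significant = res.p_anova_bonferroni < alpha
            if res.significant:
                res.scheffe_pairwise = scheffe_posthoc(per_group, labels=group_order)
        results.append(res)
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy per-parameter report: group mean +/- SD, statistics, corrected p."""
    rows = []
    for r in results:
        row: dict = dict(zip(_KEYS, r.parameter_id))
        for g, (n, m, sd) in r.group_stats.items():
            row[f"n_{g}"] = n
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = sd
        if r.t_stat is not None:
            row.update(
                t_stat=r.t_stat,
                p_raw=r.p_raw,
                p_bonferroni=r.p_bonferroni,
                cohens_d=r.cohens_d,
            )
        if r.f_stat is not None:
            row.update(
                F_stat=r.f_stat,
                p_anova_raw=r.p_anova_raw,
                p_anova_bonferroni=r.p_anova_bonferroni,
                eta_squared=r.eta_squared,
            )
        for (ga, gb), p in r.scheffe_pairwise.items():
            row[f"scheffe_p_{ga}_{gb}"] = p
        row["significant"] = r.significant
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(_KEYS, ignore_index=True)
    return frame
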