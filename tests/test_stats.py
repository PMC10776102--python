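"""Group-comparison statistics against independent references and identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import rombergsway as rs
from rombergsway.stats import one_way_anova, scheffe_posthoc, two_sample_t


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.cohens_d == 0.0

    def test_frozen_example(self):
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.6742346141747673, rel=1e-12)
        assert res.df == 4
        assert res.p == pytest.approx(0.021311641128756713, rel=1e-9)
        assert res.cohens_d == pytest.approx(-3.0, rel=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        fwd, rev = two_sample_t(a, b), two_sample_t(b, a)
        assert fwd.t == pytest.approx(-rev.t, rel=1e-12)
        assert fwd.cohens_d == pytest.approx(-rev.cohens_d, rel=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)

    def test_constant_groups_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_t([1.0], [2.0, 3.0])


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, g, g])
        assert res.F == 0.0 and res.p == 1.0 and res.eta_squared == 0.0

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert res.degenerate
        assert res.p == 0.0 and res.eta_squared == 1.0

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        anova = one_way_anova([a, b])
        tt = two_sample_t(a, b)
        assert anova.F == pytest.approx(tt.t**2, rel=1e-9)
        assert anova.p == pytest.approx(tt.p, rel=1e-9)

    def test_eta_squared_partition(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.5)]
        res = one_way_anova(groups)
        ss_total = sum(((np.concatenate(groups) - np.concatenate(groups).mean()) ** 2))
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert res.eta_squared + ss_within / ss_total == pytest.approx(1.0, rel=1e-12)


class TestBonferroni:
    def test_examples(self):
        assert rs.bonferroni_correct(0.004, 12) == pytest.approx(0.048)
        assert rs.bonferroni_correct(0.2, 12) == 1.0
        assert rs.bonferroni_correct(0.0, 12) == 0.0

    @given(
        st.floats(0, 1), st.floats(0, 1), st.integers(1, 50), st.integers(1, 50)
    )
    def test_monotone_in_p_and_factor(self, p1, p2, f1, f2):
        p_lo, p_hi = sorted((p1, p2))
        f_lo, f_hi = sorted((f1, f2))
        assert rs.bonferroni_correct(p_lo, f_lo) <= rs.bonferroni_correct(p_hi, f_lo)
        assert rs.bonferroni_correct(p_lo, f_lo) <= rs.bonferroni_correct(p_lo, f_hi)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rs.bonferroni_correct(1.2)
        with pytest.raises(ValueError):
            rs.bonferroni_correct(0.5, 0)


class TestScheffe:
    def test_two_groups_equals_t_test(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        pairs = scheffe_posthoc([a, b], labels=["a", "b"])
        assert pairs[("a", "b")] == pytest.approx(two_sample_t(a, b).p, rel=1e-9)

    def test_identical_groups_all_one(self):
        g = [1.0, 2.0, 3.0]
        assert all(p == 1.0 for p in scheffe_posthoc([g, g, g]).values())

    def test_conservative_vs_pairwise_t(self, rng):
        # against the unadjusted pairwise test on the same ANOVA-pooled
        # error scale, Scheffé can only raise the p-value (k >= 3)
        for _ in range(25):
            groups = [rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(4, 12))) for _ in range(3)]
            pairs = scheffe_posthoc(groups)
            N = sum(g.size for g in groups)
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - 3)
            for (i, j), p in pairs.items():
                gi, gj = groups[i], groups[j]
                t = (gi.mean() - gj.mean()) / np.sqrt(msw * (1 / gi.size + 1 / gj.size))
                p_pair = 2 * sps.t.sf(abs(t), N - 3)
                assert p >= p_pair - 1e-12


class TestAgainstReferenceImplementations:
    """t, F, eta^2, Cohen's d cross-checked against scipy and pingouin."""

    def test_t_and_anova_match_scipy(self, rng):
        for _ in range(100):
            na, nb = rng.integers(3, 30, 2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            mine = two_sample_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert mine.t == pytest.approx(ref.statistic, rel=1e-9)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

            groups = [rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(3, 20))) for _ in range(3)]
            mine_f = one_way_anova(groups)
            ref_f = sps.f_oneway(*groups)
            assert mine_f.F == pytest.approx(ref_f.statistic, rel=1e-9)
            assert mine_f.p == pytest.approx(ref_f.pvalue, rel=1e-9)

    def test_effect_sizes_match_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 25)))
            b = rng.normal(0.7, 1.3, int(rng.integers(5, 25)))
            d_ref = pingouin.compute_effsize(a, b, eftype="cohen")
            assert two_sample_t(a, b).cohens_d == pytest.approx(d_ref, rel=1e-9)

            groups = [rng.normal(m, 1, 12) for m in (0.0, 0.4, 1.0)]
            frame = pd.DataFrame(
                {
                    "y": np.concatenate(groups),
                    "g": np.repeat(["g0", "g1", "g2"], 12),
                }
            )
            aov = pingouin.anova(data=frame, dv="y", between="g", detailed=True)
            assert one_way_anova(groups).eta_squared == pytest.approx(
                float(aov.loc[0, "np2"]), rel=1e-9
            )


class TestCompareGroups:
    def _table(self, config):
        _, table = rs.simulate_and_extract(config)
        return table

    def test_two_identical_groups_nothing_significant(self):
        # a cohort whose VH arm is a literal copy of the HC arm: every t is
        # exactly 0, so no parameter can be flagged
        config = rs.CohortConfig(
            n_per_group=4, group_labels=("HC",), duration=4.0, seed=5
        )
        table = self._table(config)
        clone = table.copy()
        clone["group"] = "UVH"
        clone["subject_id"] = clone["subject_id"].str.replace("HC", "UVH")
        results = rs.compare_groups(pd.concat([table, clone]), "two-group")
        assert len(results) == 144
        assert all(r.t_stat == 0.0 and r.p_raw == 1.0 for r in results)
        assert sum(r.significant for r in results) == 0

    def test_three_group_gates_scheffe_on_corrected_anova(self):
        config = rs.CohortConfig(n_per_group=6, duration=4.0, seed=9)
        results = rs.compare_groups(self._table(config), "three-group")
        for r in results:
            assert 0 <= r.p_anova_raw <= 1
            assert r.p_anova_bonferroni >= r.p_anova_raw
            assert 0 <= r.eta_squared <= 1
            if r.significant:
                assert set(r.scheffe_pairwise) == {("HC", "UVH"), ("HC", "BVH"), ("UVH", "BVH")}
            else:
                assert r.scheffe_pairwise == {}

    def test_two_group_pools_vh(self):
        config = rs.CohortConfig(n_per_group=3, duration=4.0, seed=2)
        results = rs.compare_groups(self._table(config), "two-group")
        assert all(set(r.group_stats) == {"VH", "HC"} for r in results)
        assert all(r.group_stats["VH"][0] == 6 for r in results)

    def test_comparison_frame_columns(self):
        config = rs.CohortConfig(n_per_group=3, duration=4.0, seed=2)
        frame = rs.comparison_frame(rs.compare_groups(self._table(config), "two-group"))
        assert len(frame) == 144
        for col in ("t_stat", "p_raw", "p_bonferroni", "cohens_d", "significant"):
            assert col in frame.columns

    def test_unknown_design_rejected(self, small_config):
        _, table = rs.simulate_and_extract(small_config)
        with pytest.raises(ValueError, match="design"):
            rs.compare_groups(table, "four-group")
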