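"""Scalar statistics: gating, tests, effect sizes, ANOVA, classification, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from oracles import bky_reference
from scipy import stats as sps

from mobidt import stats as st
from mobidt.errors import DegenerateSetError, InvalidConfigError


class TestNormalityGate:
    def test_normal_draws_mostly_parametric(self):
        rng = np.random.default_rng(0)
        routes = [st.normality_gate(rng.normal(0, 1, 26)) for _ in range(200)]
        assert np.mean([r == "parametric" for r in routes]) >= 0.90

    def test_cauchy_draws_mostly_nonparametric(self):
        rng = np.random.default_rng(1)
        routes = [st.normality_gate(rng.standard_cauchy(25)) for _ in range(100)]
        assert np.mean([r == "nonparametric" for r in routes]) >= 0.90

    def test_small_and_constant_samples(self):
        with pytest.raises(InvalidConfigError):
            st.normality_gate(np.array([1.0, 2.0]))
        with pytest.warns(UserWarning):
            assert st.normality_gate(np.ones(10)) == "nonparametric"


class TestPairedT:
    def test_printed_effect_size_identity(self):
        """t = 2.85 with n = 26 pairs implies Cohen's d = t/sqrt(n) = 0.56."""
        assert 2.85 / np.sqrt(26) == pytest.approx(0.56, abs=0.005)
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 1, 26)
        y = rng.normal(0.0, 1, 26)
        res = st.paired_t(x, y)
        assert res.effect_size == pytest.approx(res.statistic / np.sqrt(26), abs=1e-12)

    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateSetError):
            st.paired_t(x, x)

    def test_formula_oracle(self):
        x = np.array([2.1, 3.4, 1.9, 4.2, 2.8, 3.3])
        y = np.array([1.8, 3.1, 2.2, 3.5, 2.2, 3.0])
        res = st.paired_t(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.df == 5
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 5), abs=1e-12)
        sp_t, sp_p = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(sp_t) and res.p_value == pytest.approx(sp_p)


class TestWilcoxon:
    def test_printed_effect_size_identity(self):
        """z = 4.02 over 25 pairs implies Cohen's r = |z|/sqrt(50) = 0.57."""
        assert 4.02 / np.sqrt(2 * 25) == pytest.approx(0.57, abs=0.005)

    def test_effect_size_uses_2n_observations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.8, 1, 25)
        y = rng.normal(0.0, 1, 25)
        res = st.wilcoxon_signed_rank(x, y)
        assert res.effect_size == pytest.approx(abs(res.z) / np.sqrt(50), abs=1e-12)

    def test_antisymmetric_sample_z_near_zero(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        res = st.wilcoxon_signed_rank(x, np.zeros(8))
        assert abs(res.z) < 0.1

    def test_exact_p_matches_sign_enumeration_oracle(self):
        """For 8 tie-free pairs the exact two-sided p equals the tail mass of
        min(T+, T-) enumerated over all 2^8 sign assignments."""
        rng = np.random.default_rng(4)
        d = rng.normal(0.6, 1.0, 8)
        res = st.wilcoxon_signed_rank(d, np.zeros(8), method="exact")
        ranks = sps.rankdata(np.abs(d))
        obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            tplus = sum(r for r, s in zip(ranks, signs) if s)
            if min(tplus, ranks.sum() - tplus) <= obs:
                count += 1
        assert res.p_value == pytest.approx(count / 2 ** 8, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateSetError):
            st.wilcoxon_signed_rank(np.ones(8), np.ones(8))


class TestIndependentT:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 10)
        res = st.independent_t(a, a.copy())
        assert res.statistic == pytest.approx(0.0) and res.effect_size == pytest.approx(0.0)

    def test_sign_matches_shift_and_formula(self):
        a = np.array([5.1, 6.2, 5.8, 6.0])
        b = np.array([4.0, 4.5, 4.2, 4.8, 4.1])
        res = st.independent_t(a, b)
        sp = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)
        assert res.statistic > 0 and res.df == 7


class TestMixedAnova:
    def _toy(self):
        groups = np.array(["A"] * 4 + ["B"] * 4)
        y = np.array(
            [[10.0, 12.0], [11.0, 13.0], [9.0, 11.0], [10.0, 12.0],
             [14.0, 14.5], [15.0, 15.5], [13.0, 13.5], [14.0, 14.5]]
        )
        return groups, y

    def test_all_equal_gives_zero_f(self):
        groups = np.array(["A"] * 3 + ["B"] * 3)
        res, _ = st.anova_2x2_mixed(groups, np.full((6, 2), 7.0))
        assert all(r.statistic == 0.0 for r in res.values())

    def test_hand_computed_ss_oracle(self):
        """Additive dataset: group shift 3.75, condition shift computed from
        cell means; all SS terms verified against the by-hand decomposition."""
        groups, y = self._toy()
        res, table = st.anova_2x2_mixed(groups, y)
        gm = y.mean()
        ss_total = ((y - gm) ** 2).sum()
        subj = y.mean(axis=1)
        ss_bs = 2 * ((subj - gm) ** 2).sum()
        ma, mb = y[:4].mean(), y[4:].mean()
        ss_group = 2 * (4 * (ma - gm) ** 2 + 4 * (mb - gm) ** 2)
        ss_cond = 8 * ((y.mean(axis=0) - gm) ** 2).sum()
        tab = dict(zip(table.source, table.ss))
        assert tab["total"] == pytest.approx(ss_total, abs=1e-9)
        assert tab["group"] == pytest.approx(ss_group, abs=1e-9)
        assert tab["condition"] == pytest.approx(ss_cond, abs=1e-9)
        assert tab["subjects_within_groups"] == pytest.approx(ss_bs - ss_group, abs=1e-9)

    def test_ss_conservation(self, rng):
        groups = np.array(["A"] * 13 + ["B"] * 12)
        y = rng.normal(0, 1, (25, 2))
        _, table = st.anova_2x2_mixed(groups, y)
        parts = table.set_index("source")["ss"]
        total = parts[["group", "subjects_within_groups", "condition",
                       "interaction", "condition_x_subjects"]].sum()
        assert total == pytest.approx(parts["total"], rel=1e-9)

    def test_matches_pingouin_balanced(self, rng):
        import pingouin as pg

        groups = np.array(["A"] * 6 + ["B"] * 6)
        y = rng.normal(0, 1, (12, 2))
        y[6:] += 0.8
        y[:, 1] += 0.4
        res, _ = st.anova_2x2_mixed(groups, y)
        rows = [
            {"s": i, "g": groups[i], "c": c, "y": y[i, j]}
            for i in range(12) for j, c in enumerate(["c1", "c2"])
        ]
        ref = pg.mixed_anova(data=pd.DataFrame(rows), dv="y", within="c",
                             between="g", subject="s").set_index("Source")
        assert res["group"].statistic == pytest.approx(ref.loc["g", "F"], abs=1e-6)
        assert res["condition"].statistic == pytest.approx(ref.loc["c", "F"], abs=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6
        )
        assert res["group"].p_value == pytest.approx(ref.loc["g", "p_unc"], abs=1e-9)

    def test_power_simulation_group_effect_only(self):
        """Injected group effect, no condition effect: group p < 0.05 often,
        condition p behaves as a null."""
        rng = np.random.default_rng(6)
        group_sig, cond_sig = 0, 0
        n_sim = 100
        for _ in range(n_sim):
            groups = np.array(["A"] * 13 + ["B"] * 12)
            y = rng.normal(0, 1, (25, 2))
            y[13:] += 1.5
            res, _ = st.anova_2x2_mixed(groups, y)
            group_sig += res["group"].p_value < 0.05
            cond_sig += res["condition"].p_value < 0.05
        assert group_sig >= 0.90 * n_sim
        assert cond_sig <= 0.15 * n_sim

    def test_singleton_group_raises(self):
        with pytest.raises(InvalidConfigError):
            st.anova_2x2_mixed(np.array(["A", "B", "B"]), np.zeros((3, 2)))


class TestClassifyImprover:
    def test_zero_delta_is_nimp(self):
        lab, _ = st.classify_improver(0.0, np.array([0.2, -0.1, 0.4, 0.05]))
        assert lab == "nIMP"

    def test_threshold_from_normal_quantile(self):
        """sigma = 0.4 puts the bound at 1.96 * 0.4 = 0.784: +1.0 is IMP,
        -1.0 (significant decline) is still nIMP."""
        rng = np.random.default_rng(7)
        deltas = rng.normal(0, 1, 40)
        deltas = deltas / deltas.std(ddof=1) * 0.4
        lab_up, thr = st.classify_improver(1.0, deltas)
        lab_dn, _ = st.classify_improver(-1.0, deltas)
        assert thr == pytest.approx(sps.norm.ppf(0.975) * 0.4, abs=1e-9)
        assert lab_up == "IMP" and lab_dn == "nIMP"

    def test_degenerate_cohort_raises(self):
        with pytest.raises(DegenerateSetError):
            st.classify_improver(0.5, np.zeros(5))

    def test_null_cohort_upper_tail_rate(self):
        """Under a pure-null cohort only the ~2.5% upper tail is labeled IMP."""
        rng = np.random.default_rng(8)
        n_imp, total = 0, 0
        for _ in range(200):
            deltas = rng.normal(0, 0.4, 26)
            labels, _ = st.classify_cohort(deltas)
            n_imp += labels.count("IMP")
            total += 26
        rate = n_imp / total
        assert abs(rate - 0.025) < 3 * np.sqrt(0.025 * 0.975 / total) + 0.005


class TestBkyFdr:
    def test_extremes(self):
        mask, crit = st.bky_fdr(np.full(16, 0.9))
        assert not mask.any() and np.isnan(crit)
        mask, crit = st.bky_fdr(np.full(16, 0.001))
        assert mask.all() and crit == 0.001

    def test_matches_independent_reference(self, rng):
        for _ in range(200):
            m = rng.integers(5, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            p = np.clip(p, 1e-12, 1.0)
            ours, _ = st.bky_fdr(p, 0.05)
            assert np.array_equal(ours, bky_reference(p, 0.05))

    def test_rejects_superset_of_stage1_bh(self, rng):
        """The second-stage level q' * m / m0 never falls below the stage-1
        level q' = q/(1+q), so the final rejections contain the plain BH
        rejections at q'."""
        from statsmodels.stats.multitest import multipletests

        q = 0.05
        for _ in range(100):
            p = np.clip(rng.random(16) ** 2, 1e-12, 1.0)
            bky_mask, _ = st.bky_fdr(p, q)
            bh_mask = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
            assert (bky_mask | bh_mask).sum() == bky_mask.sum()

    def test_invalid_p_raises(self):
        with pytest.raises(InvalidConfigError):
            st.bky_fdr(np.array([0.5, 0.0]))


class TestAggregation:
    def test_paper_design_yields_16(self):
        """3 group-level + 1 independent t + 2 ANOVAs x 3 + 6 EEG minima."""
        scalars = [st.TestResult(f"s{i}", 1.0, 10, 0.2, 0.1, "cohen_d")
                   for i in range(10)]

        class FakeCluster:
            def __init__(self, p):
                self._p = p

            def min_p(self):
                return self._p

        clusters = {f"c{i}": FakeCluster(0.03 * (i + 1)) for i in range(6)}
        table = st.aggregate_pvalues_for_fdr(scalars, clusters)
        assert len(table) == 16

    def test_comparison_without_clusters_contributes_nothing(self):
        class Empty:
            def min_p(self):
                return np.nan

        table = st.aggregate_pvalues_for_fdr([], {"none": Empty()})
        assert len(table) == 0

    def test_singleton(self):
        table = st.aggregate_pvalues_for_fdr(
            [st.TestResult("only", 2.0, 10, 0.04, 0.3, "cohen_d")]
        )
        assert list(table.p) == [0.04]
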