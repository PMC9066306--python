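"""Group-comparison statistics: rank tests, Bayes factors, ANCOVA, power."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, ttest_ind

from equivnoise.errors import IncompleteInputError, ParameterDomainError
from equivnoise.stats import (
    PowerSpec,
    bayes_rank_bf10,
    bf_label,
    catch_exclusion_threshold,
    jzs_bf10,
    jzs_bf10_gauss_quadrature,
    mann_whitney,
    normality_gate,
    partial_rank_correlation,
    quade_ancova,
    required_n_two_sample,
)


def brute_force_mann_whitney(x, y):
    """Exhaustive permutation null of U1 (tie-free data only)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yi for xi in x for yi in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(xi > yi for xi in xs for yi in ys))
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.w_stat == 0
        assert res.p_two_sided == pytest.approx(1 / 3, rel=1e-9)
        assert res.rank_biserial == -1.0
        assert res.method == "exact"

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.rank_biserial == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.method == "approximate"  # ties disable the exact path

    def test_antisymmetry_of_effect_size(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.rank_biserial == pytest.approx(-b.rank_biserial)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_full_separation_gives_unit_effect_size(self):
        res = mann_whitney([10, 11, 12], [1, 2, 3, 4])
        assert res.rank_biserial == 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=10, unique=True
        ),
        n1=st.integers(2, 5),
    )
    def test_exact_mode_matches_enumeration(self, data, n1):
        if n1 >= len(data) - 1:
            n1 = len(data) - 2
        x, y = np.array(data[:n1]), np.array(data[n1:])
        u_ref, p_ref = brute_force_mann_whitney(x, y)
        res = mann_whitney(x, y)
        assert res.w_stat == u_ref
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-9)
        assert -1.0 <= res.rank_biserial <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(IncompleteInputError):
            mann_whitney([], [1.0])


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bf10(0.0, 48, 48) < 1.0

    def test_monotone_in_t_and_reciprocal_identity(self):
        bfs = [jzs_bf10(t, 48, 48) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        # BF10 * BF01 = 1 by construction of the ratio
        assert jzs_bf10(2.2, 30, 30) * (1.0 / jzs_bf10(2.2, 30, 30)) == pytest.approx(1.0)

    def test_two_integration_routes_agree(self):
        # tan-substitution quadrature vs inverse-gamma g-marginalisation
        for t, n in [(2.5, 48), (0.8, 20), (4.0, 15)]:
            a = jzs_bf10(t, n, n, cauchy_scale=1.0)
            b = jzs_bf10_gauss_quadrature(t, n, n, cauchy_scale=1.0)
            assert a == pytest.approx(b, rel=1e-3)

    def test_scale_is_honoured(self):
        assert jzs_bf10(2.0, 30, 30, cauchy_scale=0.707) != jzs_bf10(2.0, 30, 30, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterDomainError):
            jzs_bf10(float("inf"), 10, 10)
        with pytest.raises(ParameterDomainError):
            jzs_bf10(1.0, 1, 10)


class TestBayesRank:
    def test_null_data_supports_null(self, rng):
        x = rng.normal(0, 1, 40)
        res = bayes_rank_bf10(x, x.copy(), iterations=3000, chains=3, seed=5)
        assert res.bf10 < 1.0

    def test_shifted_data_supports_alternative(self, rng):
        x = rng.normal(0, 1, 48)
        y = rng.normal(1.0, 1, 48)
        res = bayes_rank_bf10(x, y, iterations=3000, chains=3, seed=6)
        assert res.bf10 > 1.0

    def test_agrees_with_parametric_jzs_on_normal_data(self):
        # on normal data the latent-normal rank BF should track the JZS BF
        # of the underlying observations (information loss from ranks is small)
        ratios = []
        for seed in (2, 4, 9):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 48)
            y = rng.normal(0.45, 1, 48)
            t, _ = ttest_ind(x, y)
            parametric = jzs_bf10(abs(t), 48, 48)
            ranked = bayes_rank_bf10(x, y, iterations=6000, chains=4, seed=seed + 50)
            ratios.append(ranked.bf10 / parametric)
        geo = math.exp(np.mean(np.log(ratios)))
        assert 1 / 1.5 < geo < 1.5

    def test_low_iterations_warn(self, rng):
        with pytest.warns(UserWarning):
            bayes_rank_bf10(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                            iterations=500, chains=2, seed=1)


class TestQuadeAncova:
    def test_constant_covariate_reduces_to_rank_t_test(self, rng):
        dv = rng.normal(0, 1, 30)
        group = np.repeat([0, 1], 15)
        with pytest.warns(UserWarning):
            res = quade_ancova(dv, np.ones(30), group)
        ranks = rankdata(dv) - (len(dv) + 1) / 2
        t_ref, p_ref = ttest_ind(ranks[group == 0], ranks[group == 1])
        assert res.statistic == pytest.approx(t_ref)
        assert res.p_two_sided == pytest.approx(p_ref)
        assert res.slope == 0.0

    def test_residuals_centred(self, rng):
        dv = rng.normal(0, 1, 40)
        cov = dv * 0.5 + rng.normal(0, 1, 40)
        res = quade_ancova(dv, cov, np.repeat([0, 1], 20))
        assert abs(res.residuals.sum()) < 1e-8

    def test_covariate_confound_is_removed(self, rng):
        # group differs only through the covariate: adjusting must remove it
        n = 60
        group = np.repeat([0, 1], n // 2)
        cov = rng.normal(group * 2.0, 1.0)
        dv = cov + rng.normal(0, 0.1, n)
        raw_p = ttest_ind(dv[group == 0], dv[group == 1]).pvalue
        adj = quade_ancova(dv, cov, group)
        assert raw_p < 0.001
        assert adj.p_two_sided > raw_p

    def test_requires_two_groups(self, rng):
        with pytest.raises(ParameterDomainError):
            quade_ancova(rng.normal(0, 1, 9), rng.normal(0, 1, 9), np.zeros(9))


class TestPartialCorrelation:
    def test_identity(self, rng):
        a = rng.normal(0, 1, 30)
        c = rng.normal(0, 1, 30)
        r, p = partial_rank_correlation(a, a, c)
        assert r == pytest.approx(1.0)

    def test_confound_removed(self, rng):
        n = 200
        c = rng.normal(0, 1, n)
        a = c + rng.normal(0, 1, n)
        b = c + rng.normal(0, 1, n)
        raw = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        r, _ = partial_rank_correlation(a, b, c)
        assert raw > 0.3
        assert abs(r) < 0.2

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a = rng.normal(0, 1, 40)
        b = 0.5 * a + rng.normal(0, 1, 40)
        c = rng.normal(0, 1, 40)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        ref = pingouin.partial_corr(df, x="a", y="b", covar="c", method="spearman")
        r, p = partial_rank_correlation(a, b, c)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_too_few_observations(self):
        with pytest.raises(IncompleteInputError):
            partial_rank_correlation([1, 2], [3, 4], [5, 6])


class TestPowerAnalysis:
    def test_study_design_effect_size(self):
        # d = 0.747, alpha .05, 95% power, two-tailed
        assert required_n_two_sample(PowerSpec(0.747, 0.05, 0.95, 2)) == 48

    def test_monotone_in_effect_size(self):
        ns = [required_n_two_sample(PowerSpec(d, 0.05, 0.95, 2)) for d in (0.4, 0.747, 1.2)]
        assert ns[0] > ns[1] > ns[2]

    def test_matches_statsmodels_oracle(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        ref = smp.TTestIndPower().solve_power(effect_size=1.0, alpha=0.05, power=0.8)
        assert required_n_two_sample(PowerSpec(1.0, 0.05, 0.8, 2)) == math.ceil(ref)


class TestCatchCriterion:
    def test_study_cutoff(self):
        # 4+ errors of 15 is the first count not significantly above chance
        assert catch_exclusion_threshold(15, 0.5, 0.05) == 4

    def test_exact_binomial_boundary(self):
        # P(X >= 12) = 576/32768 < 0.05 <= P(X >= 11) = 1941/32768
        from scipy.stats import binom

        assert binom.sf(11, 15, 0.5) == pytest.approx(576 / 32768)
        assert binom.sf(10, 15, 0.5) == pytest.approx(1941 / 32768)

    def test_monotone_in_alpha(self):
        cuts = [catch_exclusion_threshold(15, 0.5, a) for a in (0.001, 0.05, 0.5)]
        assert cuts[0] <= cuts[1] <= cuts[2]

    def test_vanishing_chance_level_requires_total_failure(self):
        assert catch_exclusion_threshold(15, 1e-9, 0.05) == 15


class TestNormalityGate:
    def test_gaussian_passes(self, rng):
        gate = normality_gate(rng.normal(0, 1, 200))
        assert not gate.use_nonparametric

    def test_lognormal_rejected(self, rng):
        gate = normality_gate(rng.lognormal(0, 1, 48))
        assert gate.use_nonparametric
        assert gate.p < 0.05

    def test_sample_size_contract(self):
        with pytest.raises(IncompleteInputError):
            normality_gate([1.0, 2.0])


def test_bf_interpretation_bands():
    assert bf_label(0.1) == "supports null"
    assert bf_label(1.0) == "inconclusive"
    assert bf_label(5.0) == "supports alternative"
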