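"""Bootstrap estimation statistics, p-value machinery, agreement fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chemotax as ct
from chemotax.stats import rng_for


def bh_brute_force(pvals, fdr=0.05):
    """Step-up enumeration: largest k with p_(k) <= k/m * fdr; reject 1..k."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    sorted_p = np.asarray(pvals)[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * fdr:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestBootstrapMeanDifference:
    def test_identical_samples_center_on_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        eff = ct.bootstrap_mean_difference(x, x, n_resamples=2000, seed=1)
        assert eff.mean_difference == 0.0
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_point_estimate_is_exact_difference_of_means(self):
        t, c = np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0])
        eff = ct.bootstrap_mean_difference(t, c, seed=0)
        assert eff.mean_difference == 1.0  # not bootstrapped

    def test_ci_matches_independent_reimplementation(self):
        rng = np.random.default_rng(3)
        t, c = rng.normal(5, 2, 80), rng.normal(0, 2, 90)
        eff = ct.bootstrap_mean_difference(t, c, n_resamples=5000, seed=42, label="chk")
        # brute-force bootstrap following the documented seed protocol
        r = rng_for(42, "chk")
        it = r.integers(0, t.size, size=(5000, t.size))
        ic = r.integers(0, c.size, size=(5000, c.size))
        dist = t[it].mean(axis=1) - c[ic].mean(axis=1)
        lo, hi = np.percentile(dist, [2.5, 97.5])
        assert (eff.ci_low, eff.ci_high) == (pytest.approx(lo), pytest.approx(hi))

    def test_point_estimate_seed_independent(self):
        rng = np.random.default_rng(4)
        t, c = rng.normal(2, 1, 40), rng.normal(0, 1, 40)
        e1 = ct.bootstrap_mean_difference(t, c, seed=1, n_resamples=500)
        e2 = ct.bootstrap_mean_difference(t, c, seed=2, n_resamples=500)
        assert e1.mean_difference == e2.mean_difference
        assert (e1.ci_low, e1.ci_high) != (e2.ci_low, e2.ci_high)

    def test_bca_interval_available(self):
        rng = np.random.default_rng(5)
        t, c = rng.normal(3, 1, 50), rng.normal(0, 1, 50)
        eff = ct.bootstrap_mean_difference(t, c, n_resamples=1000, seed=1, method="bca")
        assert eff.ci_low < eff.mean_difference < eff.ci_high

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ct.bootstrap_mean_difference([], [1.0, 2.0])


class TestCiToPvalue:
    def test_symmetric_distribution_p_near_one(self):
        rng = np.random.default_rng(0)
        dist = rng.normal(0, 1, 5001)
        assert ct.ci_to_pvalue(dist) > 0.9

    def test_all_positive_floors_at_resolution(self):
        dist = np.abs(np.random.default_rng(1).normal(5, 1, 5000)) + 0.1
        assert ct.ci_to_pvalue(dist) == pytest.approx(2 / 5001)

    def test_needs_enough_resamples(self):
        with pytest.raises(ValueError):
            ct.ci_to_pvalue(np.ones(50))


class TestBenjaminiHochberg:
    def test_all_ones_rejects_nothing(self):
        recs = ct.benjamini_hochberg([1.0] * 5)
        assert not any(r.rejected for r in recs)

    def test_example_vector(self):
        p = [0.001, 0.01, 0.02, 0.03, 0.04]
        recs = ct.benjamini_hochberg(p, fdr=0.05)
        brute = bh_brute_force(p, 0.05)
        assert [r.rejected for r in recs] == list(brute)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_brute_force_step_up(self, p):
        recs = ct.benjamini_hochberg(p, fdr=0.05)
        assert [r.rejected for r in recs] == list(bh_brute_force(p, 0.05))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_adjusted_p_dominates_raw(self, p):
        for r in ct.benjamini_hochberg(p):
            assert r.adjusted_p >= r.raw_p - 1e-12

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.integers(1, 9))
    def test_raising_fdr_never_shrinks_rejections(self, p, tens):
        low = {i for i, r in enumerate(ct.benjamini_hochberg(p, fdr=0.01))
               if r.rejected}
        high = {i for i, r in enumerate(ct.benjamini_hochberg(p, fdr=0.01 + 0.01 * tens))
                if r.rejected}
        assert low <= high


class TestMannWhitney:
    def test_identical_samples_not_distinguished(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = ct.mann_whitney_u(x, x)
        assert p > 0.9

    def test_disjoint_small_samples_exact(self):
        u, p = ct.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)


class TestDeltaDelta:
    def test_identical_genotypes_give_zero(self):
        g = np.array([1.0, 3.0, 2.0, 4.0])
        dd = ct.delta_delta(g, g + 5, g, g + 5, n_resamples=500, seed=0)
        assert dd.delta_delta == 0.0

    def test_constructed_means(self):
        mk = lambda m: np.full(10, float(m))
        dd = ct.delta_delta(mk(0), mk(5), mk(1), mk(2), n_resamples=500, seed=0)
        assert (dd.delta1, dd.delta2, dd.delta_delta) == (-1.0, 3.0, -4.0)
        assert dd.abs_value == 4.0

    def test_identity_exact(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i, 1, 30) for i in range(4)]
        dd = ct.delta_delta(*groups, n_resamples=500, seed=3)
        assert dd.delta_delta == dd.delta1 - dd.delta2

    @given(st.floats(-50, 50))
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(11)
        groups = [rng.normal(i, 1, 20) for i in range(4)]
        base = ct.delta_delta(*groups, n_resamples=200, seed=5)
        moved = ct.delta_delta(*(g + shift for g in groups), n_resamples=200, seed=5)
        assert moved.delta_delta == pytest.approx(base.delta_delta, abs=1e-9)

    def test_strict_literal_mode_reproduces_printed_formula(self):
        mk = lambda m: np.full(10, float(m))
        dd = ct.delta_delta(mk(0), mk(5), mk(1), mk(2), n_resamples=500, seed=0,
                            strict_literal=True)
        assert dd.delta2 == 4.0  # mean(g1_test) - mean(g2_control)
        assert dd.delta_delta == -5.0


class TestAgreementStats:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        fit = ct.agreement_stats(x, x)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0)

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 50)
        y = 2 * x + rng.normal(0, 0.3, 50)
        fit = ct.agreement_stats(x, y)
        assert fit.slope == pytest.approx(2.0, abs=0.1)
        assert fit.r_squared == pytest.approx(fit.pearson_r**2)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            ct.agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
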