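"""MR estimators and sensitivity diagnostics."""

import numpy as np
import pytest
from scipy import stats

from conftest import hset
from mrpipe import mr_core
from mrpipe.mr_core import (egger, heterogeneity, ivw, radial_outliers,
                            wald_ratios, weighted_median, weighted_mode)


class TestWaldRatios:
    def test_single_division(self):
        r = wald_ratios(hset([0.5], [0.01], [0.1], [0.05]))
        assert r.b[0] == pytest.approx(0.2)
        assert r.s[0] == pytest.approx(0.1)

    def test_negative_exposure_effect_flips_sign(self):
        r = wald_ratios(hset([-0.5], [0.01], [0.1], [0.05]))
        assert r.b[0] == pytest.approx(-0.2)
        assert r.s[0] == pytest.approx(0.1)

    def test_zero_exposure_effect_dropped(self):
        r = wald_ratios(hset([0.0, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05]))
        assert r.dropped == [("rs1", "zero_exposure_effect")]
        assert r.snp_ids == ["rs2"]

    def test_all_dropped_errors(self):
        with pytest.raises(ValueError, match="no usable instruments"):
            wald_ratios(hset([0.0], [0.01], [0.1], [0.05]))


class TestIVW:
    def test_homogeneous_ratios(self):
        res = ivw(hset([1, 2, 4], [0.01] * 3, [0.2, 0.4, 0.8], [0.1] * 3))
        assert res.estimate == pytest.approx(0.2)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-20)
        assert res.re_scale == 1.0

    def test_hand_computed_example(self):
        res = ivw(hset([1, 1, 2], [0.1] * 3, [0.3, 0.1, 0.4], [0.1, 0.1, 0.2]))
        assert res.estimate == pytest.approx(0.2)
        assert res.cochran_q == pytest.approx(2.0)
        assert res.se / res.re_scale == pytest.approx(0.0577, abs=5e-5)
        assert res.q_df == 2

    def test_order_invariance(self, rng):
        bx, by = rng.normal(0.1, 0.02, 8), rng.normal(0.02, 0.01, 8)
        sy = rng.random(8) * 0.05 + 0.01
        a = ivw(hset(bx, [0.01] * 8, by, sy))
        perm = rng.permutation(8)
        b = ivw(hset(bx[perm], [0.01] * 8, by[perm], sy[perm]))
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(hset([1.0], [0.1], [0.2], [0.1]))

    def test_random_effects_never_deflates(self, rng):
        for _ in range(20):
            j = int(rng.integers(2, 12))
            res = ivw(hset(rng.normal(0.1, 0.03, j), [0.01] * j,
                           rng.normal(0.0, 0.1, j), rng.random(j) * 0.1 + 0.01))
            assert res.re_scale >= 1.0

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            j = int(rng.integers(2, 13))
            bx = rng.normal(0.1, 0.05, j)
            by = rng.normal(0.02, 0.05, j)
            sy = rng.random(j) * 0.1 + 0.01
            res = ivw(hset(bx, [0.01] * j, by, sy))
            fit = sm.WLS(by, bx[:, None], weights=sy ** -2).fit()
            assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)


class TestEgger:
    def test_exact_fit_through_origin(self):
        res = egger(hset([1, 2, 3], [0.01] * 3, [0.2, 0.4, 0.6], [0.1] * 3))
        assert res.estimate == pytest.approx(0.2)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_with_intercept(self):
        # all points on beta_out = 0.1 + 0.2 * beta_exp
        res = egger(hset([1, 2, 3], [0.01] * 3, [0.3, 0.5, 0.7], [0.1] * 3))
        assert res.estimate == pytest.approx(0.2)
        assert res.egger_intercept == pytest.approx(0.1)

    def test_orientation_invariance(self):
        a = egger(hset([1, 2, 3], [0.01] * 3, [0.35, 0.5, 0.64], [0.1] * 3))
        b = egger(hset([1, -2, 3], [0.01] * 3, [0.35, -0.5, 0.64], [0.1] * 3))
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)

    def test_too_few_snps(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(hset([1, 2], [0.01] * 2, [0.2, 0.4], [0.1] * 2))

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            j = int(rng.integers(3, 13))
            bx = np.abs(rng.normal(0.1, 0.05, j))
            by = rng.normal(0.02, 0.05, j)
            sy = rng.random(j) * 0.1 + 0.01
            res = egger(hset(bx, [0.01] * j, by, sy))
            fit = sm.WLS(by, sm.add_constant(bx), weights=sy ** -2).fit()
            assert res.estimate == pytest.approx(fit.params[1], rel=1e-10)
            assert res.egger_intercept == pytest.approx(fit.params[0], rel=1e-9)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        res = weighted_median(hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3],
                                   [0.1] * 3), n_boot=50, seed=1)
        assert res.estimate == pytest.approx(0.2)

    def test_two_snps_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            weighted_median(hset([1, 1], [0.01] * 2, [0.1, 0.3], [0.1] * 2))

    def test_unequal_weights_match_interp_oracle(self):
        # weights 0.7/0.2/0.1 on ratios 0.1/0.2/0.3 (se_out tuned to weights)
        w = np.array([0.7, 0.2, 0.1])
        sy = w ** -0.5
        res = weighted_median(hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], sy),
                              n_boot=50, seed=1)
        wn = w / w.sum()
        s = np.cumsum(wn) - wn / 2
        expected = np.interp(0.5, s, [0.1, 0.2, 0.3])
        assert res.estimate == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_reproducible(self):
        h = hset([1, 1, 1, 1], [0.05] * 4, [0.1, 0.2, 0.25, 0.3], [0.1] * 4)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se > 0


class TestWeightedMode:
    def test_point_mass(self):
        res = weighted_mode(hset([1, 2, 4], [0.01] * 3, [0.2, 0.4, 0.8],
                                 [0.1] * 3), n_boot=10, seed=1)
        assert res.estimate == pytest.approx(0.2)
        assert res.se == 0.0

    def test_cluster_beats_outlier(self):
        res = weighted_mode(hset([1] * 4, [0.01] * 4,
                                 [0.19, 0.20, 0.21, 1.0], [0.1] * 4),
                            n_boot=10, seed=1)
        assert 0.19 <= res.estimate <= 0.21
        # independent dense-grid density oracle
        b = np.array([0.19, 0.20, 0.21, 1.0])
        h = mr_core._mode_bandwidth(b, 1.0)
        grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 50_001)
        dens = np.exp(-0.5 * ((grid[:, None] - b) / h) ** 2).sum(axis=1)
        assert res.estimate == pytest.approx(grid[np.argmax(dens)], abs=2e-3)

    def test_symmetric_tie_takes_smaller_mode(self):
        res = weighted_mode(hset([1] * 4, [0.01] * 4, [0.1, 0.1, 0.3, 0.3],
                                 [0.1] * 4), n_boot=10, seed=1)
        # overlapping kernels pull both peaks slightly inward; the rule is
        # that the smaller of the two tied modes is returned
        assert res.estimate == pytest.approx(0.1, abs=0.02)
        assert res.estimate < 0.2


class TestHeterogeneity:
    def test_identical_ratios(self):
        q, q_p, i2, _ = heterogeneity(hset([1, 2], [0.01] * 2, [0.2, 0.4],
                                           [0.1] * 2))
        assert q == pytest.approx(0.0, abs=1e-20) and i2 == 0.0

    def test_hand_computed(self):
        q, q_p, i2, _ = heterogeneity(hset([1, 1, 2], [0.1] * 3,
                                           [0.3, 0.1, 0.4], [0.1, 0.1, 0.2]))
        assert q == pytest.approx(2.0)
        assert i2 == 0.0  # Q <= df
        assert q_p == pytest.approx(stats.chi2.sf(2.0, 2), rel=1e-12)

    def test_i2_formula_at_q_ten(self):
        # same configuration with 5x weights scales Q to 10 with df 2
        s5 = 0.1 / np.sqrt(5)
        q, _, i2, _ = heterogeneity(hset([1, 1, 2], [0.1] * 3,
                                         [0.3, 0.1, 0.4], [s5, s5, 2 * s5]))
        assert q == pytest.approx(10.0)
        assert i2 == pytest.approx(0.8)


class TestRadial:
    def test_homogeneous_no_outliers(self):
        res = radial_outliers(hset([1, 2, 4], [0.01] * 3, [0.2, 0.4, 0.8],
                                   [0.1] * 3))
        assert res.outliers == []

    def test_single_gross_outlier_flagged(self):
        bx = [1.0] * 10
        by = [0.2] * 9 + [2.0]
        sy = [0.3] * 10
        res = radial_outliers(hset(bx, [0.01] * 10, by, sy))
        assert res.outliers == ["rs10"]
        # per-SNP chi-square oracle
        theta = ivw(hset(bx, [0.01] * 10, by, sy)).estimate
        qj = (np.array(by) / np.array(bx) - theta) ** 2 / np.array(sy) ** 2
        pj = stats.chi2.sf(qj, 1)
        assert np.allclose(res.q_pvals, pj)

    def test_alpha_zero_never_flags(self):
        res = radial_outliers(hset([1.0] * 5, [0.01] * 5,
                                   [0.1, 0.2, 0.9, 0.2, 0.1], [0.05] * 5),
                              alpha=0.0)
        assert res.outliers == []

    def test_contributions_sum_to_total_q(self, rng):
        j = 12
        h = hset(rng.normal(0.1, 0.02, j), [0.01] * j,
                 rng.normal(0.02, 0.05, j), rng.random(j) * 0.1 + 0.01)
        res = radial_outliers(h)
        assert res.q_contributions.sum() == pytest.approx(res.total_q, rel=1e-12)
        q, *_ = heterogeneity(h)
        assert res.total_q == pytest.approx(q, rel=1e-12)

    def test_iteration_removes_sequentially(self):
        # rs12 is flagged on the first pass; only once it is gone does rs11
        # stand out against the tightened fit
        bx = [1.0] * 12
        by = [0.2] * 10 + [0.9, 3.0]
        sy = [0.3] * 12
        single = radial_outliers(hset(bx, [0.01] * 12, by, sy))
        assert single.outliers == ["rs12"]
        res = radial_outliers(hset(bx, [0.01] * 12, by, sy), iterate=True)
        assert set(res.outliers) == {"rs11", "rs12"}
        assert res.iterations > 1


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(st.tuples(
    st.floats(-5, 5), st.floats(0.01, 2)), min_size=3, max_size=12))
def test_weighted_median_bounded_and_weight_invariant(pairs):
    """The weighted median always lies inside the range of the ratios and
    is invariant to rescaling all weights."""
    b = np.array([p[0] for p in pairs])
    w = np.array([p[1] for p in pairs])
    est = mr_core._weighted_median_1d(b, w)
    assert b.min() - 1e-12 <= est <= b.max() + 1e-12
    assert mr_core._weighted_median_1d(b, 10 * w) == pytest.approx(
        est, rel=1e-12, abs=1e-12)


def test_scale_equivariance(rng):
    """Multiplying outcome betas and SEs by c scales every estimate by c."""
    j, c = 10, 3.7
    bx = rng.normal(0.1, 0.02, j)
    by = rng.normal(0.02, 0.03, j)
    sy = rng.random(j) * 0.05 + 0.01
    sx = [0.01] * j
    base = hset(bx, sx, by, sy)
    scaled = hset(bx, sx, by * c, sy * c)
    for fn, kw in [(ivw, {}), (egger, {}),
                   (weighted_median, {"n_boot": 100, "seed": 3}),
                   (weighted_mode, {"n_boot": 50, "seed": 3})]:
        a, b = fn(base, **kw), fn(scaled, **kw)
        assert b.estimate == pytest.approx(c * a.estimate, rel=1e-9)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)
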