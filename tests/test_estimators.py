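"""Causal estimators against hand computations and independent oracles.

The oracles are deliberately naive: normal equations assembled from the
weighted design for IVW/Egger, and an explicit cumulative-weight step
function for the weighted median.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from mrkit import estimators as est
from mrkit.estimators import (
    IVWEstimator,
    MREggerEstimator,
    WeightedMedianEstimator,
)

from .conftest import make_pair, random_pairs


# ---------------------------------------------------------------------------
# independent oracles


def ivw_oracle(bx, by, sy):
    """Weighted regression through the origin by explicit normal equations."""
    w = 1.0 / np.asarray(sy) ** 2
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def egger_oracle(bx, by, sy):
    """Weighted regression with intercept via the 2x2 normal equations,
    after the gamma > 0 recoding."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    s = np.sign(bx)
    s[s == 0] = 1
    x, y = np.abs(bx), by * s
    w = 1.0 / np.asarray(sy) ** 2
    A = np.array([[np.sum(w), np.sum(w * x)], [np.sum(w * x), np.sum(w * x * x)]])
    b = np.array([np.sum(w * y), np.sum(w * x * y)])
    intercept, slope = np.linalg.solve(A, b)
    return float(slope), float(intercept)


def weighted_median_oracle(ratios, weights):
    """50% crossing of the exhaustive cumulative-weight step function with
    linear interpolation between midpoints."""
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    mid = np.cumsum(w) - w / 2
    if 0.5 <= mid[0]:
        return float(r[0])
    if 0.5 >= mid[-1]:
        return float(r[-1])
    j = int(np.searchsorted(mid, 0.5))
    frac = (0.5 - mid[j - 1]) / (mid[j] - mid[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


# ---------------------------------------------------------------------------


class TestWaldRatio:
    def test_direct_division(self):
        p = make_pair(0.1, 0.05, 0.02)
        out = est.wald_ratio(p)
        assert out.beta == pytest.approx(0.5)
        assert out.se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        out = est.wald_ratio(make_pair(0.1, 0.0, 0.02))
        assert out.beta == 0.0 and out.pval == 1.0

    def test_negative_effect_with_ci(self):
        out = est.wald_ratio(make_pair(0.2, -0.05, 0.01))
        assert out.beta == pytest.approx(-0.25)
        assert out.se == pytest.approx(0.05)
        assert out.ci_low == pytest.approx(-0.348)
        assert out.ci_high == pytest.approx(-0.152)

    def test_degenerate_instrument(self):
        with pytest.raises(ValueError, match="degenerate"):
            est.wald_ratio(make_pair(0.0, 0.1, 0.02))


class TestIVW:
    def test_two_pair_closed_form(self):
        pairs = [make_pair(1.0, 0.5, 1.0), make_pair(1.0, 1.0, 1.0)]
        assert est.ivw(pairs).beta == pytest.approx(0.75)

    def test_homogeneous_ratios(self):
        pairs = [make_pair(b, 0.3 * b, 0.02) for b in (0.1, 0.2, 0.3)]
        fixed = est.ivw(pairs, "fixed")
        random = est.ivw(pairs, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.3)
        assert random.beta == pytest.approx(0.3)
        # weights differ across pairs so Q > 0 is possible; here ratios are
        # exactly equal, Q = 0 and the two SEs coincide
        assert fixed.se == pytest.approx(random.se)

    def test_single_pair_reduces_to_wald_ratio(self):
        pair = make_pair(0.1, 0.05, 0.02)
        ivw_est = est.ivw([pair])
        wald = est.wald_ratio(pair)
        assert ivw_est.beta == pytest.approx(wald.beta)
        assert ivw_est.se == pytest.approx(wald.se)

    def test_equal_weights_equal_unweighted_slope(self, rng):
        """IVW with constant se equals sum(xy)/sum(x^2) to 1e-10."""
        for _ in range(20):
            n = int(rng.integers(5, 21))
            bx = rng.uniform(-0.5, 0.5, n)
            by = rng.normal(0.2 * bx, 0.05)
            pairs = [make_pair(bx[i], by[i], 0.03) for i in range(n)]
            expected = float(np.sum(bx * by) / np.sum(bx * bx))
            assert est.ivw(pairs).beta == pytest.approx(expected, abs=1e-10)

    def test_multiplicative_random_scaling_matches_q(self, rng):
        """SE_random = SE_fixed * sqrt(Q/df) whenever Q/df > 1."""
        bx = rng.uniform(0.1, 0.5, 10)
        by = rng.normal(0.2 * bx, 0.2)  # strongly heterogeneous
        pairs = [make_pair(bx[i], by[i], 0.01) for i in range(10)]
        fixed = est.ivw(pairs, "fixed")
        random = est.ivw(pairs, "multiplicative_random")
        q, df, _ = est.cochran_q(pairs, fixed.beta)
        assert q / df > 1
        assert random.se == pytest.approx(fixed.se * np.sqrt(q / df))


class TestMREgger:
    def test_exact_linear_data(self):
        pairs = [make_pair(g, 0.03 + 0.4 * g, 0.02) for g in (0.1, 0.2, 0.3, 0.4)]
        slope, icpt, icpt_se, icpt_p = est.mr_egger(pairs)
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert icpt == pytest.approx(0.03, abs=1e-12)

    def test_origin_data_matches_ivw(self):
        """With a truly zero intercept and equal weights, the Egger slope
        equals the IVW slope."""
        pairs = [make_pair(g, 0.25 * g, 0.02) for g in (0.1, 0.2, 0.3, 0.5)]
        slope, icpt, *_ = est.mr_egger(pairs)
        assert icpt == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(est.ivw(pairs).beta, abs=1e-10)

    def test_two_pairs_insufficient(self):
        with pytest.raises(ValueError, match="3"):
            est.mr_egger([make_pair(0.1, 0.05, 0.02), make_pair(0.2, 0.1, 0.02)])

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng, int(rng.integers(5, 21)))
            bx = np.array([p.beta_exp for p in pairs])
            by = np.array([p.beta_out for p in pairs])
            sy = np.array([p.se_out for p in pairs])
            slope, icpt, *_ = est.mr_egger(pairs)
            o_slope, o_icpt = egger_oracle(bx, by, sy)
            assert slope.beta == pytest.approx(o_slope, abs=1e-10)
            assert icpt == pytest.approx(o_icpt, abs=1e-10)

    def test_intercept_p_uses_t_distribution(self):
        pairs = [make_pair(g, 0.05 + 0.4 * g + e, 0.02) for g, e in
                 [(0.1, 0.001), (0.2, -0.002), (0.3, 0.002), (0.4, -0.001), (0.5, 0.0)]]
        _, icpt, icpt_se, icpt_p = est.mr_egger(pairs)
        expected = 2 * stats.t.sf(abs(icpt / icpt_se), len(pairs) - 2)
        assert icpt_p == pytest.approx(expected)


class TestWeightedMedian:
    def test_middle_mass_point(self):
        pairs = [make_pair(1.0, r, 1.0) for r in (0.1, 0.5, 0.9)]
        assert est.weighted_median(pairs, n_boot=10, seed=0).beta == pytest.approx(0.5)

    def test_all_ratios_equal(self):
        pairs = [make_pair(b, 0.4 * b, 0.02) for b in (0.1, 0.2, 0.3, 0.4)]
        out = est.weighted_median(pairs, n_boot=500, seed=0)
        assert out.beta == pytest.approx(0.4)

    def test_symmetric_crossing_interpolates_midpoint(self):
        # ratios 0,1,2,3 with weights .4,.1,.1,.4: cumulative midpoints
        # .2,.45,.55,.8 -> the 0.5 crossing interpolates to 1.5
        w = [0.4, 0.1, 0.1, 0.4]
        ratios = [0.0, 1.0, 2.0, 3.0]
        se_y = [np.sqrt(1 / wi) for wi in w]  # x=1 -> weight = 1/se^2
        pairs = [make_pair(1.0, r, s) for r, s in zip(ratios, se_y)]
        out = est.weighted_median(pairs, n_boot=10, seed=0)
        assert out.beta == pytest.approx(1.5)
        assert weighted_median_oracle(ratios, w) == pytest.approx(1.5)

    def test_matches_crossing_oracle(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng, int(rng.integers(5, 21)))
            bx = np.array([p.beta_exp for p in pairs])
            by = np.array([p.beta_out for p in pairs])
            sy = np.array([p.se_out for p in pairs])
            out = est.weighted_median(pairs, n_boot=2, seed=0)
            oracle = weighted_median_oracle(by / bx, bx**2 / sy**2)
            assert out.beta == pytest.approx(oracle, abs=1e-14)

    def test_bootstrap_se_is_seeded(self):
        pairs = [make_pair(b, 0.4 * b + d, 0.02) for b, d in
                 [(0.1, 0.01), (0.2, -0.01), (0.3, 0.02), (0.4, 0.0)]]
        a = est.weighted_median(pairs, n_boot=200, seed=42)
        b = est.weighted_median(pairs, n_boot=200, seed=42)
        assert a.se == b.se


class TestCochranQ:
    def test_homogeneous(self):
        pairs = [make_pair(b, 0.3 * b, 0.02) for b in (0.1, 0.2, 0.3)]
        q, df, p = est.cochran_q(pairs, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_hand_computation(self):
        # two pairs with unit weights (x=1, se=1), ratios 0 and 1, ref 0.5:
        # Q = 1*(0-.5)^2 + 1*(1-.5)^2 = 0.5, df = 1
        pairs = [make_pair(1.0, 0.0, 1.0), make_pair(1.0, 1.0, 1.0)]
        q, df, p = est.cochran_q(pairs, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.5, 1))

    def test_relabeling_invariance(self, rng):
        pairs = random_pairs(rng, 8)
        q1, *_ = est.cochran_q(pairs, 0.1)
        q2, *_ = est.cochran_q(pairs[::-1], 0.1)
        assert q1 == pytest.approx(q2)


class TestLeaveOneOut:
    def test_homogeneous_pairs_not_flagged(self):
        pairs = [make_pair(b, 0.3 * b, 0.02) for b in (0.1, 0.15, 0.2, 0.25, 0.3)]
        table, flag = est.leave_one_out(pairs)
        assert len(table) == 5
        assert not flag
        assert np.allclose(table["beta"], 0.3)

    def test_dominant_outlier_flips_sign(self):
        # four small positive-ratio pairs plus one high-precision strongly
        # negative pair that dominates the pooled slope
        pairs = [make_pair(0.1, 0.01, 0.5, variant_id=f"rs{i}") for i in range(4)]
        pairs.append(make_pair(0.5, -0.4, 0.001, variant_id="outlier"))
        full = est.ivw(pairs)
        table, flag = est.leave_one_out(pairs)
        assert full.beta < 0
        assert flag
        row = table[table["excluded_variant"] == "outlier"].iloc[0]
        assert row["beta"] > 0 and row["influential"]

    def test_row_count_equals_n_snp(self, rng):
        pairs = random_pairs(rng, 7)
        table, _ = est.leave_one_out(pairs)
        assert len(table) == 7


class TestToOddsRatio:
    def test_null_effect(self):
        or_, lo, hi = est.to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_reconstructs_protective_il18_scale_row(self):
        """A log-OR of -0.3481 with SE reconstructed from a printed 95% CI
        (0.538, 0.925) reproduces OR 0.706 and its bounds."""
        se = (np.log(0.925) - np.log(0.538)) / 3.92
        or_, lo, hi = est.to_odds_ratio(-0.3481, se)
        assert or_ == pytest.approx(0.706, abs=0.001)
        assert lo == pytest.approx(0.538, abs=0.002)
        assert hi == pytest.approx(0.925, abs=0.002)

    def test_multiplicative_symmetry(self):
        or_, lo, hi = est.to_odds_ratio(0.3, 0.12)
        assert hi / or_ == pytest.approx(or_ / lo)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            est.to_odds_ratio(0.1, -0.5)


class TestEquivariance:
    def test_negating_outcome_negates_estimates_and_fixes_ses(self, rng):
        pairs = random_pairs(rng, 12)
        neg = [
            make_pair(p.beta_exp, -p.beta_out, p.se_out, p.se_exp, p.variant_id)
            for p in pairs
        ]
        for method in (est.ivw, lambda ps: est.mr_egger(ps)[0]):
            a = method(pairs)
            b = method(neg)
            assert b.beta == pytest.approx(-a.beta, abs=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        # weighted median: the point estimate is exactly equivariant; its
        # bootstrap SE is equivariant in distribution (finite replicates
        # use different noise draws), so it is compared statistically
        a = est.weighted_median(pairs, n_boot=400, seed=3)
        b = est.weighted_median(neg, n_boot=400, seed=3)
        assert b.beta == pytest.approx(-a.beta, abs=1e-12)
        assert b.se == pytest.approx(a.se, rel=0.25)


class TestSklearnInterface:
    """The estimators follow the scikit-learn contract."""

    @pytest.mark.parametrize(
        "estimator",
        [IVWEstimator(), MREggerEstimator(), WeightedMedianEstimator(n_boot=20)],
    )
    def test_get_set_params_and_clone(self, estimator):
        params = estimator.get_params()
        cloned = clone(estimator)
        assert cloned.get_params() == params
        estimator.set_params(**params)

    def test_fitted_attributes_and_predict(self, rng):
        bx = rng.uniform(0.1, 0.5, 10)
        by = 0.3 * bx + rng.normal(0, 0.01, 10)
        sy = np.full(10, 0.02)
        model = IVWEstimator().fit(bx, by, sy)
        assert hasattr(model, "beta_") and hasattr(model, "q_pval_")
        pred = model.predict(np.array([0.0, 1.0]))
        assert pred[0] == 0.0
        assert pred[1] == pytest.approx(model.beta_)
        egger = MREggerEstimator().fit(bx, by, sy)
        assert egger.predict(np.array([0.0]))[0] == pytest.approx(egger.intercept_)

    def test_column_vector_input_accepted(self, rng):
        bx = rng.uniform(0.1, 0.5, 8)
        by = 0.3 * bx
        sy = np.full(8, 0.02)
        flat = IVWEstimator().fit(bx, by, sy).beta_
        col = IVWEstimator().fit(bx.reshape(-1, 1), by, sy).beta_
        assert flat == col

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            IVWEstimator().fit([0.1, 0.2], [0.1, 0.2], [0.01, -0.01])
        with pytest.raises(ValueError, match="shape"):
            IVWEstimator().fit([0.1, 0.2], [0.1], [0.01])
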