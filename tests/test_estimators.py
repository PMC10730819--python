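"""Univariable MR estimators against closed-form values and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from mrkit.errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from mrkit.estimators import (
    _weighted_median_point,
    _wls,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrkit.simulate import MediatorChain, Pleiotropy, SimConfig, simulate
from mrkit.summary_io import harmonize

from conftest import make_harmonized


class TestWaldRatio:
    def test_arithmetic(self):
        e = wald_ratio(0.05, 0.01, 0.10)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)

    def test_null_outcome(self):
        assert wald_ratio(0.0, 0.01, 0.10).beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.05, 0.01, 0.0)

    def test_first_order_se_close_to_second_order_when_strong(self):
        # strong instrument: F = (0.3/0.02)^2 = 225 > 100
        beta_exp, se_exp, beta_out, se_out = 0.3, 0.02, 0.1, 0.05
        first = wald_ratio(beta_out, se_out, beta_exp).se
        second = np.sqrt(
            se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        )
        assert abs(first - second) / second < 0.05


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.10], 0.01, [0.05], 0.01)
        w = wald_ratio(0.05, 0.01, 0.10)
        e = ivw(h)
        assert e.beta == pytest.approx(w.beta)
        assert e.se == pytest.approx(w.se)

    def test_equal_weight_ratios_average(self):
        h = make_harmonized([1.0, 1.0], 0.01, [0.4, 0.6], 1.0)
        assert ivw(h, mode="fixed").beta == pytest.approx(0.5)

    def test_matches_statsmodels_wls_through_origin(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.2, 0.05, 20)
        y = 0.3 * x + rng.normal(0, 0.05, 20)
        se = rng.uniform(0.03, 0.08, 20)
        h = make_harmonized(x, 0.01, y, se)
        fit = sm.WLS(y, x, weights=1 / se**2).fit()
        assert ivw(h, mode="fixed").beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_invariant_to_order_and_joint_sign_flip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.2, 0.05, 15)
        y = 0.3 * x + rng.normal(0, 0.05, 15)
        se = rng.uniform(0.03, 0.08, 15)
        base = ivw(make_harmonized(x, 0.01, y, se)).beta
        perm = rng.permutation(15)
        assert ivw(make_harmonized(x[perm], 0.01, y[perm], se[perm])).beta == pytest.approx(base)
        flip = rng.choice([-1.0, 1.0], 15)
        assert ivw(make_harmonized(x * flip, 0.01, y * flip, se)).beta == pytest.approx(base)

    def test_fixed_se_never_exceeds_mre_se(self):
        rng = np.random.default_rng(2)
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(0.2, 0.05, 10)
            y = 0.3 * x + r.normal(0, 0.1, 10)
            h = make_harmonized(x, 0.01, y, 0.05)
            assert ivw(h, mode="fixed").se <= ivw(h, mode="mre").se + 1e-15

    def test_degenerate_exposure_rejected(self):
        h = make_harmonized([0.0, 0.0], 0.01, [0.1, 0.2], 0.05)
        with pytest.raises(DegenerateInstrumentError):
            ivw(h)


def _grid_scan_median(ratios, weights, n_grid=2_000_001):
    """Brute-force oracle: locate the 0.5 crossing of the piecewise-linear
    weighted CDF by scanning its knots one by one."""
    order = np.argsort(ratios)
    b = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return b[0]
    if 0.5 >= cum[-1]:
        return b[-1]
    for k in range(len(b) - 1):
        if cum[k] <= 0.5 <= cum[k + 1]:
            # solve the linear segment exactly
            t = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
            return b[k] * (1 - t) + b[k + 1] * t
    raise AssertionError("no crossing found")


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], 0.01, [0.1, 0.5, 0.9], 1.0)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_point_estimate_matches_grid_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.normal(0.3, 0.2, 5)
        weights = rng.uniform(0.5, 3.0, 5)
        assert _weighted_median_point(ratios, weights) == pytest.approx(
            _grid_scan_median(ratios, weights), abs=1e-8
        )

    def test_within_ratio_range(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, 0.05, 9)
        y = rng.normal(0.05, 0.03, 9)
        h = make_harmonized(x, 0.01, y, 0.05)
        est = weighted_median(h, n_boot=100, seed=1).beta
        ratios = y / x
        assert ratios.min() <= est <= ratios.max()

    def test_requires_three_snps(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.1], 0.05)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, seed=0)

    def test_bootstrap_se_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.2, 0.05, 10)
        y = 0.3 * x + rng.normal(0, 0.05, 10)
        h = make_harmonized(x, 0.01, y, 0.05)
        a = weighted_median(h, n_boot=200, seed=11)
        b = weighted_median(h, n_boot=200, seed=11)
        assert a == b


class TestEgger:
    def test_recovers_constant_pleiotropy_and_slope(self):
        cfg = SimConfig(
            seed=17, J=100, theta=0.2,
            pleiotropy=Pleiotropy(mode="directional", magnitude=0.05),
        )
        sim = simulate(cfg)
        h = harmonize(sim.exposure, sim.outcome)
        res = mr_egger(h)
        assert abs(res.intercept - 0.05) < 2 * res.intercept_se
        assert abs(res.slope.beta - 0.2) < 2 * res.slope.se

    def test_matches_statsmodels_wls_with_intercept(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(0.2, 0.05, 30))
        y = 0.02 + 0.3 * x + rng.normal(0, 0.05, 30)
        se = rng.uniform(0.03, 0.08, 30)
        h = make_harmonized(x, 0.01, y, se)
        res = mr_egger(h)
        fit = sm.WLS(y, sm.add_constant(x), weights=1 / se**2).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], rel=1e-10)

    def test_intercept_coverage_under_no_pleiotropy(self):
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            sim = simulate(SimConfig(seed=seed, J=50, theta=0.2))
            h = harmonize(sim.exposure, sim.outcome)
            res = mr_egger(h)
            hits += abs(res.intercept) < 2 * res.intercept_se
        assert hits / n_rep >= 0.93

    def test_no_intercept_fit_reproduces_ivw(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.2, 0.05, 12)
        y = 0.3 * x + rng.normal(0, 0.05, 12)
        se = rng.uniform(0.03, 0.08, 12)
        h = make_harmonized(x, 0.01, y, se)
        coefs, _, _, _ = _wls(x, y, 1 / se**2, intercept=False)
        assert ivw(h, mode="fixed").beta == pytest.approx(coefs[0], rel=1e-12)

    def test_zero_exposure_variance_is_collinearity_error(self):
        h = make_harmonized([0.2, 0.2, 0.2, 0.2], 0.01, [0.1, 0.12, 0.08, 0.11], 0.05)
        with pytest.raises(CollinearityError):
            mr_egger(h)

    def test_requires_three_snps(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.1], 0.05)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)


class TestOddsRatio:
    def test_null_effect(self):
        orv, lo, hi = to_odds_ratio(0.0, 0.1)
        assert orv == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_log2_effect(self):
        orv, lo, hi = to_odds_ratio(np.log(2), 1e-12)
        assert orv == pytest.approx(2.0)
        assert lo == pytest.approx(2.0, rel=1e-6)

    @given(beta=st.floats(-3, 3, allow_nan=False), se=st.floats(1e-6, 1))
    def test_log_roundtrip(self, beta, se):
        orv, _, _ = to_odds_ratio(beta, se)
        assert np.log(orv) == pytest.approx(beta, abs=1e-12)
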