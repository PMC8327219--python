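"""Wald ratios and the three combined MR estimators."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr import (
    EggerRegression,
    HarmonizedPair,
    IVWEstimator,
    ValidationError,
    WaldRatio,
    WeightedMedianEstimator,
    egger,
    ivw,
    pairs_to_frame,
    wald_ratio,
    wald_ratios,
    weighted_median,
)


def make_pair(snp="rs1", beta_exp=0.1, beta_out=0.02, se_out=0.01,
              se_exp=0.002, gene=None):
    return HarmonizedPair(snp=snp, effect_allele="A", other_allele="G",
                          beta_exp=beta_exp, se_exp=se_exp, eaf_exp=0.3,
                          beta_out=beta_out, se_out=se_out, eaf_out=0.3,
                          gene=gene)


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_arithmetic():
    r = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.02, se_out=0.01))
    assert r.ratio == pytest.approx(0.2)
    assert r.se_ratio == pytest.approx(0.1)
    assert r.weight == pytest.approx(100.0)


def test_wald_ratio_zero_outcome_and_sign_invariance():
    assert wald_ratio(make_pair(beta_out=0.0)).ratio == 0.0
    a = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.02))
    b = wald_ratio(make_pair(beta_exp=-0.1, beta_out=-0.02))
    assert a.ratio == b.ratio and a.se_ratio == b.se_ratio


def test_wald_ratio_zero_exposure_errors():
    with pytest.raises(ValidationError, match="undefined ratio"):
        wald_ratio(make_pair(beta_exp=0.0))


# ---------------------------------------------------------------------------
# IVW


def test_ivw_two_ratio_oracle():
    """Closed-form weighted mean: {0.2 w=100, 0.05 w=100} -> 0.125, fixed
    SE sqrt(1/200)."""
    ratios = [WaldRatio("rs1", 0.2, 0.1, 100.0), WaldRatio("rs2", 0.05, 0.1, 100.0)]
    res = ivw(ratios, variant="fixed")
    assert res.beta_xy == pytest.approx(0.125)
    assert res.se == pytest.approx(math.sqrt(1 / 200), rel=1e-12)
    assert res.n_snps == 2


def test_ivw_constant_ratios_underdispersion_floors_to_fixed():
    ratios = [WaldRatio(f"rs{i}", 0.3, 0.1, 100.0) for i in range(5)]
    fe = ivw(ratios, variant="fixed")
    mre = ivw(ratios, variant="multiplicative-re")
    assert mre.beta_xy == fe.beta_xy == pytest.approx(0.3)
    assert mre.se == fe.se  # s = 0 <= 1, floor keeps the fixed SE


def test_ivw_point_estimate_variant_independent():
    rng = np.random.default_rng(7)
    ratios = [WaldRatio(f"rs{i}", rng.normal(), s, 1 / s**2)
              for i, s in enumerate(rng.uniform(0.05, 0.5, 20))]
    assert ivw(ratios, "fixed").beta_xy == pytest.approx(
        ivw(ratios, "multiplicative-re").beta_xy, rel=1e-14)


def test_ivw_empty_errors_and_single_ratio_falls_back(caplog):
    with pytest.raises(ValidationError):
        ivw([])
    with caplog.at_level(logging.WARNING, logger="tsmr.estimators"):
        res = ivw([WaldRatio("rs1", 0.2, 0.1, 100.0)], "multiplicative-re")
    assert res.se == pytest.approx(0.1)
    assert "falling back" in caplog.text


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_ivw_equals_weighted_through_origin_regression(seed):
    """Algebraic identity vs an independent normal-equations / WLS oracle."""
    rng = np.random.default_rng(seed)
    j = rng.integers(2, 40)
    be = rng.uniform(0.01, 0.2, j) * rng.choice([-1, 1], j)
    bo = rng.normal(0.0, 0.05, j)
    seo = rng.uniform(0.005, 0.1, j)
    est = IVWEstimator().fit(pd.DataFrame(
        {"beta_exp": be, "beta_out": bo, "se_out": seo}))
    # oracle 1: explicit normal equations of the weighted through-origin fit
    w = 1.0 / seo**2
    oracle = np.sum(w * be * bo) / np.sum(w * be**2)
    assert est.estimate_ == pytest.approx(oracle, abs=1e-10)
    # oracle 2: statsmodels WLS without intercept
    wls = sm.WLS(bo, be, weights=w).fit()
    assert est.estimate_ == pytest.approx(wls.params[0], abs=1e-10)


def test_ivw_fixture_estimate(primary_pairs):
    res = ivw(wald_ratios(primary_pairs))
    assert res.n_snps == 79
    assert math.exp(res.beta_xy) == pytest.approx(1.06, abs=0.02)


# ---------------------------------------------------------------------------
# Weighted median


def test_weighted_median_breakpoint_rule():
    """Equal weights {1, 2, 10}: the middle ratio's breakpoint is exactly
    0.5, so the estimate is 2 with no interpolation."""
    ratios = [WaldRatio("a", 1.0, 1.0, 1.0), WaldRatio("b", 2.0, 1.0, 1.0),
              WaldRatio("c", 10.0, 1.0, 1.0)]
    res = weighted_median(ratios, reps=50, seed=1)
    assert res.beta_xy == pytest.approx(2.0)


def test_weighted_median_identical_ratios():
    ratios = [WaldRatio(f"rs{i}", 0.7, 0.1, 100.0) for i in range(5)]
    res = weighted_median(ratios, reps=200, seed=3)
    assert res.beta_xy == pytest.approx(0.7)
    # bootstrap spread reflects only the sampling SD of a median of draws
    assert 0.0 < res.se < 0.1


def test_weighted_median_dominant_weight_returns_that_ratio():
    ratios = [WaldRatio("a", -1.0, 1.0, 1e-6), WaldRatio("b", 0.42, 0.001, 1e6),
              WaldRatio("c", 3.0, 1.0, 1e-6), WaldRatio("d", 5.0, 1.0, 1e-6)]
    res = weighted_median(ratios, reps=10, seed=0)
    assert res.beta_xy == pytest.approx(0.42, abs=1e-6)


def test_weighted_median_bootstrap_seeded_reproducible():
    rng = np.random.default_rng(11)
    ratios = [WaldRatio(f"rs{i}", r, 0.2, 25.0)
              for i, r in enumerate(rng.normal(0, 1, 12))]
    a = weighted_median(ratios, reps=300, seed=5)
    b = weighted_median(ratios, reps=300, seed=5)
    c = weighted_median(ratios, reps=300, seed=6)
    assert a.se == b.se
    assert a.se != c.se  # different seed, different bootstrap draws
    assert a.beta_xy == c.beta_xy  # point estimate is deterministic


def test_weighted_median_preconditions():
    ratios = [WaldRatio("a", 1.0, 1.0, 1.0)] * 2
    with pytest.raises(ValidationError, match=">= 3"):
        weighted_median(ratios, reps=100)
    three = [WaldRatio(f"r{i}", float(i), 1.0, 1.0) for i in range(3)]
    with pytest.raises(ValidationError, match="reps"):
        weighted_median(three, reps=1)


def test_weighted_median_fixture_estimate(primary_pairs):
    res = weighted_median(wald_ratios(primary_pairs), reps=1000, seed=0)
    assert math.exp(res.beta_xy) == pytest.approx(0.97, abs=0.02)


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_recovers_exact_line():
    """Points exactly on beta_out = 0.01 + 0.5 * beta_exp."""
    pairs = [make_pair(f"rs{i}", beta_exp=b, beta_out=0.01 + 0.5 * b, se_out=0.01)
             for i, b in enumerate([0.02, 0.05, 0.08, 0.11, 0.19])]
    slope, intercept = egger(pairs)
    assert slope.beta_xy == pytest.approx(0.5, abs=1e-10)
    assert intercept.beta_xy == pytest.approx(0.01, abs=1e-12)
    assert slope.df == 3


def test_egger_orientation_invariance():
    rng = np.random.default_rng(2)
    pairs = [make_pair(f"rs{i}", beta_exp=b, beta_out=rng.normal(0, 0.02),
                       se_out=s)
             for i, (b, s) in enumerate(zip(rng.uniform(0.01, 0.2, 15),
                                            rng.uniform(0.005, 0.05, 15)))]
    flipped = [make_pair(p.snp, -p.beta_exp, -p.beta_out, p.se_out)
               if i % 2 else p for i, p in enumerate(pairs)]
    s1, i1 = egger(pairs)
    s2, i2 = egger(flipped)
    assert s1.beta_xy == pytest.approx(s2.beta_xy, abs=1e-12)
    assert i1.beta_xy == pytest.approx(i2.beta_xy, abs=1e-12)
    assert s1.se == pytest.approx(s2.se, abs=1e-12)


def test_egger_against_statsmodels_wls():
    """Independent WLS oracle (all beta_exp > 0, overdispersed residuals so
    no SE flooring is involved)."""
    rng = np.random.default_rng(4)
    be = rng.uniform(0.02, 0.2, 25)
    bo = 0.005 + 0.3 * be + rng.normal(0, 0.05, 25)
    seo = rng.uniform(0.005, 0.02, 25)
    X = pairs_to_frame([make_pair(f"rs{i}", be[i], bo[i], seo[i])
                        for i in range(25)])
    est = EggerRegression().fit(X)
    wls = sm.WLS(bo, sm.add_constant(be), weights=1 / seo**2).fit()
    assert est.intercept_ == pytest.approx(wls.params[0], rel=1e-10)
    assert est.estimate_ == pytest.approx(wls.params[1], rel=1e-10)
    assert est.scale_ > 1  # overdispersed: statsmodels SEs apply unchanged
    assert est.se_ == pytest.approx(wls.bse[1], rel=1e-10)
    assert est.intercept_se_ == pytest.approx(wls.bse[0], rel=1e-10)


def test_egger_requires_three_instruments():
    with pytest.raises(ValidationError, match=">=3"):
        egger([make_pair("rs1"), make_pair("rs2")])


def test_egger_fixture_estimates(primary_pairs):
    slope, intercept = egger(primary_pairs)
    assert math.exp(slope.beta_xy) == pytest.approx(1.01, abs=0.03)
    assert intercept.beta_xy == pytest.approx(0.002, abs=0.002)
    assert intercept.se == pytest.approx(0.006, abs=0.002)


# ---------------------------------------------------------------------------
# sklearn protocol


def test_estimators_follow_sklearn_protocol(primary_pairs):
    from sklearn.base import clone
    X = pairs_to_frame(primary_pairs)
    for est in (IVWEstimator(variant="fixed"),
                WeightedMedianEstimator(n_boot=50, random_state=1),
                EggerRegression()):
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        fitted = cloned.fit(X)
        assert fitted.n_snps_ == 79
        assert np.isfinite(fitted.estimate_) and fitted.se_ > 0
        assert fitted.ci_low_ < fitted.ci_high_
    assert IVWEstimator().set_params(variant="fixed").variant == "fixed"


def test_mr_result_confidence_interval_formula(primary_pairs):
    res = ivw(wald_ratios(primary_pairs))
    assert res.ci_low == pytest.approx(res.beta_xy - 1.96 * res.se)
    assert res.ci_high == pytest.approx(res.beta_xy + 1.96 * res.se)
    assert res.ci_low < res.ci_high
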