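"""Two-sample MR estimators: Wald ratios, IVW, weighted median, MR-Egger.

Each SNP yields a Wald ratio ``beta_out / beta_exp`` — the causal effect of
the exposure on the outcome implied by that instrument — with first-order
standard error ``se_out / |beta_exp|``. The combined estimators differ in
how they pool the ratios:

* **IVW** — inverse-variance-weighted mean, algebraically the slope of a
  weighted through-origin regression of ``beta_out`` on ``beta_exp`` with
  weights ``1/se_out**2``. The ``fixed`` variant uses ``sqrt(1/sum(w))`` as
  the SE; the default ``multiplicative-re`` variant inflates it by the
  residual scale of that regression, floored at 1.
* **Weighted median** — the 50 %-weighted quantile of the ordered ratios;
  consistent when less than half of the total weight comes from invalid
  (pleiotropic) instruments. SE by seeded parametric bootstrap.
* **MR-Egger** — weighted least squares of ``beta_out`` on ``beta_exp``
  with an unconstrained intercept after orienting every SNP so that
  ``beta_exp >= 0``. The slope estimates the causal effect under the InSIDE
  assumption; the intercept estimates average directional pleiotropy.

The estimator classes follow the scikit-learn protocol (``fit``, fitted
attributes with trailing underscores, ``get_params``/``set_params``); the
module-level functions are thin wrappers around them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .harmonization import HarmonizedPair
from .summary_data import ValidationError

__all__ = [
    "WaldRatio",
    "MRResult",
    "wald_ratio",
    "wald_ratios",
    "pairs_to_frame",
    "IVWEstimator",
    "WeightedMedianEstimator",
    "EggerRegression",
    "ivw",
    "weighted_median",
    "egger",
]

logger = logging.getLogger(__name__)

#: normal quantile used throughout for 95 % confidence intervals
Z95 = 1.96

IVW_VARIANTS = ("fixed", "multiplicative-re")


@dataclass
class WaldRatio:
    """One SNP's causal-effect estimate and inverse-variance weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass
class MRResult:
    """A combined causal estimate with its uncertainty."""

    method: str
    beta_xy: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    df: int | None = None


def wald_ratio(pair: HarmonizedPair) -> WaldRatio:
    """Per-SNP causal estimate ``beta_out / beta_exp``.

    The SE is the first-order delta-method value ``se_out / |beta_exp|``
    (exposure-side sampling error deliberately ignored).
    """
    if pair.beta_exp == 0.0:
        raise ValidationError(f"{pair.snp}: undefined ratio (beta_exp = 0)")
    se = pair.se_out / abs(pair.beta_exp)
    return WaldRatio(pair.snp, pair.beta_out / pair.beta_exp, se, 1.0 / se**2)


def wald_ratios(pairs: Iterable[HarmonizedPair]) -> list[WaldRatio]:
    return [wald_ratio(p) for p in pairs]


def pairs_to_frame(pairs: Iterable[HarmonizedPair]) -> pd.DataFrame:
    """Harmonized pairs as a DataFrame (the estimators' input container)."""
    return pd.DataFrame(
        [{"snp": p.snp, "beta_exp": p.beta_exp, "se_exp": p.se_exp,
          "eaf_exp": p.eaf_exp, "beta_out": p.beta_out, "se_out": p.se_out,
          "eaf_out": p.eaf_out, "gene": p.gene}
         for p in pairs]
    )


def _extract(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Pull (beta_exp, beta_out, se_out, snp labels) out of the fit input.

    ``X`` may be a DataFrame with columns ``beta_exp``, ``beta_out``,
    ``se_out``, a sequence of :class:`HarmonizedPair`, or an array of shape
    (J, 3) in that column order.
    """
    if isinstance(X, pd.DataFrame):
        be = X["beta_exp"].to_numpy(float)
        bo = X["beta_out"].to_numpy(float)
        seo = X["se_out"].to_numpy(float)
        snps = X["snp"].to_numpy() if "snp" in X.columns else None
    elif len(X) and isinstance(next(iter(X)), HarmonizedPair):
        return _extract(pairs_to_frame(X))
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 3:
            raise ValueError("array input must have shape (n_snps, 3): "
                             "beta_exp, beta_out, se_out")
        be, bo, seo = arr[:, 0], arr[:, 1], arr[:, 2]
        snps = None
    if len(be) == 0:
        raise ValidationError("no instruments supplied")
    if np.any(~np.isfinite(be)) or np.any(~np.isfinite(bo)) or np.any(~np.isfinite(seo)):
        raise ValidationError("non-finite summary statistics in estimator input")
    if np.any(seo <= 0):
        raise ValidationError("outcome standard errors must be > 0")
    if np.any(be == 0):
        raise ValidationError("beta_exp = 0 instruments must be excluded upstream")
    return be, bo, seo, snps


def _normal_p(z: float) -> float:
    return 2.0 * stats.norm.sf(abs(z))


def _ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


# ---------------------------------------------------------------------------
# IVW


def _ivw_from_ratios(ratio: np.ndarray, weight: np.ndarray, variant: str
                     ) -> tuple[float, float, float]:
    """Weighted mean, SE and residual scale s (multiplicative model)."""
    if variant not in IVW_VARIANTS:
        raise ValueError(f"unknown IVW variant {variant!r}")
    J = len(ratio)
    sw = weight.sum()
    beta = float(np.sum(weight * ratio) / sw)
    se_fixed = math.sqrt(1.0 / sw)
    if variant == "fixed":
        return beta, se_fixed, 1.0
    if J < 2:
        logger.warning("multiplicative-re IVW requires >= 2 instruments; "
                       "falling back to fixed-effect SE")
        return beta, se_fixed, 1.0
    s2 = float(np.sum(weight * (ratio - beta) ** 2) / (J - 1))
    s = math.sqrt(s2)
    return beta, se_fixed * max(1.0, s), s


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted combination of per-SNP Wald ratios.

    Parameters
    ----------
    variant : {"multiplicative-re", "fixed"}
        SE model. Both share the same point estimate; ``multiplicative-re``
        scales the fixed-effect SE by the residual scale of the weighted
        through-origin regression, floored at 1.
    """

    def __init__(self, variant: str = "multiplicative-re"):
        self.variant = variant

    def fit(self, X, y=None) -> "IVWEstimator":
        be, bo, seo, snps = _extract(X)
        ratio = bo / be
        weight = be**2 / seo**2
        beta, se, scale = _ivw_from_ratios(ratio, weight, self.variant)
        self.estimate_, self.se_, self.scale_ = beta, se, scale
        self.ci_low_, self.ci_high_ = _ci(beta, se)
        self.pvalue_ = _normal_p(beta / se)
        self.n_snps_ = len(ratio)
        self.ratios_ = ratio
        self.weights_ = weight
        self.snp_ids_ = snps
        return self

    def result_(self) -> MRResult:
        method = "ivw-fe" if self.variant == "fixed" else "ivw-mre"
        return MRResult(method, self.estimate_, self.se_, self.ci_low_,
                        self.ci_high_, self.pvalue_, self.n_snps_,
                        df=self.n_snps_ - 1)


def ivw(ratios: Sequence[WaldRatio], variant: str = "multiplicative-re") -> MRResult:
    """IVW meta-analysis of a collection of Wald ratios."""
    if len(ratios) == 0:
        raise ValidationError("IVW requires at least one ratio")
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta, se, _ = _ivw_from_ratios(r, w, variant)
    lo, hi = _ci(beta, se)
    method = "ivw-fe" if variant == "fixed" else "ivw-mre"
    return MRResult(method, beta, se, lo, hi, _normal_p(beta / se),
                    len(ratios), df=len(ratios) - 1)


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median_rows(R: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted median of each row of ``R`` with per-column weights ``w``.

    Sort each row; form normalized breakpoints ``p_j = cum(w) - w_j/2``;
    linearly interpolate the sorted ratios at p = 0.5. A ratio whose
    breakpoint is exactly 0.5 is returned as-is (the interpolation weight
    collapses onto it); 0.5 outside the breakpoint range clamps to the
    extreme ratio.
    """
    R = np.atleast_2d(R)
    order = np.argsort(R, axis=1)
    Rs = np.take_along_axis(R, order, axis=1)
    Ws = w[order]
    cum = np.cumsum(Ws, axis=1) - 0.5 * Ws
    P = cum / Ws.sum(axis=1, keepdims=True)
    B, J = R.shape
    k = (P < 0.5).sum(axis=1)            # index of first breakpoint >= 0.5
    est = np.empty(B)
    lo_edge = k == 0
    hi_edge = k == J
    est[lo_edge] = Rs[lo_edge, 0]
    est[hi_edge] = Rs[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    i = np.nonzero(mid)[0]
    kk = k[mid]
    p0, p1 = P[i, kk - 1], P[i, kk]
    r0, r1 = Rs[i, kk - 1], Rs[i, kk]
    est[mid] = r0 + (r1 - r0) * (0.5 - p0) / (p1 - p0)
    return est


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    Parameters
    ----------
    n_boot : int
        Bootstrap replicates for the SE (each draws every ratio from
        ``Normal(ratio, se_ratio)`` and recomputes the weighted median).
    random_state : int
        Seed for the bootstrap generator; results are reproducible.
    """

    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None) -> "WeightedMedianEstimator":
        if self.n_boot < 2:
            raise ValidationError("weighted median requires n_boot >= 2")
        be, bo, seo, snps = _extract(X)
        if len(be) < 3:
            raise ValidationError("weighted median requires >= 3 instruments")
        ratio = bo / be
        se_ratio = seo / np.abs(be)
        weight = 1.0 / se_ratio**2
        beta = float(_weighted_median_rows(ratio[None, :], weight)[0])
        rng = np.random.default_rng(self.random_state)
        draws = rng.normal(ratio, se_ratio, size=(self.n_boot, len(ratio)))
        boots = _weighted_median_rows(draws, weight)
        se = float(boots.std(ddof=1))
        self.estimate_, self.se_ = beta, se
        self.ci_low_, self.ci_high_ = _ci(beta, se)
        self.pvalue_ = _normal_p(beta / se)
        self.n_snps_ = len(ratio)
        self.bootstrap_estimates_ = boots
        self.snp_ids_ = snps
        return self

    def result_(self) -> MRResult:
        return MRResult("weighted-median", self.estimate_, self.se_,
                        self.ci_low_, self.ci_high_, self.pvalue_, self.n_snps_)


def weighted_median(ratios: Sequence[WaldRatio], reps: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median estimate from a collection of Wald ratios."""
    if reps < 2:
        raise ValidationError("weighted median requires reps >= 2")
    if len(ratios) < 3:
        raise ValidationError("weighted median requires >= 3 instruments")
    r = np.array([x.ratio for x in ratios])
    se_r = np.array([x.se_ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = float(_weighted_median_rows(r[None, :], w)[0])
    rng = np.random.default_rng(seed)
    boots = _weighted_median_rows(rng.normal(r, se_r, size=(reps, len(r))), w)
    se = float(boots.std(ddof=1))
    lo, hi = _ci(beta, se)
    return MRResult("weighted-median", beta, se, lo, hi,
                    _normal_p(beta / se), len(ratios))


# ---------------------------------------------------------------------------
# MR-Egger


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure betas with a
    free intercept.

    SNPs are first oriented so every ``beta_exp`` is non-negative (both
    betas negated where needed); the fit is invariant to the incoming
    orientation convention. Weights are ``1/se_out**2``; both SEs are
    inflated by the residual scale floored at 1; p-values use a t reference
    with J - 2 degrees of freedom.
    """

    def fit(self, X, y=None) -> "EggerRegression":
        be, bo, seo, snps = _extract(X)
        J = len(be)
        if J < 3:
            raise ValidationError("Egger requires >=3 instruments")
        sign = np.where(be < 0, -1.0, 1.0)
        be, bo = be * sign, bo * sign
        w = 1.0 / seo**2
        sq = np.sqrt(w)
        Xd = np.column_stack([np.ones(J), be]) * sq[:, None]
        yd = bo * sq
        coef, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ coef
        sigma2 = float(resid @ resid) / (J - 2)
        cov_unscaled = np.linalg.inv(Xd.T @ Xd)
        infl = max(1.0, math.sqrt(sigma2))
        se = np.sqrt(np.diag(cov_unscaled)) * infl

        self.intercept_, self.estimate_ = float(coef[0]), float(coef[1])
        self.intercept_se_, self.se_ = float(se[0]), float(se[1])
        self.df_ = J - 2
        self.scale_ = math.sqrt(sigma2)
        self.ci_low_, self.ci_high_ = _ci(self.estimate_, self.se_)
        self.intercept_ci_ = _ci(self.intercept_, self.intercept_se_)
        self.pvalue_ = 2.0 * stats.t.sf(abs(self.estimate_ / self.se_), self.df_)
        self.intercept_pvalue_ = 2.0 * stats.t.sf(
            abs(self.intercept_ / self.intercept_se_), self.df_)
        self.n_snps_ = J
        self.snp_ids_ = snps
        return self

    def results_(self) -> tuple[MRResult, MRResult]:
        slope = MRResult("egger-slope", self.estimate_, self.se_, self.ci_low_,
                         self.ci_high_, self.pvalue_, self.n_snps_, df=self.df_)
        intercept = MRResult("egger-intercept", self.intercept_,
                             self.intercept_se_, *self.intercept_ci_,
                             self.intercept_pvalue_, self.n_snps_, df=self.df_)
        return slope, intercept


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MRResult, MRResult]:
    """MR-Egger slope and intercept for a set of harmonized pairs."""
    est = EggerRegression().fit(pairs_to_frame(pairs))
    return est.results_()
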