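"""Sensitivity analyses: leave-one-out, instrument subsets, heterogeneity.

Leave-one-out re-runs the IVW analysis with each instrument omitted in
turn; an omission whose confidence interval excludes the full-panel point
estimate marks that SNP as an outlier candidate (a single variant driving
the result, e.g. through pleiotropy). The subset analysis restricts the
panel to biologically focused instruments (selected by nearest gene or by
rsID). Cochran's Q quantifies the heterogeneity that the multiplicative
random-effects IVW scale absorbs: Q/(J-1) equals that model's residual
scale squared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .estimators import MRResult, WaldRatio, ivw, wald_ratios
from .harmonization import HarmonizedPair
from .summary_data import ValidationError

__all__ = [
    "LeaveOneOutRow",
    "leave_one_out",
    "loo_to_frame",
    "subset_analysis",
    "cochran_q",
]

FULL_SET_LABEL = "none"


@dataclass
class LeaveOneOutRow:
    """One IVW re-estimate with a single SNP omitted (or the full panel)."""

    omitted_snp: str
    beta_xy: float
    se: float
    ci_low: float
    ci_high: float
    excludes_full: bool = False   # omission CI excludes the full-set estimate


def leave_one_out(pairs: Sequence[HarmonizedPair],
                  variant: str = "multiplicative-re") -> list[LeaveOneOutRow]:
    """IVW with each SNP omitted in turn, plus the all-SNP row.

    Returns ``len(pairs) + 1`` rows; the row labelled ``"none"`` is the
    full-panel result and comes first.
    """
    if len(pairs) < 2:
        raise ValidationError("leave-one-out requires >= 2 instruments")
    full = ivw(wald_ratios(pairs), variant=variant)
    rows = [LeaveOneOutRow(FULL_SET_LABEL, full.beta_xy, full.se,
                           full.ci_low, full.ci_high)]
    for i, omitted in enumerate(pairs):
        subset = [p for j, p in enumerate(pairs) if j != i]
        res = ivw(wald_ratios(subset), variant=variant)
        rows.append(LeaveOneOutRow(
            omitted.snp, res.beta_xy, res.se, res.ci_low, res.ci_high,
            excludes_full=not (res.ci_low <= full.beta_xy <= res.ci_high),
        ))
    return rows


def loo_to_frame(rows: Iterable[LeaveOneOutRow]) -> pd.DataFrame:
    """Forest-plot-ready table: label, estimate, ci_low, ci_high, flag."""
    return pd.DataFrame(
        [{"label": r.omitted_snp, "estimate": r.beta_xy, "se": r.se,
          "ci_low": r.ci_low, "ci_high": r.ci_high,
          "excludes_full": r.excludes_full}
         for r in rows]
    )


def subset_analysis(pairs: Sequence[HarmonizedPair],
                    genes: Sequence[str] | None = None,
                    snps: Sequence[str] | None = None,
                    variant: str = "multiplicative-re") -> MRResult:
    """IVW restricted to instruments selected by nearest gene or by rsID."""
    if genes is None and snps is None:
        raise ValueError("provide a gene list or an rsID list")
    selected = list(pairs)
    label = []
    if genes is not None:
        wanted = {g.upper() for g in genes}
        selected = [p for p in selected if (p.gene or "").upper() in wanted]
        label.append(f"genes={{{', '.join(sorted(wanted))}}}")
    if snps is not None:
        wanted_ids = set(snps)
        selected = [p for p in selected if p.snp in wanted_ids]
        label.append(f"snps={{{', '.join(sorted(wanted_ids))}}}")
    if len(selected) < 2:
        raise ValidationError(
            f"subset selector {' & '.join(label)} matched {len(selected)} "
            "instruments; >= 2 required")
    return ivw(wald_ratios(selected), variant=variant)


def cochran_q(ratios: Sequence[WaldRatio]) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic for a set of Wald ratios.

    ``Q = sum(w * (ratio - ivw)**2)`` with ``df = J - 1``; the p-value is
    the upper chi-square tail.
    """
    if len(ratios) < 2:
        raise ValidationError("Cochran's Q requires >= 2 ratios")
    beta = ivw(ratios, variant="fixed").beta_xy
    q = float(sum(r.weight * (r.ratio - beta) ** 2 for r in ratios))
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df))
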