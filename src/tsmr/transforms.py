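"""Scale transformations, instrument-strength metrics and the results report.

Causal estimates come out of the estimators on the analysis scale: log-odds
per SD of ln-25(OH)D for the binary caries outcomes, SD units of the
residualized DMFS score for adult caries severity. For interpretation they
are re-expressed as

* an odds ratio, ``OR = exp(beta)`` with CI ``exp(beta +/- 1.96 * SE)``;
* affected tooth surfaces, ``beta * s`` with CI ``s * (beta +/- 1.96 * SE)``,
  where ``s = 19.87`` DMFS per SD is the back-transform constant estimated
  in an external adult reference population.

Instrument strength uses the variance-explained approximation for a
standardized phenotype, ``r^2 ~= 2 * beta^2 * f * (1 - f)`` per SNP, summed
over the panel, plus per-SNP F = (beta/se)^2 and the R^2-based overall
F-statistic approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .estimators import MRResult, Z95
from .summary_data import InstrumentSet, ValidationError, _is_missing

__all__ = [
    "TransformedResult",
    "InstrumentStrength",
    "to_odds_ratio",
    "to_dmfs_surfaces",
    "instrument_strength",
    "render_report",
    "round_half_away",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (presentation-layer rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TransformedResult:
    """A causal estimate re-expressed on an interpretable scale."""

    scale: str              # odds-ratio | dmfs-surfaces | raw
    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str
    outcome_name: str
    beta_xy: float = math.nan
    se: float = math.nan
    n_snps: int = 0


def to_odds_ratio(result: MRResult, outcome_name: str = "outcome",
                  legacy_additive_ci: bool = False) -> TransformedResult:
    """Exponentiate a log-odds causal estimate into an odds ratio.

    The default CI is ``exp(beta +/- 1.96 * SE)``. ``legacy_additive_ci``
    instead reports ``OR +/- 1.96 * SE(beta)``, an additive approximation
    some published tables use; it is provided for comparison only.
    """
    or_ = math.exp(result.beta_xy)
    if legacy_additive_ci:
        lo, hi = or_ - Z95 * result.se, or_ + Z95 * result.se
    else:
        lo = math.exp(result.beta_xy - Z95 * result.se)
        hi = math.exp(result.beta_xy + Z95 * result.se)
    return TransformedResult("odds-ratio", or_, lo, hi, result.pvalue,
                             result.method, outcome_name,
                             beta_xy=result.beta_xy, se=result.se,
                             n_snps=result.n_snps)


def to_dmfs_surfaces(result: MRResult, scale_factor: float = 19.87,
                     outcome_name: str = "dmfs") -> TransformedResult:
    """Back-transform an SD-scale estimate to affected tooth surfaces."""
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be > 0")
    return TransformedResult(
        "dmfs-surfaces",
        result.beta_xy * scale_factor,
        scale_factor * (result.beta_xy - Z95 * result.se),
        scale_factor * (result.beta_xy + Z95 * result.se),
        result.pvalue, result.method, outcome_name,
        beta_xy=result.beta_xy, se=result.se, n_snps=result.n_snps,
    )


@dataclass
class InstrumentStrength:
    """Variance explained and F-statistics for an instrument panel."""

    per_snp_r2: list[tuple[str, float]]
    total_r2: float
    per_snp_F: list[tuple[str, float]]
    overall_F: float
    n_exposure: int
    n_snps: int
    skipped: list[str] = field(default_factory=list)


def instrument_strength(instruments: InstrumentSet, n_exposure: int) -> InstrumentStrength:
    """Instrument-strength metrics for an exposure panel.

    Per SNP: variance explained ``r^2 = 2 * beta^2 * f * (1 - f)`` (valid
    for a standardized phenotype) and ``F = (beta / se)^2``. Overall:
    ``F = (R2 / (1 - R2)) * (n - J - 1) / J`` with ``R2`` the summed
    variance explained. SNPs with missing frequency or beta are skipped
    with a logged warning.
    """
    r2s: list[tuple[str, float]] = []
    fs: list[tuple[str, float]] = []
    skipped: list[str] = []
    for r in instruments:
        if _is_missing(r.eaf) or _is_missing(r.beta):
            logger.warning("instrument_strength: skipping %s (missing eaf or beta)", r.snp)
            skipped.append(r.snp)
            continue
        r2s.append((r.snp, 2.0 * r.beta**2 * r.eaf * (1.0 - r.eaf)))
        if not _is_missing(r.se):
            fs.append((r.snp, (r.beta / r.se) ** 2))
    total = sum(v for _, v in r2s)
    j = len(r2s)
    overall = (total / (1.0 - total)) * ((n_exposure - j - 1) / j) if j else math.nan
    return InstrumentStrength(r2s, total, fs, overall, n_exposure, j, skipped)


# ---------------------------------------------------------------------------
# Report rendering


def _fmt_ci(lo: float, hi: float) -> str:
    return f"{round_half_away(lo):.2f}, {round_half_away(hi):.2f}"


def results_frame(results: Iterable[TransformedResult]) -> pd.DataFrame:
    """Full-precision results table plus rounded presentation columns."""
    rows = []
    for r in results:
        rows.append({
            "outcome": r.outcome_name, "method": r.method, "n_snps": r.n_snps,
            "beta": r.beta_xy, "se": r.se, "scale": r.scale,
            "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "pvalue": r.pvalue,
            "estimate_2dp": round_half_away(r.estimate),
            "ci_2dp": _fmt_ci(r.ci_low, r.ci_high),
        })
    return pd.DataFrame(rows)


def render_report(results: Sequence[TransformedResult],
                  strength: InstrumentStrength | None = None,
                  exclusions: pd.DataFrame | None = None) -> str:
    """Render a Markdown summary of the analysis.

    Deterministic: the same inputs render byte-identical output.
    """
    if not results:
        raise ValidationError("render_report requires at least one result")
    lines = ["# Two-sample MR results", ""]
    lines += ["| Outcome | Method | SNPs | Estimate | 95% CI | P |",
              "|---|---|---|---|---|---|"]
    unit = {"odds-ratio": "OR", "dmfs-surfaces": "surfaces", "raw": "beta"}
    for r in results:
        est = f"{unit[r.scale]}= {round_half_away(r.estimate):.2f}"
        lines.append(
            f"| {r.outcome_name} | {r.method} | {r.n_snps} | {est} "
            f"| {_fmt_ci(r.ci_low, r.ci_high)} | {r.pvalue:.2g} |")
    if strength is not None and strength.n_snps:
        lines += ["", "## Instrument strength", "",
                  f"- SNPs with frequency data: {strength.n_snps}",
                  f"- total variance explained: {100 * strength.total_r2:.1f}%",
                  f"- overall F-statistic: {strength.overall_F:.1f}"]
        if strength.skipped:
            lines.append(f"- skipped (missing eaf/beta): {', '.join(strength.skipped)}")
    if exclusions is not None and len(exclusions):
        lines += ["", "## Exclusions", ""]
        for row in exclusions.itertuples(index=False):
            lines.append(f"- {row.snp} ({row.outcome}): {row.reason}")
    lines.append("")
    return "\n".join(lines)
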