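"""Allele harmonization of exposure and outcome summary statistics.

Two GWASs may report the same SNP with respect to different alleles or on
different strands. Before any per-SNP causal estimate can be formed, both
betas must refer to the same effect allele. The exposure record's printed
effect allele is the reference orientation; the outcome side is sign-flipped
(beta negated, frequency complemented) when its alleles are reported the
other way round, and strand-complemented (A<->T, C<->G) when the letters
only match on the opposite strand.

Palindromic SNPs (allele pair A/T or C/G) are strand-ambiguous: the letters
alone cannot reveal whether the two studies used the same strand. Three
policies are supported:

``assume-forward``
    trust the reported letters as-is (both studies on the same strand);
``infer-by-frequency``
    use allele frequencies to resolve the strand: exclude the SNP when the
    configured frequency lies inside the ambiguity window (too close to 0.5
    to be informative), otherwise flip the outcome when the minor-allele
    side disagrees between the studies;
``drop-all``
    exclude every palindromic SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .summary_data import (
    AnalysisConfig,
    InstrumentSet,
    ValidationError,
    VariantAssociation,
    _is_missing,
)

__all__ = [
    "COMPLEMENT",
    "HarmonizedPair",
    "is_palindromic",
    "complement_allele",
    "flip_association",
    "harmonize_pair",
    "build_analysis_set",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTION_NONE = "none"
ACTION_FLIPPED = "flipped"


def complement_allele(a: str) -> str:
    try:
        return COMPLEMENT[a.upper()]
    except KeyError as err:
        raise ValidationError(f"invalid allele {a!r}") from err


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is its own strand complement ({A,T} or {C,G})."""
    pair = {a1.upper(), a2.upper()}
    if not pair <= set("ACGT"):
        bad = sorted(pair - set("ACGT"))
        raise ValidationError(f"invalid allele {bad[0]!r}")
    return pair in ({"A", "T"}, {"C", "G"})


def flip_association(v: VariantAssociation) -> VariantAssociation:
    """Re-express a record with respect to its other allele.

    Swaps the alleles, negates beta and complements the frequency. The
    operation is involutive: ``flip(flip(v)) == v``.
    """
    return replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta=-v.beta,
        eaf=v.eaf if _is_missing(v.eaf) else 1.0 - v.eaf,
    )


@dataclass
class HarmonizedPair:
    """Exposure and outcome statistics for one SNP on a common effect allele."""

    snp: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    is_palindromic: bool = False
    is_ambiguous: bool = False
    action: str = ACTION_NONE      # none | flipped | excluded:<reason>
    gene: str | None = None

    @property
    def excluded(self) -> bool:
        return self.action.startswith("excluded")

    @property
    def exclusion_reason(self) -> str | None:
        if not self.excluded:
            return None
        return self.action.split(":", 1)[1]


def _excluded(exposure: VariantAssociation, reason: str, *,
              palindromic: bool = False, ambiguous: bool = False) -> HarmonizedPair:
    return HarmonizedPair(
        snp=exposure.snp,
        effect_allele=exposure.effect_allele or "N",
        other_allele=exposure.other_allele or "N",
        beta_exp=exposure.beta, se_exp=exposure.se, eaf_exp=exposure.eaf,
        beta_out=math.nan, se_out=math.nan, eaf_out=math.nan,
        is_palindromic=palindromic, is_ambiguous=ambiguous,
        action=f"excluded:{reason}", gene=exposure.gene,
    )


def _ambiguity_frequencies(config: AnalysisConfig, eaf_exp: float, eaf_out: float) -> list[float]:
    return {
        "exposure": [eaf_exp],
        "outcome": [eaf_out],
        "either": [eaf_exp, eaf_out],
    }[config.ambiguity_study]


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    config: AnalysisConfig | None = None,
) -> HarmonizedPair:
    """Align one SNP's outcome record to the exposure record's effect allele.

    Returns a :class:`HarmonizedPair` whose ``action`` records what was done
    (``none``, ``flipped`` or ``excluded:<reason>``). Incompatible allele
    sets yield an excluded pair rather than an exception.
    """
    config = config or AnalysisConfig()
    if exposure.snp != outcome.snp:
        raise ValidationError(
            f"snp mismatch: exposure {exposure.snp} vs outcome {outcome.snp}")
    if not outcome.has_statistics:
        return _excluded(exposure, "missing outcome statistics")

    e1, e2 = exposure.effect_allele, exposure.other_allele
    o = outcome
    palindromic = is_palindromic(e1, e2)

    flipped = False
    if (o.effect_allele, o.other_allele) == (e1, e2):
        pass
    elif (o.effect_allele, o.other_allele) == (e2, e1):
        o = flip_association(o)
        flipped = True
    elif not palindromic:
        # try the opposite strand
        oc1, oc2 = complement_allele(o.effect_allele), complement_allele(o.other_allele)
        if (oc1, oc2) == (e1, e2):
            o = replace(o, effect_allele=oc1, other_allele=oc2)
        elif (oc1, oc2) == (e2, e1):
            o = flip_association(replace(o, effect_allele=oc1, other_allele=oc2))
            flipped = True
        else:
            return _excluded(exposure, "allele mismatch")
    else:  # palindromic and letters do not match in either order
        return _excluded(exposure, "allele mismatch", palindromic=True)

    ambiguous = False
    if palindromic:
        if config.palindrome_policy == "drop-all":
            return _excluded(exposure, "palindromic", palindromic=True)
        if config.palindrome_policy == "infer-by-frequency":
            freqs = _ambiguity_frequencies(config, exposure.eaf, o.eaf)
            if any(_is_missing(f) for f in freqs):
                return _excluded(exposure, "palindromic with missing frequency",
                                 palindromic=True, ambiguous=True)
            if any(config.ambiguity_low < f < config.ambiguity_high for f in freqs):
                return _excluded(exposure, "palindromic with intermediate frequency",
                                 palindromic=True, ambiguous=True)
            # informative frequencies: flip the strand when the minor-allele
            # side disagrees between the two studies
            if not _is_missing(o.eaf) and (exposure.eaf < 0.5) != (o.eaf < 0.5):
                o = replace(flip_association(o),
                            effect_allele=o.effect_allele, other_allele=o.other_allele)
                flipped = True

    return HarmonizedPair(
        snp=exposure.snp,
        effect_allele=e1, other_allele=e2,
        beta_exp=exposure.beta, se_exp=exposure.se, eaf_exp=exposure.eaf,
        beta_out=o.beta, se_out=o.se, eaf_out=o.eaf,
        is_palindromic=palindromic, is_ambiguous=ambiguous,
        action=ACTION_FLIPPED if flipped else ACTION_NONE,
        gene=exposure.gene,
    )


def build_analysis_set(
    exposure: InstrumentSet,
    outcome: InstrumentSet,
    config: AnalysisConfig | None = None,
) -> tuple[list[HarmonizedPair], pd.DataFrame]:
    """Build the analysis-ready instrument set for one outcome.

    Walks the exposure panel in order, drops SNPs without usable outcome
    statistics, harmonizes the rest and applies the palindrome policy.
    Returns the retained pairs plus an exclusion report (one row per
    excluded SNP: ``snp, outcome, reason, detail``). Retained + excluded
    always equals the exposure SNP count.
    """
    config = config or AnalysisConfig()
    outcome_by_snp = {r.snp: r for r in outcome}

    retained: list[HarmonizedPair] = []
    report_rows: list[dict] = []

    def exclude(snp: str, reason: str, detail: str = "") -> None:
        report_rows.append({"snp": snp, "outcome": config.outcome_name,
                            "reason": reason, "detail": detail})

    for exp in exposure:
        out = outcome_by_snp.get(exp.snp)
        if out is None:
            exclude(exp.snp, "missing from outcome", "snp absent from outcome table")
            continue
        if not out.has_statistics:
            exclude(exp.snp, "missing outcome statistics",
                    "outcome beta/se not reported")
            continue
        if not exp.has_statistics:
            exclude(exp.snp, "missing exposure statistics",
                    "exposure beta/se not reported")
            continue
        if exp.beta == 0.0:
            exclude(exp.snp, "zero exposure beta", "Wald ratio undefined")
            continue
        pair = harmonize_pair(exp, out, config)
        if pair.excluded:
            exclude(exp.snp, pair.exclusion_reason or "excluded",
                    f"alleles {exp.effect_allele}/{exp.other_allele}, "
                    f"eaf_exp={exp.eaf:g}, eaf_out={out.eaf:g}" if not _is_missing(out.eaf)
                    else f"alleles {exp.effect_allele}/{exp.other_allele}")
            continue
        retained.append(pair)

    if not retained:
        raise ValidationError("no usable instruments after harmonization")
    report = pd.DataFrame(report_rows, columns=["snp", "outcome", "reason", "detail"])
    assert len(retained) + len(report) == len(exposure)
    return retained, report
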