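"""GWAS summary-statistic data model, tab-separated I/O and validation.

The two-sample MR pipeline consumes two kinds of tables with a shared schema:
an *exposure* table (per-SNP associations with standardized natural-log serum
25(OH)D) and one *outcome* table per caries trait (log-odds-ratio scale for
the binary paediatric outcomes, standardized-residual units for adult DMFS).
Columns: ``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pvalue,
n, gene`` — tab-separated with a header row; missing cells are encoded ``NA``
(``nan`` and empty cells are also accepted on read).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "VariantAssociation",
    "InstrumentSet",
    "AnalysisConfig",
    "RunConfig",
    "read_summary_table",
    "write_summary_table",
    "read_proxy_table",
    "apply_proxy_map",
    "load_run_config",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for on-disk tables
COLUMNS = ["snp", "chr", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "pvalue", "n", "gene"]
MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se"]

#: strings accepted as a missing cell
NA_STRINGS = {"", "NA", "na", "nan", "NaN", "None", "."}

#: smallest positive float64; printed p-values below the representable range
#: (the exposure GWAS reports values such as 2.9E-1689) are clamped here so
#: the p ∈ (0, 1] invariant survives parsing.
TINY_P = 5e-324


class SchemaError(ValueError):
    """A required column is absent or the file layout is not understood."""


class ValidationError(ValueError):
    """A cell or record violates the data model's invariants."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float):
        return math.isnan(x)
    return False


@dataclass
class VariantAssociation:
    """One SNP's summary statistics in one study.

    ``beta`` is the additive effect per copy of ``effect_allele``; its scale
    depends on the study (SD of ln-25(OH)D for the exposure, log-OR for the
    binary caries outcomes, SD units for DMFS). Statistics may be missing
    (``nan`` / ``None``) for SNPs absent from an outcome GWAS.
    """

    snp: str
    effect_allele: str | None
    other_allele: str | None
    eaf: float = math.nan
    beta: float = math.nan
    se: float = math.nan
    pvalue: float = math.nan
    n: float = math.nan
    chrom: int | None = None
    pos: int | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.snp or not isinstance(self.snp, str):
            raise ValidationError("snp identifier must be a non-empty string")
        for attr in ("effect_allele", "other_allele"):
            a = getattr(self, attr)
            if a is not None:
                a = a.upper()
                if a not in VALID_ALLELES:
                    raise ValidationError(
                        f"{self.snp}: invalid allele {a!r} for {attr}")
                object.__setattr__(self, attr, a)
        if self.effect_allele is not None and self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp}: effect and other allele are identical")
        if not _is_missing(self.se) and self.se <= 0:
            raise ValidationError(f"{self.snp}: se must be > 0, got {self.se}")
        if not _is_missing(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp}: eaf must be in [0, 1], got {self.eaf}")
        if not _is_missing(self.pvalue) and not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(
                f"{self.snp}: pvalue must be in (0, 1], got {self.pvalue}")

    @property
    def has_statistics(self) -> bool:
        """True when beta and se are both present."""
        return not (_is_missing(self.beta) or _is_missing(self.se))

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class InstrumentSet:
    """An ordered panel of variant associations plus selection thresholds."""

    records: list[VariantAssociation]
    selection_pvalue_threshold: float = 5e-8
    maf_threshold: float = 0.05
    proxy_r2_threshold: float = 0.7
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate snp ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp for r in self.records]

    def get(self, snp: str) -> VariantAssociation:
        for r in self.records:
            if r.snp == snp:
                return r
        raise KeyError(snp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp": r.snp, "chr": r.chrom, "pos": r.pos,
              "effect_allele": r.effect_allele, "other_allele": r.other_allele,
              "eaf": r.eaf, "beta": r.beta, "se": r.se,
              "pvalue": r.pvalue, "n": r.n, "gene": r.gene}
             for r in self.records],
            columns=COLUMNS,
        )

    def validate_selection(self) -> None:
        """Check the instrument-selection invariants where fields are present.

        Every record with a p-value must reach genome-wide significance at
        ``selection_pvalue_threshold`` and every record with a frequency must
        have minor-allele frequency >= ``maf_threshold``.
        """
        bad: list[str] = []
        for r in self.records:
            if not _is_missing(r.pvalue) and r.pvalue > self.selection_pvalue_threshold:
                bad.append(f"{r.snp} (p={r.pvalue:g})")
            if not _is_missing(r.eaf) and r.maf < self.maf_threshold:
                bad.append(f"{r.snp} (maf={r.maf:g})")
        if bad:
            raise ValidationError("instrument selection violated: " + "; ".join(bad))


# ---------------------------------------------------------------------------
# Analysis configuration

PALINDROME_POLICIES = ("assume-forward", "infer-by-frequency", "drop-all")
AMBIGUITY_STUDIES = ("exposure", "outcome", "either")


@dataclass
class AnalysisConfig:
    """Per-outcome harmonization and estimation settings.

    The frequency-ambiguity window defaults to the open interval
    (0.39, 0.61) applied to the exposure-side effect-allele frequency: a
    palindromic SNP whose frequency is that close to 0.5 cannot have its
    strand resolved and is excluded under the ``infer-by-frequency`` policy.
    """

    outcome_name: str = "outcome"
    outcome_type: str = "binary"                 # binary | quantitative
    palindrome_policy: str = "assume-forward"    # assume-forward | infer-by-frequency | drop-all
    ambiguity_low: float = 0.39
    ambiguity_high: float = 0.61
    ambiguity_study: str = "exposure"            # exposure | outcome | either
    dmfs_scale_factor: float = 19.87
    wm_bootstrap_reps: int = 1000
    rng_seed: int = 0
    ivw_variant: str = "multiplicative-re"       # fixed | multiplicative-re

    def __post_init__(self) -> None:
        if self.outcome_type not in ("binary", "quantitative"):
            raise ValidationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.palindrome_policy not in PALINDROME_POLICIES:
            raise ValidationError(f"unknown palindrome_policy {self.palindrome_policy!r}")
        if self.ambiguity_study not in AMBIGUITY_STUDIES:
            raise ValidationError(f"unknown ambiguity_study {self.ambiguity_study!r}")
        if not 0.0 <= self.ambiguity_low < 0.5 < self.ambiguity_high <= 1.0:
            raise ValidationError(
                "ambiguity window must satisfy 0 <= low < 0.5 < high <= 1, got "
                f"({self.ambiguity_low}, {self.ambiguity_high})")
        if self.dmfs_scale_factor <= 0:
            raise ValidationError("dmfs_scale_factor must be > 0")
        if self.wm_bootstrap_reps < 2:
            raise ValidationError("wm_bootstrap_reps must be >= 2")


@dataclass
class RunConfig:
    """A full analysis configuration: exposure table plus per-outcome settings."""

    exposure_path: Path
    exposure_n: int
    outcomes: dict[str, tuple[Path, AnalysisConfig]]


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_float(cell: str, column: str, snp: str) -> float:
    s = cell.strip()
    if s in NA_STRINGS:
        return math.nan
    try:
        v = float(s)
    except ValueError as err:
        raise ValidationError(
            f"{snp}: malformed numeric cell {cell!r} in column {column!r}") from err
    if v == 0.0 and column == "pvalue" and any(c in "123456789" for c in s):
        # a printed value like 2.9E-1689 underflows float64; clamp to keep p > 0
        return TINY_P
    return v


def _parse_int(cell: str, column: str, snp: str) -> int | None:
    s = cell.strip()
    if s in NA_STRINGS:
        return None
    try:
        return int(float(s))
    except ValueError as err:
        raise ValidationError(
            f"{snp}: malformed integer cell {cell!r} in column {column!r}") from err


def read_summary_table(path: str | Path, schema: str = "exposure") -> InstrumentSet:
    """Read a tab-separated summary-statistics table into an :class:`InstrumentSet`.

    All rows are returned, including those whose statistics are entirely
    missing (``NA``); row order is preserved. ``schema`` records whether the
    table is an exposure or an outcome table; both share one column layout.
    """
    if schema not in ("exposure", "outcome"):
        raise ValueError(f"schema must be 'exposure' or 'outcome', got {schema!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")

    records: list[VariantAssociation] = []
    for _, row in df.iterrows():
        snp = row["snp"].strip()
        def opt(col: str) -> str:
            return row[col] if col in df.columns else "NA"
        allele = lambda col: None if row[col].strip() in NA_STRINGS else row[col].strip()
        records.append(VariantAssociation(
            snp=snp,
            effect_allele=allele("effect_allele"),
            other_allele=allele("other_allele"),
            eaf=_parse_float(row["eaf"], "eaf", snp),
            beta=_parse_float(row["beta"], "beta", snp),
            se=_parse_float(row["se"], "se", snp),
            pvalue=_parse_float(opt("pvalue"), "pvalue", snp),
            n=_parse_float(opt("n"), "n", snp),
            chrom=_parse_int(opt("chr"), "chr", snp),
            pos=_parse_int(opt("pos"), "pos", snp),
            gene=None if opt("gene").strip() in NA_STRINGS else opt("gene").strip(),
        ))
    return InstrumentSet(
        records,
        provenance=[f"read {len(records)} records from {path.name} ({schema} schema)"],
    )


def _fmt(value, integer: bool = False) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if integer:
        return str(int(value))
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        # sample sizes parse as floats; print them back as integers
        return str(int(value))
    return repr(float(value)) if isinstance(value, float) else str(value)


def write_summary_table(instruments: InstrumentSet, path: str | Path) -> None:
    """Write an :class:`InstrumentSet` as a tab-separated table.

    Floats are written with round-tripping precision so that
    ``read(write(x)) == x`` field by field.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in instruments:
            fh.write("\t".join([
                r.snp,
                _fmt(r.chrom, integer=True),
                _fmt(r.pos, integer=True),
                r.effect_allele or "NA",
                r.other_allele or "NA",
                _fmt(r.eaf), _fmt(r.beta), _fmt(r.se), _fmt(r.pvalue),
                _fmt(r.n),
                r.gene or "NA",
            ]) + "\n")


# ---------------------------------------------------------------------------
# LD-proxy substitution


def read_proxy_table(path: str | Path) -> pd.DataFrame:
    """Read a proxy-substitution table: columns missing_snp, proxy_snp, r2."""
    df = pd.read_csv(path, sep="\t")
    for col in ("missing_snp", "proxy_snp", "r2"):
        if col not in df.columns:
            raise SchemaError(f"proxy table missing column {col!r}")
    return df


def apply_proxy_map(
    instruments: InstrumentSet,
    proxies: pd.DataFrame,
    lookup: InstrumentSet | None = None,
    r2_threshold: float | None = None,
) -> InstrumentSet:
    """Substitute or exclude instruments according to an LD-proxy table.

    Each ``missing_snp`` whose best proxy reaches ``r2 >= r2_threshold``
    (boundary inclusive) is replaced *in place* by the proxy's record, taken
    from ``lookup`` (e.g. the full exposure GWAS table). Entries below the
    threshold are excluded. Every substitution and exclusion is appended to
    the returned set's provenance. LD computation itself is out of scope —
    the r² values are caller-supplied.
    """
    thr = instruments.proxy_r2_threshold if r2_threshold is None else r2_threshold
    if len(proxies) and not proxies["r2"].between(0.0, 1.0).all():
        raise ValidationError("proxy r2 values must lie in [0, 1]")

    notes = list(instruments.provenance)
    records = list(instruments.records)
    index = {r.snp: i for i, r in enumerate(records)}
    drop: set[int] = set()
    for row in proxies.itertuples(index=False):
        if row.missing_snp not in index:
            notes.append(f"proxy entry for {row.missing_snp} ignored: not in instrument set")
            continue
        i = index[row.missing_snp]
        if row.r2 >= thr:
            if lookup is None:
                raise ValidationError(
                    f"proxy substitution for {row.missing_snp} requested but no lookup supplied")
            try:
                records[i] = lookup.get(row.proxy_snp)
            except KeyError as err:
                raise ValidationError(
                    f"proxy SNP {row.proxy_snp} absent from the supplied lookup source") from err
            notes.append(
                f"substituted {row.missing_snp} -> {row.proxy_snp} (r2={row.r2:g} >= {thr:g})")
        else:
            drop.add(i)
            notes.append(
                f"excluded {row.missing_snp}: best proxy {row.proxy_snp} r2={row.r2:g} < {thr:g}")
    kept = [r for i, r in enumerate(records) if i not in drop]
    return InstrumentSet(
        kept,
        selection_pvalue_threshold=instruments.selection_pvalue_threshold,
        maf_threshold=instruments.maf_threshold,
        proxy_r2_threshold=thr,
        provenance=notes,
    )


# ---------------------------------------------------------------------------
# Run configuration (YAML)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Layout::

        exposure: {file: vitd_exposure.tsv, n: 443734}
        dmfs_scale_factor: 19.87
        outcomes:
          caries_primary: {file: ..., outcome_type: binary,
                           palindrome_policy: assume-forward}

    Relative file paths are resolved against the YAML file's directory.
    Top-level keys matching :class:`AnalysisConfig` fields act as defaults
    for every outcome and may be overridden per outcome.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    shared_keys = ("ambiguity_low", "ambiguity_high", "ambiguity_study",
                   "dmfs_scale_factor", "wm_bootstrap_reps", "rng_seed", "ivw_variant")
    shared = {k: raw[k] for k in shared_keys if k in raw}
    outcomes: dict[str, tuple[Path, AnalysisConfig]] = {}
    for name, spec in raw["outcomes"].items():
        opts = dict(shared)
        opts.update({k: v for k, v in spec.items() if k != "file"})
        outcomes[name] = (base / spec["file"], AnalysisConfig(outcome_name=name, **opts))
    return RunConfig(
        exposure_path=base / raw["exposure"]["file"],
        exposure_n=int(raw["exposure"]["n"]),
        outcomes=outcomes,
    )
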