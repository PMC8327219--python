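"""Packaged summary-statistic fixtures.

The package ships verbatim transcriptions of the published per-SNP
association tables for the 25(OH)D / dental-caries analysis:

* ``vitd_exposure.tsv`` — 83 conditionally independent SNPs associated with
  standardized ln-25(OH)D at genome-wide significance (n = 443,734).
* ``<outcome>_outcome.tsv`` — the same SNPs' associations with each caries
  outcome (``caries_primary``, ``caries_permanent``, ``dmfs``); SNPs absent
  from an outcome GWAS carry ``NA`` statistics.

These are frozen golden files; checksum tests guard against drift.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .summary_data import InstrumentSet, RunConfig, load_run_config, read_summary_table

OUTCOMES = ("caries_primary", "caries_permanent", "dmfs")

#: exposure GWAS sample size (table caption)
EXPOSURE_GWAS_N = 443_734


def data_path(name: str) -> Path:
    """Absolute path of a packaged data file."""
    p = resources.files("tsmr").joinpath("data", name)
    return Path(str(p))


def load_exposure() -> InstrumentSet:
    """The 83-SNP 25(OH)D instrument panel."""
    return read_summary_table(data_path("vitd_exposure.tsv"), schema="exposure")


def load_outcome(name: str) -> InstrumentSet:
    """Per-SNP association statistics for one caries outcome."""
    if name not in OUTCOMES:
        raise ValueError(f"unknown outcome {name!r}; available: {', '.join(OUTCOMES)}")
    return read_summary_table(data_path(f"{name}_outcome.tsv"), schema="outcome")


def paper_config_path() -> Path:
    """Path of the bundled default run configuration."""
    return data_path("paper.yaml")


def load_paper_config() -> RunConfig:
    """The bundled run configuration for the packaged fixtures."""
    return load_run_config(paper_config_path())
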