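import math

import pytest

from tsmr import AnalysisConfig, VariantAssociation, build_analysis_set
from tsmr.datasets import load_exposure, load_outcome, load_paper_config


@pytest.fixture(scope="session")
def exposure():
    return load_exposure()


@pytest.fixture(scope="session")
def paper_config():
    return load_paper_config()


@pytest.fixture(scope="session")
def outcomes():
    return {name: load_outcome(name)
            for name in ("caries_primary", "caries_permanent", "dmfs")}


@pytest.fixture(scope="session")
def analysis_sets(exposure, outcomes, paper_config):
    """Harmonized pairs + exclusion report for each outcome, paper defaults."""
    sets = {}
    for name, (_, cfg) in paper_config.outcomes.items():
        sets[name] = build_analysis_set(exposure, outcomes[name], cfg)
    return sets


@pytest.fixture(scope="session")
def primary_pairs(analysis_sets):
    return analysis_sets["caries_primary"][0]


@pytest.fixture(scope="session")
def dmfs_pairs(analysis_sets):
    return analysis_sets["dmfs"][0]


def make_variant(snp="rs1", a1="A", a2="G", eaf=0.3, beta=0.1, se=0.01,
                 pvalue=1e-10, n=1000, gene=None, chrom=1, pos=100):
    return VariantAssociation(snp=snp, effect_allele=a1, other_allele=a2,
                              eaf=eaf, beta=beta, se=se, pvalue=pvalue,
                              n=n, gene=gene, chrom=chrom, pos=pos)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def default_config():
    return AnalysisConfig()
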