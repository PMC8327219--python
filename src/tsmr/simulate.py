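"""Synthetic two-sample GWAS summary statistics with known truth.

The generator works at the summary level — the natural resolution for a
two-sample MR analysis, which never sees individual genotypes. The
structural model per SNP j:

    gamma_j   true exposure effect (magnitudes drawn log-uniformly over the
              range seen in the real instrument panel, random sign)
    alpha_j   true direct (pleiotropic) effect on the outcome
    beta_exp_j ~ Normal(gamma_j, se_exp_j)
    beta_out_j ~ Normal(theta * gamma_j + alpha_j, se_out_j)

Pleiotropy modes: ``none`` (alpha = 0, all instruments valid), ``balanced``
(mean-zero alpha — IVW remains consistent), ``directional`` (non-zero mean
alpha under InSIDE — biases IVW, detectable via the Egger intercept) and
``inside-violating`` (alpha correlated with gamma — biases Egger too).
``pleiotropy_fraction`` restricts pleiotropy to a random subset of SNPs,
which lets invalid-weight scenarios for the weighted median be posed.

Defaults mirror the packaged real tables: 79 SNPs, exposure |beta| in
[0.012, 0.19] with SEs around 0.002-0.004, outcome SEs 0.009-0.05, allele
frequencies in [0.05, 0.95], roughly a quarter of SNPs palindromic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerRegression, IVWEstimator, WeightedMedianEstimator, pairs_to_frame
from .harmonization import build_analysis_set
from .summary_data import (
    AnalysisConfig,
    InstrumentSet,
    ValidationError,
    VariantAssociation,
    write_summary_table,
)

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "evaluate_estimators"]

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside-violating")


@dataclass
class SimulationConfig:
    """Parameters of one simulated exposure/outcome study pair."""

    n_snps: int = 79
    causal_effect: float = 0.0
    beta_exp_range: tuple[float, float] = (0.012, 0.19)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    se_exp_range: tuple[float, float] = (0.002, 0.004)
    se_out_range: tuple[float, float] = (0.009, 0.05)
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    palindromic_fraction: float = 0.25
    missing_outcome_fraction: float = 0.05
    n_exposure: int = 443_734
    n_outcome: int = 17_035
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ValidationError("n_snps must be >= 3")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("beta_exp_range", "eaf_range", "se_exp_range", "se_out_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: lower bound exceeds upper bound")
        if self.beta_exp_range[0] <= 0 or self.beta_exp_range[0] == self.beta_exp_range[1] == 0:
            raise ValidationError("beta_exp_range must cover positive magnitudes")
        if self.se_exp_range[0] <= 0 or self.se_out_range[0] <= 0:
            raise ValidationError("se scales must be > 0")
        for name in ("pleiotropy_fraction", "palindromic_fraction", "missing_outcome_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class SimulatedStudy:
    """A synthetic exposure/outcome table pair with the generating truth."""

    exposure: InstrumentSet
    outcome: InstrumentSet
    theta: float
    gamma: np.ndarray          # true per-SNP exposure effects
    alpha: np.ndarray          # true per-SNP direct effects
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Serialize both tables through the standard TSV writer."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        exp_path = directory / "exposure.tsv"
        out_path = directory / "outcome.tsv"
        write_summary_table(self.exposure, exp_path)
        write_summary_table(self.outcome, out_path)
        return exp_path, out_path


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if lo == hi:
        return np.full(size, lo)
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig,
                gamma: np.ndarray) -> np.ndarray:
    j = cfg.n_snps
    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, j)
    elif cfg.pleiotropy_mode == "directional":
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, j)
    else:  # inside-violating: direct effects proportional to instrument strength
        alpha = cfg.pleiotropy_mean * gamma / np.mean(np.abs(gamma))
        if cfg.pleiotropy_sd > 0:
            alpha = alpha + rng.normal(0.0, cfg.pleiotropy_sd, j)
    if cfg.pleiotropy_fraction < 1.0:
        invalid = rng.random(j) < cfg.pleiotropy_fraction
        alpha = np.where(invalid, alpha, 0.0)
    return alpha


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one exposure/outcome summary-statistic table pair.

    Fully reproducible from ``config.seed``. The tables serialize through
    the standard readers unchanged, so every pipeline stage downstream of
    file input can be exercised on them.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps

    magnitude = _loguniform(rng, *cfg.beta_exp_range, j)
    if np.ptp(magnitude) == 0 and cfg.beta_exp_range[0] == cfg.beta_exp_range[1] == 0:
        raise ValidationError("degenerate exposure-effect distribution")
    # draw direct effects in the exposure-increasing orientation, then apply
    # the (arbitrary) allele-coding sign to gamma and alpha TOGETHER: flipping
    # a SNP's effect allele negates every effect of that allele, and
    # "directional" pleiotropy is directional w.r.t. the exposure-increasing
    # allele, not w.r.t. the reported coding
    alpha_oriented = _draw_alpha(rng, cfg, magnitude)
    coding = rng.choice([-1.0, 1.0], j)
    gamma = magnitude * coding
    alpha = alpha_oriented * coding

    eaf = rng.uniform(*cfg.eaf_range, j)
    se_exp = rng.uniform(*cfg.se_exp_range, j)
    se_out = rng.uniform(*cfg.se_out_range, j)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.causal_effect * gamma + alpha, se_out)

    n_pal = int(round(cfg.palindromic_fraction * j))
    pal_mask = np.zeros(j, dtype=bool)
    pal_mask[rng.choice(j, n_pal, replace=False)] = True
    missing = rng.random(j) < cfg.missing_outcome_fraction

    exp_records, out_records = [], []
    for i in range(j):
        pool = PALINDROMIC_PAIRS if pal_mask[i] else NON_PALINDROMIC_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        snp = f"rs9{i + 1:06d}"
        z = beta_exp[i] / se_exp[i]
        exp_records.append(VariantAssociation(
            snp=snp, effect_allele=a1, other_allele=a2, eaf=float(eaf[i]),
            beta=float(beta_exp[i]), se=float(se_exp[i]),
            pvalue=max(float(2 * stats.norm.sf(abs(z))), 5e-324),
            n=cfg.n_exposure, chrom=1 + i % 22, pos=10_000 + 1_000 * i,
            gene=f"GENE{i + 1}"))
        if missing[i]:
            out_records.append(VariantAssociation(
                snp=snp, effect_allele=None, other_allele=None,
                chrom=1 + i % 22, pos=10_000 + 1_000 * i))
        else:
            zo = beta_out[i] / se_out[i]
            out_records.append(VariantAssociation(
                snp=snp, effect_allele=a1, other_allele=a2, eaf=float(eaf[i]),
                beta=float(beta_out[i]), se=float(se_out[i]),
                pvalue=max(float(2 * stats.norm.sf(abs(zo))), 5e-324),
                n=cfg.n_outcome, chrom=1 + i % 22, pos=10_000 + 1_000 * i))

    return SimulatedStudy(
        exposure=InstrumentSet(exp_records, provenance=[f"simulated (seed={cfg.seed})"]),
        outcome=InstrumentSet(out_records, provenance=[f"simulated (seed={cfg.seed})"]),
        theta=cfg.causal_effect, gamma=gamma, alpha=alpha, config=cfg,
    )


def evaluate_estimators(
    configs: dict[str, SimulationConfig],
    replicates: int = 1000,
    seed: int = 0,
    estimators: tuple[str, ...] = ("ivw", "weighted-median", "egger"),
    wm_boot: int = 200,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo performance of the MR estimators under known truth.

    For each named scenario, runs ``replicates`` simulated studies through
    harmonization and the selected estimators and reports bias, empirical
    SE, RMSE, 95 % CI coverage and the rejection rate of the no-effect test
    (type-I error when the scenario's causal effect is zero, power
    otherwise). Deterministic given ``seed``.
    """
    if replicates < 2:
        raise ValidationError("replicates must be >= 2")
    z = stats.norm.ppf(1 - alpha_level / 2)
    harmonize_cfg = AnalysisConfig(outcome_name="simulated",
                                   palindrome_policy="assume-forward")
    rows = []
    for scen_idx, (name, cfg) in enumerate(configs.items()):
        estimates: dict[str, list[tuple[float, float]]] = {e: [] for e in estimators}
        egger_intercepts: list[float] = []
        for rep in range(replicates):
            rep_seed = (seed * 1_000_003 + scen_idx * 10_007 + rep) % (2**31 - 1)
            study = simulate_study(replace(cfg, seed=rep_seed))
            pairs, _ = build_analysis_set(study.exposure, study.outcome, harmonize_cfg)
            X = pairs_to_frame(pairs)
            if "ivw" in estimators:
                m = IVWEstimator().fit(X)
                estimates["ivw"].append((m.estimate_, m.se_))
            if "weighted-median" in estimators:
                m = WeightedMedianEstimator(n_boot=wm_boot, random_state=rep_seed).fit(X)
                estimates["weighted-median"].append((m.estimate_, m.se_))
            if "egger" in estimators:
                m = EggerRegression().fit(X)
                estimates["egger"].append((m.estimate_, m.se_))
                egger_intercepts.append(m.intercept_)
        for est_name, vals in estimates.items():
            b = np.array([v[0] for v in vals])
            s = np.array([v[1] for v in vals])
            theta = cfg.causal_effect
            cover = np.mean((b - z * s <= theta) & (theta <= b + z * s))
            reject = np.mean(np.abs(b / s) > z)
            rows.append({
                "scenario": name, "estimator": est_name, "theta": theta,
                "replicates": replicates,
                "mean_estimate": float(b.mean()),
                "bias": float(b.mean() - theta),
                "empirical_se": float(b.std(ddof=1)),
                "rmse": float(np.sqrt(np.mean((b - theta) ** 2))),
                "coverage": float(cover),
                "rejection_rate": float(reject),
                "mean_egger_intercept": float(np.mean(egger_intercepts))
                if est_name == "egger" else math.nan,
            })
    return pd.DataFrame(rows)
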