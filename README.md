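# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of an exposure on an outcome using
genetic variants as instrumental variables, working entirely from published
per-SNP summary statistics (two-sample design). It was built around, and
ships as fixtures, the complete printed input tables of a study of serum
25-hydroxyvitamin D (25(OH)D) and dental caries: an 83-SNP instrument panel
for standardized ln-25(OH)D (n = 443,734) and that panel's association
statistics with three caries outcomes — caries in primary teeth
(n = 17,035 children), caries in permanent teeth in childhood/adolescence
(n = 13,386) and adult caries severity as standardized decayed/missing/
filled tooth-surface (DMFS) counts (n = 26,792).

## What it computes

For each SNP *j* with exposure effect β̂ₓⱼ and outcome effect β̂ᵧⱼ (aligned
to a common effect allele), the Wald ratio and its first-order SE are

    β̂ⱼ = β̂ᵧⱼ / β̂ₓⱼ ,   se(β̂ⱼ) = se(β̂ᵧⱼ) / |β̂ₓⱼ| .

Combined estimators (wⱼ = 1/se(β̂ⱼ)²):

* **IVW**: β̂_IVW = Σwⱼβ̂ⱼ / Σwⱼ — the slope of a weighted through-origin
  regression of β̂ᵧ on β̂ₓ. SE options: fixed-effect √(1/Σwⱼ), or
  (default) multiplicative random effects, the fixed SE scaled by the
  regression's residual scale floored at 1.
* **Weighted median**: the 50 %-weighted quantile of the ordered ratios
  (breakpoints pⱼ = cum(w̃) − w̃ⱼ/2, linear interpolation at 0.5), SE by
  seeded parametric bootstrap; consistent while < 50 % of weight comes
  from invalid instruments.
* **MR-Egger**: WLS of β̂ᵧ on β̂ₓ with a free intercept after orienting
  every β̂ₓ ≥ 0; the slope is the causal estimate under the InSIDE
  assumption and the intercept estimates average directional pleiotropy
  (t reference, J − 2 df).

Around the estimators: tab-separated summary-statistic I/O with
validation; LD-proxy substitution from a user-supplied table
(r² ≥ 0.7 substitutes, below excludes); allele harmonization with
configurable palindromic-SNP policies (`assume-forward`,
`infer-by-frequency` with a frequency-ambiguity window, `drop-all`);
leave-one-out and gene-subset sensitivity analyses; Cochran's Q;
odds-ratio (e^β, CI e^(β±1.96·SE)) and DMFS tooth-surface (19.87 × β)
transforms; instrument strength (per-SNP r² ≈ 2β²ƒ(1−ƒ), F statistics);
and a summary-level simulator with known truth for estimator calibration.

The estimator classes (`IVWEstimator`, `WeightedMedianEstimator`,
`EggerRegression`) follow the scikit-learn protocol (`fit`, fitted
attributes, `get_params`/`set_params`); `ivw`, `weighted_median`, `egger`
are functional wrappers.

## Worked example

```python
import math
from tsmr import build_analysis_set, ivw, wald_ratios
from tsmr.datasets import load_exposure, load_outcome, load_paper_config

config = load_paper_config()
exposure = load_exposure()                       # 83 SNPs
for name, (_, cfg) in config.outcomes.items():
    pairs, excluded = build_analysis_set(exposure, load_outcome(name), cfg)
    res = ivw(wald_ratios(pairs))
    print(f"{name}: J={len(pairs)} beta={res.beta_xy:.5f} "
          f"OR={math.exp(res.beta_xy):.3f} se={res.se:.4f}")
```

prints

```
caries_primary: J=79 beta=0.05137 OR=1.053 se=0.1292
caries_permanent: J=79 beta=-0.00234 OR=0.998 se=0.1194
dmfs: J=78 beta=-0.01584 OR=0.984 se=0.0385
```

i.e. per 1 SD higher genetically proxied ln-25(OH)D: an odds ratio of
about 1.05 for caries in primary teeth, 1.00 for permanent teeth, and
−0.01584 × 19.87 ≈ −0.31 affected tooth surfaces in adults — small
estimates with wide confidence intervals, no evidence of a causal effect.
Note the paediatric analyses retain 79 of the 83 instruments (three SNPs
have no outcome data and no usable proxy, one is missing from the
paediatric GWAS); the adult analysis additionally excludes two palindromic
SNPs whose allele frequencies are too close to 0.5 to resolve strand,
leaving 78.

The same pipeline from a shell:

```bash
tsmr run --out results/ --subset-genes GC,CYP2R1 --seed 1
tsmr report --results-dir results/
```

which emits, per outcome, the harmonized table, an exclusion audit, all
estimator results (full precision + rounded presentation columns), the
leave-one-out forest table and a manifest with input checksums and record
counts.

## Acceptance script

`scripts/acceptance.py` re-runs the whole analysis from the packaged
fixture tables — harmonization, the three estimators per outcome, the
GC/CYP2R1 subset and the variance-explained panel summary — and writes the
resulting headline numbers (odds ratios, tooth-surface estimates, Egger
intercept, total r²) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The `--seed` controls the weighted-median bootstrap; the reported point
estimates are deterministic.

See `docs/methods.md` for the statistical model, the harmonization
policies and their defaults, the simulator's design and known limitations.
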