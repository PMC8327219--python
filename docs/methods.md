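# Methods

## Design

Two-sample Mendelian randomization treats a panel of genetic variants as
instrumental variables for an exposure. Validity rests on three
assumptions per instrument: association with the exposure (relevance),
independence from confounders of the exposure–outcome relation, and no
effect on the outcome except through the exposure (no horizontal
pleiotropy). The package consumes only GWAS summary statistics — per-SNP
effect estimates, standard errors, allele frequencies — from two
non-overlapping studies, one for the exposure and one per outcome.

The packaged analysis instruments standardized natural-log serum 25(OH)D
with 83 conditionally independent SNPs selected at p ≤ 5×10⁻⁸ and minor
allele frequency ≥ 0.05 in European-ancestry GWASs, and tests three dental
outcomes: two binary paediatric caries traits (effects on the log-odds
scale) and adult caries severity as a standardized DMFS residual (SD
scale).

## Data model and I/O

Tables are tab-separated with header
`snp chr pos effect_allele other_allele eaf beta se pvalue n gene`;
missing cells are `NA` (also accepted: empty, `nan`). Alleles are
upper-cased on read (outcome tables print lower-case). Positions are
GRCh37, 1-based; no liftover. A handful of printed exposure p-values lie
below the float64 range (down to 10⁻¹⁶⁸⁹); they are clamped to 5e-324, the
smallest positive double, preserving the p ∈ (0, 1] invariant and every
threshold comparison of interest. Writing uses `repr` round-tripping so
read∘write is the identity.

LD-proxy substitution consumes a caller-supplied `(missing_snp,
proxy_snp, r2)` table plus a lookup panel for the replacement records;
r² ≥ 0.7 (inclusive) substitutes, below excludes, and every action is
logged in the instrument set's provenance. LD computation itself is out
of scope. Note that in the packaged fixtures the four proxy substitutions
are already baked into the printed outcome rows (under the original
rsIDs), which is why those rows' alleles and frequencies can disagree
with the exposure panel.

## Harmonization

The exposure record's effect allele is the reference orientation. The
outcome record is aligned by letters: same order — unchanged; swapped —
beta negated, frequency complemented; otherwise the strand complement is
tried before declaring an allele mismatch (excluded, not an error).

Palindromic SNPs (A/T, C/G) are strand-ambiguous by letters. Policies:

* `assume-forward` — trust the letters (default for the paediatric
  outcomes);
* `infer-by-frequency` — (default for DMFS) a SNP whose configured
  frequency lies in the open ambiguity window is excluded as unresolvable;
  otherwise the allele frequencies determine the strand, and the outcome
  is flipped when the minor-allele side disagrees between the studies;
* `drop-all` — exclude every palindromic SNP.

**Ambiguity window.** The default tests the exposure-side effect-allele
frequency against (0.39, 0.61). The window, and which study's frequency
is tested (`exposure`, `outcome`, `either`), are configurable. This
default was chosen because it is the unique frequency rule that
reproduces the published DMFS instrument count on the printed tables: it
excludes exactly rs10127775 (exposure EAF 0.605) and rs10832289 (0.410),
leaving 78 of 80 SNPs, while either-study windows unavoidably sweep in
palindromic SNPs whose *outcome* frequencies sit near 0.5 only because
those printed rows actually belong to proxy SNPs. With the strand flip
applied (it affects one SNP, rs7650253), the DMFS analysis reproduces the
published estimates to printed precision (IVW −0.0158 SD → −0.31
surfaces; Egger slope −0.78 surfaces; IVW SE 0.0385).

Why the paediatric analyses keep intermediate-frequency palindromic SNPs
while the adult analysis removes them is a property of the source
analysis, not derivable from a single rule; it is therefore explicit
per-outcome configuration (`data/paper.yaml`), not inferred intent.

Bookkeeping invariant: retained + excluded = input panel size, for every
run; the exclusion report lists each dropped SNP with a machine-readable
reason.

## Estimators

* **Wald ratio** β̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order SE se(β̂ᵧⱼ)/|β̂ₓⱼ|. The
  exposure-side sampling error is deliberately ignored (the conventional
  default); the simulator includes exposure noise precisely so this
  approximation's cost can be measured. Instruments with β̂ₓ = 0 are
  excluded with a logged reason during set construction.
* **IVW**: weighted mean of ratios, weights 1/se². Default SE is
  multiplicative random effects — the fixed SE √(1/Σw) times
  max(1, s), where s² = Σw(β̂ⱼ − β̂_IVW)²/(J−1) is the residual scale of
  the weighted through-origin regression; this matches the behaviour of
  the standard analysis software for this design. The point estimate is
  identical across variants. p-values from the normal reference.
  Cochran's Q satisfies Q/(J−1) = s² (tested as a cross-module identity).
* **Weighted median**: sort ratios, normalized weights w̃, breakpoints
  pⱼ = cum(w̃)−w̃ⱼ/2, linear interpolation at 0.5; a breakpoint exactly at
  0.5 returns that ratio, 0.5 outside the breakpoint range clamps to the
  extreme ratio. SE: parametric bootstrap (default 1000 reps), each
  replicate drawing every ratio from Normal(β̂ⱼ, se(β̂ⱼ)) with the weights
  held fixed; seeded and reproducible.
* **MR-Egger**: orient so β̂ₓ ≥ 0 (negate both betas where needed — the
  fit is invariant to the incoming orientation), WLS with intercept,
  weights 1/se(β̂ᵧ)², both SEs scaled by max(1, residual scale), t
  reference with J−2 df. Requires ≥ 3 instruments.

Confidence intervals use the 1.96 multiplier throughout, matching the
printed formulas.

## Transforms and instrument strength

Binary outcomes: OR = e^β, CI = e^(β±1.96·SE). (The published table's OR
CIs are instead consistent with the additive approximation OR ± 1.96·SE;
that form is available as `legacy_additive_ci` for comparison but is not
the default.) DMFS: surfaces = 19.87·β, CI = 19.87·(β±1.96·SE), the
constant being the externally estimated DMFS change per 1 SD of the
standardized score; configurable.

Instrument strength: per-SNP variance explained ≈ 2β²ƒ(1−ƒ) (valid for a
standardized phenotype), summed over the panel; per-SNP F = (β/se)²;
overall F ≈ (R²/(1−R²))·(n−J−1)/J. The total is reported over the full
83-SNP exposure panel (4.4 %) — the variance-explained claim describes
the instrument panel, not any outcome-specific subset; over the 79-SNP
paediatric analysis set it would be 3.4 %. The overall-F formula is the
standard R²-based approximation and is verified only as an F > 10
property, no published formula being available.

Presentation rounding is half-away-from-zero (2 dp for ORs and surfaces,
3 dp for the Egger intercept); full-precision columns are always emitted
alongside.

## Synthetic data

Summary-level generation (no individual genotypes — the analysis never
uses them): per SNP, a true exposure effect γⱼ with log-uniform magnitude
in [0.012, 0.19] (the real panel's range), a direct effect αⱼ per
pleiotropy mode, and observed effects drawn as β̂ₓⱼ ~ N(γⱼ, seₓⱼ),
β̂ᵧⱼ ~ N(θγⱼ + αⱼ, seᵧⱼ) with SE scales matching the real tables
(exposure 0.002–0.004, outcome 0.009–0.05). Allele coding signs are
applied to γ and α *together*: "directional" pleiotropy is directional
with respect to the exposure-increasing allele, which is what makes the
Egger intercept estimate its mean after reorientation. Modes: `none`,
`balanced` (mean-zero), `directional` (non-zero mean, InSIDE holds),
`inside-violating` (α proportional to instrument strength);
`pleiotropy_fraction` confines pleiotropy to a subset of SNPs so
invalid-weight scenarios for the weighted median can be posed. Defaults:
79 SNPs, 25 % palindromic, 5 % missing outcome rows — the shape of the
real tables.

What the simulator does **not** model: LD between instruments, a
liability-scale generative model for binary traits (outcome effects are
drawn directly on the log-OR scale), winner's-curse selection of
instruments, or sample overlap between the two studies. A green
simulation test therefore establishes calibration under independent,
correctly selected instruments, not robustness to those violations.

Measured under the defaults (seeded): IVW type-I error 3.3 % at the
nominal 5 % level (the multiplicative-RE floor is mildly conservative;
the fixed-effect variant gives 3.7 % on the same draws, both inside the
99 % binomial band for 1000 replicates); mean Egger intercept 0.0054
under injected directional pleiotropy of mean 0.005; all three
estimators' bias < 0.01 at θ = 0.1 with no pleiotropy.

## Numerical and design choices

* Estimator input validation rejects non-finite statistics, se ≤ 0 and
  β̂ₓ = 0; single-ratio IVW under the multiplicative model falls back to
  the fixed SE with a logged warning.
* The weighted-median bootstrap and all simulation draws use
  `numpy.random.default_rng` with explicit seeds; identical seeds give
  byte-identical pipeline outputs (the run manifest deliberately contains
  no wall-clock timestamp).
* The leave-one-out outlier flag operationalizes "no single SNP drives
  the estimate" as: an omission whose CI excludes the full-panel point
  estimate.
* The GC/CYP2R1 subset is selected via the `gene` column, not a
  hard-coded rsID list, so user panels work identically; on the fixtures
  it yields 7 paediatric instruments (4 GC + 3 CYP2R1).
* Exact-fit Egger regressions (residual scale 0) keep the unscaled SEs
  rather than dividing by zero.

## Known limitations

* The printed outcome rows for the four proxy-substituted SNPs carry the
  original rsIDs and exposure alleles; reconstructed paediatric estimates
  therefore differ from the published ones in the second decimal place
  (e.g. IVW OR 1.05 vs 1.06). The adult DMFS results reproduce exactly.
* Multi-allelic variants and indels are unsupported; no Steiger
  filtering, MR-PRESSO, mode-based or multivariable MR; no LD-aware IVW
  for correlated instruments.
* The weighted-median SE is a parametric bootstrap at the ratio level;
  alternative bootstraps (resampling both study effects) would give
  slightly different SEs. Point estimates are unaffected.
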