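# Default analysis configuration for the packaged 25(OH)D / dental-caries
# summary-statistic fixtures.
exposure:
  file: vitd_exposure.tsv
  n: 443734

dmfs_scale_factor: 19.87
wm_bootstrap_reps: 1000
rng_seed: 0
ivw_variant: multiplicative-re

# Open frequency window for palindromic-strand ambiguity, tested against the
# exposure-side effect-allele frequency under the infer-by-frequency policy.
ambiguity_low: 0.39
ambiguity_high: 0.61
ambiguity_study: exposure

outcomes:
  caries_primary:
    file: caries_primary_outcome.tsv
    outcome_type: binary
    palindrome_policy: assume-forward
  caries_permanent:
    file: caries_permanent_outcome.tsv
    outcome_type: binary
    palindrome_policy: assume-forward
  dmfs:
    file: dmfs_outcome.tsv
    outcome_type: quantitative
    palindrome_policy: infer-by-frequency
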