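# Default analysis configuration: the standard thresholds of the workflow.
outdir: hexagwas_run
seed: 0
parent_ids: [mother, father]
phenotype_column: rate_cumulative
min_genotype_depth: 20      # per-genotype coverage must exceed this
maf_min: 0.05               # minor allele frequency, strict
max_missing_frac: 0.5       # data required for at least 50% of individuals
het_low: 0.05               # alt-read fraction below -> homozygous reference
het_high: 0.95              # above -> homozygous alternative
distortion_p: 1.0e-10
dist_mean_cov: [60, 200]
dist_parent_cov: 60
dist_maf_min: 0.01
alpha: 0.1                  # Bonferroni family-wise level
ld_threshold: 0.15
ld_window_bp: 5.0e+6
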