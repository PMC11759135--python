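# Template configuration for `caprigen run --config <file>`.
# Exactly one input source must be present: either the `simulation` block
# below, or the pair genotypes_path / phenotypes_path.

# --- option A: simulate the population -----------------------------------
simulation:
  n_individuals: 635        # population size
  n_markers: 5000           # SNP panel size (independent HWE markers)
  n_causal: 500             # causal markers behind the breeding values
  maf_range: [0.05, 0.5]    # allele-frequency range of simulated markers
  epistatic_share: 0.0      # fraction of genetic variance from locus pairs
  missing_rate: 0.0         # fraction of missing genotype calls
  seed: 1
  # genetic_cov / residual_cov / trait_names / trait_means may be given
  # explicitly; defaults are the three udder traits (width, depth, spacing)
  # with heritabilities 0.16 / 0.32 / 0.13.

# --- option B: load real data (comment out `simulation` above) -----------
# genotypes_path: genotypes.vcf      # VCF (GT) or tab-delimited dosage matrix
# genotypes_format: auto             # auto | vcf | dosage
# phenotypes_path: phenotypes.csv    # sample_id, traits, milk_status, birth_year

# --- quality control ------------------------------------------------------
call_rate_min: 0.90         # marker and sample call-rate threshold
maf_min: 0.05               # minor-allele-frequency threshold
hwe_dev_max: 0.15           # |observed - expected| heterozygote frequency

# --- model / evaluation ---------------------------------------------------
blend_weight: 0.95          # G blended as w*G + (1-w)*I for the MME
methods: [gblup, krr, adaboost_rt]
k_folds: 10
seed: 1                     # fold assignment + per-fold method seeds
krr_alpha: 1.0              # KRR ridge parameter
adaboost_phi: 0.1           # Adaboost.RT relative-error threshold
n_estimators: 100           # boosting rounds

out_dir: caprigen_out
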