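# Demo: constant-Ne Wright-Fisher cohort through the full pipeline.
seed: 1
input:
  simulate:
    n_chromosomes: 6
    chrom_length_bp: 10000000
    recomb_rate: 1.0e-8        # 1 cM/Mb
    founder_snps_per_chromosome: 650
    ne_history: [[1, 100]]
    burn_in_generations: 400
    n_output_individuals: 200
sample:
  n_individuals: 200
  missing_rate: 0.02
qc:
  hwe_p_max: 1.0e-6
  missing_max: 0.1
  maf_min: 0.05
  impute_method: mode
ld:
  k_adjacent: 100
  bin_classes: [A, B]
fit:
  init_a: 2.0
meta:
  method: DL
ancestral:
  grid: {lo: 10, hi: 200, n: 12}
  bin_policy: relative
  bin_param: 0.2
  min_pairs: 100
pca:
  enabled: true
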