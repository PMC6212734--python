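# Methods

## The model

Linkage disequilibrium (LD) between two biallelic loci is measured by the
squared allelic correlation

    r² = D² / (p_A p_a p_B p_b),   D = p_AB − p_A p_B,

where p_AB is a haplotype frequency and p_A, p_B are allele frequencies.
In an isolated, randomly mating population at drift–recombination balance,
Sved's approximation links expected LD to effective population size N_e and
recombination distance c (morgans):

    E(r²) ≈ 1 / (1 + 4 N_e c).

The decay model fitted here is the mutation-adjusted form with a free
intercept,

    y_i = 1 / (a + 4 b d_i) + e_i,

where y_i is the r² of SNP pair i at genetic distance d_i. The slope-scale
parameter b estimates current N_e; a absorbs mutation and sampling effects
(a = 1 recovers Sved's curve). The model is fitted per chromosome on
pair-level r² values and the per-chromosome (a, b) are pooled by
DerSimonian–Laird random-effects meta-analysis, chromosomes acting as
independent studies.

Ancestral N_e at t generations before present comes from inverting the Sved
expectation at c = 1/(2t):

    N_T(t) = (1 / 4c) (1 / r²_c − 1),

with r²_c the mean r² of pairs about c morgans apart, pooled across
autosomes. Tight pairs (small c, large t) carry information about distant
history; loose pairs reflect the recent past.

## Pipeline stages and parameters

1. **Input** — PLINK text PED/MAP or VCF (GT field); dosages are coded on
   the minor allele with −1 as the missing sentinel. A per-chromosome
   linkage-map table (physical Mb, genetic cM) supplies cM/Mb rates.
2. **QC** (defaults, all configurable): autosome extraction, then exact
   Hardy–Weinberg test (exclude p ≤ 1e-6), missingness (> 0.1), MAF
   (< 0.05), applied sequentially in that order. The report carries both
   sequential counts (SNP charged to the first filter that removes it) and
   marginal counts (each filter on the full autosomal set); these need not
   be additive when filters overlap. Residual missing calls are imputed —
   per-SNP mode by default (deterministic; ties resolve to the lower
   dosage), or seeded Hardy–Weinberg frequency sampling.
3. **LD** — each SNP is paired with its next k = 100 neighbours on the same
   chromosome. Haplotype frequencies per pair are maximum-likelihood via
   EM; only the double-heterozygote class is phase-ambiguous. Genetic
   distance is position difference after converting base pairs with the
   chromosome-level cM/Mb rate (uniform recombination within a chromosome).
   The finite-sample corrected r² − 1/(2n) (floored at 0) is carried
   alongside raw r².
4. **Decay fit** — unweighted least squares on pair-level raw r² (the
   corrected column and 50-bin means are available behind flags), per
   chromosome, from a = 2 and a method-of-moments b.
5. **Pooling** — inverse-variance fixed-effect and DerSimonian–Laird
   random-effects (default) pooling of a and b separately, normal 95% CIs.
6. **Ancestral trajectory** — log-spaced generation grid (default 10 to
   100,000, 40 points); at each t the pairs within c(1 ± 0.2) are averaged
   (alternative: nearest-m pairs), requiring ≥ 100 pairs per bin; the
   corrected r² is used by default here because the 1/(2n) inflation
   dominates the small r² values at large distances. Points with
   non-positive corrected mean r² (implied infinite N_e) are dropped with a
   log line.

## Numerical choices

- **Exact HWE test**: conditional distribution of the heterozygote count
  given allele counts, computed with log-gamma weights; the p-value sums
  all configurations whose probability does not exceed the observed one
  (within 1e-12 log tolerance). Monomorphic SNPs return p = 1. A 1-df
  chi-square variant is available.
- **EM**: starts from linkage equilibrium, stops when the largest frequency
  change is < 1e-10 or at 1,000 iterations; the EM map preserves observed
  allele-frequency margins exactly, which also underpins the reduced
  one-dimensional likelihood-grid oracle used in tests. Pairs with a
  monomorphic member are skipped and counted.
- **Decay fit**: damped Gauss–Newton (step halving until the objective is
  non-increasing) with b optimized on the log scale for positivity and a
  unconstrained; convergence at relative parameter change < 1e-10, at most
  200 iterations (otherwise flagged and excluded from pooling). Standard
  errors are the residual-variance-scaled inverse Jacobian cross-product on
  the (a, b) scale. On noise-free model data the global optimum is
  recovered to 1e-6 across a ∈ [1, 5], b ∈ [20, 2000].
- **DerSimonian–Laird**: tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with
  fixed-effect weights, then re-weighting by 1/(v + tau²); reduces exactly
  to fixed-effect pooling when Q ≤ k − 1.
- **Binning**: half-open [lo, hi) equal-width bins; a pair exactly on an
  edge belongs to the right bin; empty bins report NaN, never 0. Duplicate
  map positions are kept (ties ordered by SNP id) and zero-distance pairs
  are legal.
- **Determinism**: one seed per run; the simulator forks an independent
  stream per chromosome, so changing one chromosome's SNP count does not
  perturb the others, and downstream stages use fixed offsets of the run
  seed.

## The synthetic-data generator

`ldne.synthetic_data` is a forward-in-time Wright–Fisher diploid simulator:
monoecious random union of gametes (selfing allowed, so census = effective
size each generation), gamete formation by crossovers at Poisson-distributed
breakpoints under a uniform per-bp rate, and a piecewise (constant or
linear) N_e history preceded by a burn-in at the oldest size (default 10×
that size). There is no mutation: founder haplotypes are drawn per SNP from
a uniform(0.05, 0.5) founder MAF distribution at linkage equilibrium —
mirroring the flat post-QC MAF spectrum of dense-chip data — and all LD is
generated by drift, which is exactly the signal the estimator models. SNPs
fixed by drift are dropped with a logged count. A final offspring cohort of
configurable size is bred from the present-day population, so a sampled
cohort can exceed the breeding N_e, as in livestock nucleus herds.

The reference validation scenario (`constant_ne_scenario`) uses N_e = 100,
18 chromosomes of 10 Mb at 1 cM/Mb, 650 founder SNPs per chromosome
(calibrated once so ≈ 2,000 informative SNPs survive drift and MAF
filtering), a 400-generation burn-in, and a 200-individual output cohort.
A full pipeline replicate runs in a few seconds.

What the generator does **not** emulate: mutation (so near-zero-distance LD
is non-stationary and slowly grows with burn-in length rather than reaching
a mutation–drift plateau), array ascertainment bias, farm or family
substructure, overlapping generations, selection, migration, and local
recombination-rate variation. Chromosomes evolve on independent pedigrees,
so between-chromosome LD is absent by construction. Consequently, passing
recovery tests demonstrates correctness of the estimator under its own
model assumptions — not robustness to the violations real livestock data
exhibit.

## Validation design and known limitations

- The simulator was cross-checked against an independent coalescent
  simulator (msprime): binned equilibrium r² at N_e = 100 agrees within
  Monte-Carlo error over the distance range the fits use.
- Constant-N_e recovery: across seeded replicates the pooled b's 95% CI
  covers the true N_e = 100, and the ancestral trajectory is flat within
  replicate-derived Monte-Carlo bands for t ≤ 200 — inside the simulated
  epoch. Beyond the simulated history the trajectory rises toward the
  founders' linkage equilibrium (an effectively infinite ancestral size);
  that is a property of the scenario, not an estimator defect.
- The Sved form is an approximation: relative to the exact
  drift-equilibrium expectation, inverted trajectory points can sit tens of
  percent above the truth at intermediate 4N_e·c even with perfect data.
  The decay fit is less affected because the free intercept a absorbs the
  near-range discrepancy and the distance-scale behaviour identifies b.
  Users should read single trajectory points as order-of-magnitude
  estimates, and the pooled b as the primary current-N_e estimate.
- r² here is the plain EM-based estimate; no kinship or structure
  correction is applied, so cryptic relatedness in real cohorts inflates
  LD and deflates N_e estimates.
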