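# ldne

LD-decay based inference of current and ancestral effective population
size (N_e) from dense diploid SNP genotypes.

Breeders and population geneticists monitor N_e — the size of the
idealized randomly mating population with the same drift/inbreeding rate
as the real one — to manage genetic diversity in closed livestock
populations. When pedigrees are incomplete, N_e can be read off the decay
of linkage disequilibrium (LD) with genetic distance: under random mating
Sved's approximation gives E(r²) ≈ 1/(1 + 4 N_e c) for loci c morgans
apart. `ldne` implements the full estimation pipeline around that model:

1. **QC** — autosome extraction, exact Hardy–Weinberg test (p ≤ 1e-6),
   missingness (> 0.1) and MAF (< 0.05) filters, mode or Hardy–Weinberg
   imputation of residual missing calls;
2. **LD** — pairwise r² = D²/(p_A p_a p_B p_b) over each SNP's next 100
   neighbours, via two-locus EM haplotype-frequency estimation from
   unphased genotypes, with the optional finite-sample correction
   r² − 1/(2n);
3. **distances** — chromosome-level cM/Mb conversion of physical
   positions, plus 50-bin distance summaries;
4. **decay fit** — per-chromosome non-linear least squares of the
   mutation-adjusted model y_i = 1/(a + 4 b d_i) + e_i (b estimates
   current N_e);
5. **pooling** — inverse-variance / DerSimonian–Laird meta-analysis of
   (a, b) across chromosomes;
6. **ancestral N_e** — inversion N_T(t) = (1/4c)(1/r²_c − 1) at
   c = 1/(2t) over a log-spaced generation grid.

A forward-in-time Wright–Fisher diploid simulator with recombination and
configurable N_e histories (`ldne.synthetic_data`) generates cohorts with
known ground truth, so the whole pipeline is validated by parameter
recovery. See `docs/methods.md` for the model details, numerical choices
and limitations.

## Worked example

```python
from ldne.synthetic_data import constant_ne_scenario, simulate_population, sample_genotypes
from ldne.qc import QcThresholds, apply_filters, impute_missing
from ldne.ld_engine import mb_to_cm, compute_ld_table
from ldne.decay_fit import fit_all_chromosomes
from ldne.meta_pool import pool_parameters
from ldne.ancestral_ne import build_trajectory

cohort = simulate_population(constant_ne_scenario(ne=100, seed=1))
G, snp_map = sample_genotypes(cohort, 200, missing_rate=0.02, seed=1001)
G, snp_map, report = apply_filters(G, snp_map, QcThresholds())
G = impute_missing(G)
snp_map = mb_to_cm(snp_map, cohort.chrom_map)
pairs = compute_ld_table(G, snp_map, k=100)
pooled_a, pooled_b = pool_parameters(fit_all_chromosomes(pairs))
print(f"retained {report.n_retained} SNPs, {len(pairs)} pairs, mean r2 = {pairs.r2.mean():.3f}")
print(f"a = {pooled_a}, current Ne (b) = {pooled_b}")
traj = build_trajectory(pairs, generation_grid=[10, 30, 100])
print(traj[["t", "n_pairs", "mean_r2", "nt"]].round(3).to_string(index=False))
```

prints

```
retained 1823 SNPs, 98103 pairs, mean r2 = 0.159
a = 1.16 (1.10; 1.23), current Ne (b) = 115.13 (87.92; 142.33)
    t  n_pairs  mean_r2      nt
 10.0    18091    0.041 118.117
 30.0    11493    0.114 116.659
100.0     5071    0.252 148.577
```

The cohort was bred at a true N_e of 100: the pooled decay parameter b
estimates the current N_e as 115 with a 95% CI (88, 142) that covers the
truth, and the inverted trajectory N_T(t) stays near 100 across recent
generations (single points carry both Monte-Carlo noise and the Sved
approximation's upward bias at intermediate distances — see
`docs/methods.md`).

The same run is available from the shell, end to end or stage by stage:

```sh
ldne all -c examples/constant_ne.yaml -o run/
ldne simulate -c examples/constant_ne.yaml -o run2/   # then qc, ld, fit, pool, ancestral, report
```

The artifact directory holds every intermediate table as TSV
(`qc_report.tsv`, `ld_pairs.tsv`, `bins_A/B.tsv`, `fits.tsv`,
`pooled.tsv`, `trajectory.tsv`), the run manifest, and the five report
figures (binned decay, SNPs per chromosome, per-chromosome parameters,
predicted vs observed r², N_e trajectory). Reruns with the same config
and seed reproduce all tables bit-identically.

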