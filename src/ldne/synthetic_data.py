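"""Forward-in-time Wright-Fisher diploid simulator with recombination.

Generates genotype cohorts whose linkage disequilibrium is produced by
genetic drift on standing variation under a configurable effective-size
history, which is exactly the statistical structure the LD-decay
pipeline assumes: at drift-recombination balance the expected r^2
between loci c morgans apart is approximately 1/(1 + 4*Ne*c).

Model choices:

- monoecious random union of gametes (selfing allowed), so the census
  size IS the effective size each generation;
- gametes form by crossover at Poisson-distributed breakpoints with a
  uniform per-bp recombination rate per chromosome;
- no mutation: founder haplotypes are drawn per SNP from a founder MAF
  distribution at linkage equilibrium, and LD then accumulates by drift
  during burn-in; SNPs fixed by drift are dropped from the output;
- chromosomes evolve on independent random streams, so changing the
  SNP count on one chromosome does not perturb the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ldne.io_formats import (
    MISSING,
    GenotypeMatrix,
    _polarize_to_minor,
    make_chrom_map_table,
    make_snp_map,
)

logger = logging.getLogger(__name__)


@dataclass
class DemographicScenario:
    """Ground-truth demography and marker layout for one simulation.

    Attributes
    ----------
    chromosomes
        One ``(length_bp, recomb_rate_morgans_per_bp)`` per chromosome
        (1e-8 M/bp = 1 cM/Mb).
    snp_counts
        Founder SNP count per chromosome (before drift losses).
    ne_history
        ``(generations_before_present, Ne)`` breakpoints, generations
        strictly increasing; sizes between breakpoints follow
        ``interpolation`` ("constant" steps or "linear" ramps), and the
        oldest Ne extends back through burn-in.
    burn_in_generations
        Generations at the oldest Ne before the history starts; default
        10x the oldest Ne.
    founder_maf_range
        Uniform (lo, hi) founder minor-allele-frequency distribution.
    n_output_individuals
        Size of the final offspring cohort bred from the present-day
        population (lets a sampled cohort exceed the breeding Ne, as in
        livestock nucleus populations); default: the present-day census.
    """

    chromosomes: list[tuple[int, float]]
    snp_counts: list[int]
    ne_history: list[tuple[int, int]]
    interpolation: str = "constant"
    burn_in_generations: int | None = None
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_output_individuals: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.snp_counts):
            raise ValueError("snp_counts must align with chromosomes")
        for length, rate in self.chromosomes:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
            if rate < 0:
                raise ValueError("recombination rates must be non-negative")
        for m, (length, _) in zip(self.snp_counts, self.chromosomes):
            if m > length:
                raise ValueError(
                    f"cannot place {m} SNPs at distinct positions on a {length} bp chromosome"
                )
        if not self.ne_history:
            raise ValueError("ne_history must have at least one breakpoint")
        gens = [g for g, _ in self.ne_history]
        if sorted(set(gens)) != gens:
            raise ValueError("ne_history generations must be strictly increasing")
        if any(ne < 2 for _, ne in self.ne_history):
            raise ValueError("all Ne values must be >= 2")
        if self.interpolation not in ("constant", "linear"):
            raise ValueError("interpolation must be 'constant' or 'linear'")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder MAF range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def oldest_ne(self) -> int:
        return self.ne_history[-1][1]

    def size_at(self, g: float) -> int:
        """Population size g generations before present."""
        gens = np.array([p[0] for p in self.ne_history], dtype=float)
        sizes = np.array([p[1] for p in self.ne_history], dtype=float)
        if g >= gens[-1]:
            return int(round(sizes[-1]))
        if self.interpolation == "linear":
            return max(2, int(round(float(np.interp(g, gens, sizes)))))
        # constant: value of the nearest breakpoint at or after g
        idx = int(np.searchsorted(gens, g, side="left"))
        return int(round(sizes[idx]))


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    snp_map: pd.DataFrame
    chrom_map: pd.DataFrame
    truth: DemographicScenario
    n_monomorphic_dropped: int = 0
    haplotypes: list[np.ndarray] = field(default_factory=list, repr=False)


def _next_generation(
    rng: np.random.Generator,
    hap: np.ndarray,
    pos_morgans: np.ndarray,
    genetic_length: float,
    n_offspring: int,
) -> np.ndarray:
    """Breed one Wright-Fisher generation; returns (2*n_offspring, m) haplotypes."""
    n_parents = hap.shape[0] // 2
    parents = rng.integers(0, n_parents, size=2 * n_offspring)
    n_crossovers = rng.poisson(genetic_length, size=2 * n_offspring)
    starts = rng.integers(0, 2, size=2 * n_offspring)
    out = np.empty((2 * n_offspring, hap.shape[1]), dtype=hap.dtype)
    plain = n_crossovers == 0
    out[plain] = hap[2 * parents[plain] + starts[plain]]
    for g in np.flatnonzero(~plain):
        breaks = np.sort(rng.uniform(0.0, genetic_length, n_crossovers[g]))
        side = (starts[g] + np.searchsorted(breaks, pos_morgans)) % 2
        h = hap[2 * parents[g] : 2 * parents[g] + 2]
        out[g] = np.where(side == 0, h[0], h[1])
    return out


def simulate_population(scenario: DemographicScenario) -> SimulatedCohort:
    """Evolve the scenario from the past to the present and return the cohort.

    The population starts as linkage-equilibrium founder haplotypes at
    the oldest Ne, burns in at that size, then follows the Ne history
    down to the present; a final offspring cohort of
    ``n_output_individuals`` is bred from the present-day population.
    Identical seeds give bit-identical output.  SNPs monomorphic in the
    output cohort are dropped with a logged count.
    """
    history_span = scenario.ne_history[-1][0]
    burn_in = (
        scenario.burn_in_generations
        if scenario.burn_in_generations is not None
        else 10 * scenario.oldest_ne
    )
    n_out = (
        scenario.n_output_individuals
        if scenario.n_output_individuals is not None
        else scenario.size_at(0)
    )
    streams = np.random.SeedSequence(scenario.seed).spawn(len(scenario.chromosomes))

    genotype_blocks, hap_blocks = [], []
    ids, chroms, positions = [], [], []
    lo, hi = scenario.founder_maf_range
    for ci, ((length_bp, rate), m, stream) in enumerate(
        zip(scenario.chromosomes, scenario.snp_counts, streams), start=1
    ):
        rng = np.random.default_rng(stream)
        pos_bp = np.sort(rng.choice(np.int64(length_bp), size=m, replace=False)) + 1
        pos_m = pos_bp * rate
        genetic_length = length_bp * rate

        founder_freq = rng.uniform(lo, hi, size=m)
        n0 = scenario.size_at(history_span + burn_in)
        hap = (rng.random((2 * n0, m)) < founder_freq).astype(np.uint8)
        for g in range(history_span + burn_in - 1, -1, -1):
            hap = _next_generation(rng, hap, pos_m, genetic_length, scenario.size_at(g))
        hap = _next_generation(rng, hap, pos_m, genetic_length, n_out)

        genotype_blocks.append(hap[0::2] + hap[1::2])
        hap_blocks.append(hap)
        ids.extend(f"chr{ci}_snp{s}" for s in range(m))
        chroms.extend([str(ci)] * m)
        positions.extend(pos_bp.tolist())

    geno = np.concatenate(genotype_blocks, axis=1).astype(np.int8)
    poly = np.ptp(geno, axis=0) > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("simulate_population: dropped %d SNPs monomorphic after drift", n_dropped)
    snp_map = make_snp_map(
        np.asarray(ids)[poly], np.asarray(chroms)[poly], np.asarray(positions)[poly], sort=True
    )
    # columns already follow (chromosome, position) order by construction
    keep_cols = np.flatnonzero(poly)
    # report dosages on the minor allele, the package-wide coding convention
    G = GenotypeMatrix(
        _polarize_to_minor(geno[:, keep_cols]), [f"ind_{i}" for i in range(n_out)]
    )
    chrom_map = make_chrom_map_table(
        [str(i) for i in range(1, len(scenario.chromosomes) + 1)],
        [length / 1e6 for length, _ in scenario.chromosomes],
        [length * rate * 100.0 for length, rate in scenario.chromosomes],
    )
    return SimulatedCohort(
        genotypes=G,
        snp_map=snp_map,
        chrom_map=chrom_map,
        truth=scenario,
        n_monomorphic_dropped=n_dropped,
        haplotypes=hap_blocks,
    )


def sample_genotypes(
    cohort: SimulatedCohort, n_individuals: int, missing_rate: float = 0.0, seed: int = 0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw individuals without replacement and mask calls at random.

    Each genotype is independently set to missing with probability
    ``missing_rate``.
    """
    G = cohort.genotypes
    if n_individuals > G.n:
        raise ValueError(f"cannot sample {n_individuals} from a cohort of {G.n}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = rng.choice(G.n, size=n_individuals, replace=False)
    values = G.values[rows].copy()
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = MISSING
    # re-polarize: subsampling and masking can flip which allele is minor
    sampled = GenotypeMatrix(
        _polarize_to_minor(values), [G.sample_ids[i] for i in rows]
    )
    return sampled, cohort.snp_map.copy()


def inject_qc_defects(
    G: GenotypeMatrix, snp_map: pd.DataFrame, defects: dict, seed: int = 0
) -> GenotypeMatrix:
    """Corrupt listed SNP columns to exercise the QC filters.

    ``defects`` keys (all optional; exactly the listed SNPs are altered):

    - ``"hwe_all_het"``: indices -> all-heterozygote columns;
    - ``"hwe_no_het"``: indices -> half 0s / half 2s, no heterozygotes;
    - ``"low_maf"``: ``(index, target_maf)`` -> exactly
      round(2*n*target_maf) minor alleles placed as heterozygotes;
    - ``"high_missing"``: ``(index, rate)`` -> exactly round(rate*n)
      missing calls.
    """
    known = {"hwe_all_het", "hwe_no_het", "low_maf", "high_missing"}
    unknown = set(defects) - known
    if unknown:
        raise ValueError(f"unknown defect kinds: {sorted(unknown)}")
    v = G.values.copy()
    n = G.n

    def _check(idx: int) -> int:
        if not 0 <= idx < G.n_snps:
            raise IndexError(f"SNP index {idx} out of range [0, {G.n_snps})")
        return int(idx)

    rng = np.random.default_rng(seed)
    for idx in defects.get("hwe_all_het", []):
        v[:, _check(idx)] = 1
    for idx in defects.get("hwe_no_het", []):
        col = np.zeros(n, dtype=np.int8)
        col[: n // 2] = 2
        rng.shuffle(col)
        v[:, _check(idx)] = col
    for idx, target in defects.get("low_maf", []):
        col = np.zeros(n, dtype=np.int8)
        carriers = rng.choice(n, size=min(n, int(round(2 * n * target))), replace=False)
        col[carriers] = 1
        v[:, _check(idx)] = col
    for idx, rate in defects.get("high_missing", []):
        holes = rng.choice(n, size=int(round(rate * n)), replace=False)
        v[holes, _check(idx)] = MISSING
    return GenotypeMatrix(v, list(G.sample_ids))


def constant_ne_scenario(
    ne: int = 100,
    n_chromosomes: int = 18,
    founder_snps_per_chromosome: int = 650,
    chrom_length_bp: int = 10_000_000,
    recomb_rate: float = 1e-8,
    burn_in_generations: int = 400,
    n_output_individuals: int = 200,
    seed: int = 0,
) -> DemographicScenario:
    """Reference validation scenario: constant Ne with 1 cM/Mb chromosomes.

    Founder SNP counts are set so that, after drift losses during burn-in
    and MAF filtering, roughly 2,000 informative SNPs remain genome-wide
    at the defaults.
    """
    return DemographicScenario(
        chromosomes=[(chrom_length_bp, recomb_rate)] * n_chromosomes,
        snp_counts=[founder_snps_per_chromosome] * n_chromosomes,
        ne_history=[(1, ne)],
        interpolation="constant",
        burn_in_generations=burn_in_generations,
        n_output_individuals=n_output_individuals,
        seed=seed,
    )
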