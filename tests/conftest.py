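"""Shared fixtures: small simulated cohorts and toy genotype files."""

import numpy as np
import pytest

from ldne.io_formats import GenotypeMatrix
from ldne.synthetic_data import (
    DemographicScenario,
    sample_genotypes,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-chromosome constant-Ne cohort, small enough for fast unit tests."""
    scenario = DemographicScenario(
        chromosomes=[(5_000_000, 1e-8), (5_000_000, 1e-8)],
        snp_counts=[220, 220],
        ne_history=[(1, 50)],
        burn_in_generations=150,
        n_output_individuals=80,
        seed=7,
    )
    return simulate_population(scenario)


@pytest.fixture(scope="session")
def small_sample(small_cohort):
    """Sampled genotypes (with a little missingness) plus their map."""
    G, snp_map = sample_genotypes(small_cohort, 60, missing_rate=0.03, seed=11)
    return G, snp_map


@pytest.fixture()
def hw_genotypes():
    """Factory for Hardy-Weinberg genotype columns at a given MAF."""

    def _make(n: int, maf: float, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.binomial(2, maf, size=n).astype(np.int8)

    return _make


@pytest.fixture()
def toy_ped_map(tmp_path):
    """Hand-written 3-individual, 4-SNP PED/MAP pair with known dosages.

    SNP1: A is the rarer allele (2 of 6) -> dosages (2, 0, 0)
    SNP2: A rarer (2 of 6) -> (1, 0, 1)
    SNP3: monomorphic C -> (0, 0, 0)
    SNP4: one missing call; C rarer among called alleles -> (MISSING, 1, 0)
    """
    map_path = tmp_path / "toy.map"
    map_path.write_text(
        "1\tsnp1\t0\t1000\n1\tsnp2\t0\t2000\n1\tsnp3\t0\t3000\n2\tsnp4\t0\t500\n"
    )
    ped_path = tmp_path / "toy.ped"
    ped_path.write_text(
        "f1 i1 0 0 0 -9 A A A C C C 0 0\n"
        "f1 i2 0 0 0 -9 C C C C C C A C\n"
        "f1 i3 0 0 0 -9 C C A C C C A A\n"
    )
    expected = np.array(
        [[2, 1, 0, -1], [0, 0, 0, 1], [0, 1, 0, 0]], dtype=np.int8
    )
    return ped_path, map_path, expected


def write_vcf(path, G: GenotypeMatrix, snp_map) -> None:
    """Write a minimal VCF with REF=B / ALT=A mirroring write_ped_map's coding."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(snp_map["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, row in enumerate(snp_map.itertuples()):
            calls = "\t".join(gt[int(g)] for g in G.values[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position_bp}\t{row.id}\tB\tA\t.\tPASS\t.\tGT\t{calls}\n"
            )
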