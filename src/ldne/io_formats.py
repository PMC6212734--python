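"""Readers and writers for genotype, map and pipeline table formats.

Every format-dialect decision lives here: PLINK text PED/MAP, VCF (GT
field only), the per-chromosome linkage-map TSV, and the tab-separated
tables the pipeline stages persist.

Genotypes are held as minor-allele dosages in {0, 1, 2} with ``MISSING``
(-1) as the explicit missing sentinel.  Polarization to the minor allele
is fixed at load time; r^2 is invariant to allele labelling, so QC
subsetting never requires re-polarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

SNP_MAP_COLUMNS = ["id", "chromosome", "position_bp", "position_morgans"]


class FormatError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. chromosome absent from a map table)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix.

    Attributes
    ----------
    values
        ``(n_individuals, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Unique per-individual identifiers, one per row.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x SNPs)")
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must equal the number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.values[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}; expected 0/1/2/{MISSING}")

    @property
    def n(self) -> int:
        """Sample size — the *n* of the r^2 - 1/(2n) finite-sample correction."""
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, index], list(self.sample_ids))

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[index, :], [self.sample_ids[i] for i in np.asarray(index)]
        )


def make_snp_map(
    ids, chromosomes, positions_bp, positions_morgans=None, sort: bool = True
) -> pd.DataFrame:
    """Assemble and validate a SNP map table.

    Within each chromosome rows are sorted by base-pair position; SNPs at
    duplicated positions are kept and ordered by id so the sort is stable
    and idempotent (zero-distance pairs are legitimate downstream).
    """
    snp_map = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=str),
            "chromosome": np.asarray(chromosomes, dtype=str),
            "position_bp": np.asarray(positions_bp, dtype=np.int64),
            "position_morgans": (
                np.full(len(ids), np.nan)
                if positions_morgans is None
                else np.asarray(positions_morgans, dtype=float)
            ),
        }
    )
    if (snp_map["position_bp"] < 0).any():
        raise ValueError("base-pair positions must be non-negative")
    if snp_map["id"].duplicated().any():
        dups = snp_map.loc[snp_map["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate SNP ids: {dups[:5]}")
    if sort:
        snp_map = sort_snp_map(snp_map)
    return snp_map


def sort_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chromosome, position, id); stable and idempotent."""
    return snp_map.sort_values(
        ["chromosome", "position_bp", "id"], kind="mergesort"
    ).reset_index(drop=True)


def _polarize_to_minor(dosage: np.ndarray) -> np.ndarray:
    """Flip columns so dosage counts the minor allele (ties keep coding)."""
    dosage = dosage.astype(np.int8, copy=True)
    observed = dosage != MISSING
    with np.errstate(invalid="ignore"):
        n_obs = observed.sum(axis=0)
        alt_sum = np.where(observed, dosage, 0).sum(axis=0)
    # allele frequency of the currently counted allele among observed calls
    freq = np.divide(alt_sum, 2.0 * n_obs, out=np.zeros(dosage.shape[1]), where=n_obs > 0)
    flip = freq > 0.5
    cols = dosage[:, flip]
    cols[cols != MISSING] = 2 - cols[cols != MISSING]
    dosage[:, flip] = cols
    return dosage


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK text PED/MAP into a minor-allele dosage matrix and SNP map.

    The MAP genetic-position column is ignored: genetic positions are
    always derived later from chromosome-level cM/Mb rates.  The PED
    missing allele code ``0`` maps to :data:`MISSING`.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            map_rows.append((parts[1], parts[0], int(parts[3])))
    ids = [r[0] for r in map_rows]
    m = len(ids)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 header + 2 alleles x {m} SNPs), got {len(parts)}"
                )
            sample_ids.append(f"{parts[0]}_{parts[1]}")
            allele_rows.append(parts[6:])

    alleles = np.array(allele_rows, dtype="U8").reshape(len(sample_ids), m, 2)
    dosage = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        called = col[col != "0"]
        distinct = np.unique(called)
        if len(distinct) > 2:
            raise FormatError(f"SNP {ids[j]}: more than two alleles observed: {distinct.tolist()}")
        if len(distinct) == 0:
            continue  # all-missing column stays MISSING
        obs = (col != "0").all(axis=1)
        if len(distinct) == 1:
            # monomorphic: the minor allele is the unobserved one, dosage 0
            dosage[obs, j] = 0
            continue
        # counted allele: the rarer one; lexicographic tiebreak for determinism
        counts = [(np.sum(called == a), a) for a in distinct]
        counts.sort(key=lambda t: (t[0], t[1]))
        minor = counts[0][1]
        dosage[obs, j] = (col[obs] == minor).sum(axis=1)

    G = GenotypeMatrix(dosage, sample_ids)
    snp_map = make_snp_map(
        [r[0] for r in map_rows], [r[1] for r in map_rows], [r[2] for r in map_rows], sort=False
    )
    order = sort_snp_map(snp_map.assign(_col=np.arange(m)))
    return G.subset_snps(order["_col"].to_numpy()), order.drop(columns="_col")


def write_ped_map(G: GenotypeMatrix, snp_map: pd.DataFrame, ped_path, map_path) -> None:
    """Write PED/MAP with alleles A (counted/minor) and B; missing as '0 0'."""
    with open(map_path, "w") as fh:
        for row in snp_map.itertuples():
            fh.write(f"{row.chromosome}\t{row.id}\t0\t{row.position_bp}\n")
    allele_strings = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            fields.extend(allele_strings[int(g)] for g in G.values[i])
            fh.write(" ".join(fields) + "\n")


def read_vcf(vcf_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF (GT field) into the same representation as :func:`read_ped_map`.

    Non-biallelic records are skipped with a logged count; ALT dosages are
    re-polarized to minor-allele dosages so PED/MAP and VCF exports of the
    same cohort load identically.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    ids, chroms, positions = [], [], []
    columns = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        if variant.format("GT") is None and variant.gt_types is None:
            raise FormatError(f"record {variant.CHROM}:{variant.POS} has no GT field")
        gts = np.asarray(variant.gt_types, dtype=np.int8)  # 0/1/2 = ALT count, 3 = missing
        gts[gts == 3] = MISSING
        columns.append(gts)
        ids.append(variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not columns:
        raise FormatError(f"{vcf_path}: no biallelic GT records found")
    dosage = _polarize_to_minor(np.column_stack(columns))
    G = GenotypeMatrix(dosage, sample_ids)
    snp_map = make_snp_map(ids, chroms, positions, sort=False)
    order = sort_snp_map(snp_map.assign(_col=np.arange(len(ids))))
    return G.subset_snps(order["_col"].to_numpy()), order.drop(columns="_col")


def read_linkage_map(table_path) -> pd.DataFrame:
    """Read the per-chromosome linkage-map table and derive cM/Mb rates.

    Expects tab-separated columns ``chromosome``, ``physical_mb``,
    ``genetic_cm``; adds ``rate_cm_per_mb = genetic_cm / physical_mb``.
    """
    table = pd.read_csv(table_path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "physical_mb", "genetic_cm"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"{table_path}: expected columns {sorted(required)}, found {list(table.columns)}"
        )
    return make_chrom_map_table(table["chromosome"], table["physical_mb"], table["genetic_cm"])


def make_chrom_map_table(chromosomes, physical_mb, genetic_cm) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "chromosome": np.asarray(chromosomes, dtype=str),
            "physical_mb": np.asarray(physical_mb, dtype=float),
            "genetic_cm": np.asarray(genetic_cm, dtype=float),
        }
    )
    if (table["physical_mb"] <= 0).any() or (table["genetic_cm"] <= 0).any():
        raise ValueError("chromosome physical and genetic lengths must be positive")
    table["rate_cm_per_mb"] = table["genetic_cm"] / table["physical_mb"]
    return table


def write_table(records: pd.DataFrame, path) -> None:
    """Persist a pipeline table as tab-separated UTF-8 with a header.

    Floats are written at full (shortest round-tripping) precision, so
    read-back reproduces integers bit-identically and reals to well below
    1e-12.
    """
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
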