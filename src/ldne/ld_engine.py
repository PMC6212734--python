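"""Pairwise linkage disequilibrium from unphased genotypes.

r^2 = D^2 / (p_A p_a p_B p_b) with D = p_AB - p_A p_B is computed from
maximum-likelihood two-locus haplotype frequencies.  Unphased diploid
genotypes leave only the double-heterozygote class phase-ambiguous, and
the EM algorithm resolves it; all other genotype classes contribute
haplotypes unambiguously.

Each SNP is paired with its next ``k`` (default 100) neighbours on the
same chromosome.  Genetic distances come from chromosome-level cM/Mb
conversion rates (uniform recombination within a chromosome); pairs are
summarized in 50 half-open distance bins per bin class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ldne.io_formats import ConfigurationError, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Named distance-bin classes: (lo_mb, hi_mb, n_bins).
BIN_CLASSES: dict[str, tuple[float, float, int]] = {
    "A": (0.0, 0.5, 50),  # 0-0.5 Mb in 0.01 Mb bins
    "B": (0.0, 5.0, 50),  # 0-5 Mb in 0.1 Mb bins
}

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFreqs:
    """ML two-locus haplotype frequencies and derived quantities."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n_obs: int

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    @property
    def D(self) -> float:
        return self.p_AB - self.p_A * self.p_B


class DegeneratePairError(ValueError):
    """A locus in the pair is monomorphic; r^2 is undefined."""


def _pair_genotype_counts(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts flattened as code 3*g_i + g_j."""
    codes = 3 * col_i.astype(np.int64) + col_j.astype(np.int64)
    return np.bincount(codes, minlength=9).astype(float)


def _em_core(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EM over a batch of pairs.

    Parameters
    ----------
    counts
        ``(n_pairs, 9)`` joint genotype counts, code ``3*g_i + g_j`` with
        dosages counting alleles A (locus 1) and B (locus 2).

    Returns
    -------
    freqs : ``(n_pairs, 4)`` haplotype frequencies (AB, Ab, aB, ab)
    n_obs : individuals per pair
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=1)
    # c columns: (g_i, g_j) = (0,0),(0,1),(0,2),(1,0),(1,1),(1,2),(2,0),(2,1),(2,2)
    n_dh = c[:, 4]  # double heterozygotes: the only phase-ambiguous class
    # unambiguous haplotype counts
    base_AB = 2 * c[:, 8] + c[:, 7] + c[:, 5]
    base_Ab = 2 * c[:, 6] + c[:, 7] + c[:, 3]
    base_aB = 2 * c[:, 2] + c[:, 1] + c[:, 5]
    base_ab = 2 * c[:, 0] + c[:, 1] + c[:, 3]
    two_n = 2.0 * n

    p_A = (base_AB + base_Ab + n_dh) / two_n
    p_B = (base_AB + base_aB + n_dh) / two_n
    # linkage-equilibrium start
    f = np.column_stack(
        [p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)]
    )
    active = np.ones(len(c), dtype=bool)
    for _ in range(EM_MAX_ITER):
        if not active.any():
            break
        fa = f[active]
        coup = fa[:, 0] * fa[:, 3]
        rep = fa[:, 1] * fa[:, 2]
        denom = coup + rep
        q = np.where(denom > 0, coup / np.where(denom > 0, denom, 1.0), 0.5)
        nd = n_dh[active]
        new = np.column_stack(
            [
                base_AB[active] + q * nd,
                base_Ab[active] + (1 - q) * nd,
                base_aB[active] + (1 - q) * nd,
                base_ab[active] + q * nd,
            ]
        ) / two_n[active, None]
        delta = np.abs(new - fa).max(axis=1)
        f[active] = new
        still = delta >= EM_TOL
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return f, n.astype(int)


def _loglik(counts: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Multinomial genotype log-likelihood under random mating."""
    f = np.asarray(freqs, dtype=float)
    pAB, pAb, paB, pab = f[..., 0], f[..., 1], f[..., 2], f[..., 3]
    class_p = np.stack(
        [
            pab**2,  # (0,0)
            2 * paB * pab,  # (0,1)
            paB**2,  # (0,2)
            2 * pAb * pab,  # (1,0)
            2 * pAB * pab + 2 * pAb * paB,  # (1,1)
            2 * pAB * paB,  # (1,2)
            pAb**2,  # (2,0)
            2 * pAB * pAb,  # (2,1)
            pAB**2,  # (2,2)
        ],
        axis=-1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(class_p > 0, np.log(np.where(class_p > 0, class_p, 1.0)), -np.inf)
        terms = np.where(counts > 0, counts * np.where(counts > 0, logp, 0.0), 0.0)
    return terms.sum(axis=-1)


def em_haplotype_freqs(col_i: np.ndarray, col_j: np.ndarray) -> HaplotypeFreqs:
    """ML haplotype frequencies for one SNP pair from complete dosage columns.

    Starts from linkage equilibrium and iterates EM until the largest
    frequency change is below 1e-10 (or 1,000 iterations); the genotype
    log-likelihood is non-decreasing across iterations.
    """
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    if col_i.shape != col_j.shape:
        raise ValueError("columns must have equal length")
    if not (np.isin(col_i, (0, 1, 2)).all() and np.isin(col_j, (0, 1, 2)).all()):
        raise ValueError("columns must be complete (imputed) dosages in {0,1,2}")
    for name, col in (("i", col_i), ("j", col_j)):
        if np.all(col == col[0]):
            raise DegeneratePairError(f"locus {name} is monomorphic")
    counts = _pair_genotype_counts(col_i, col_j)[None, :]
    f, n = _em_core(counts)
    return HaplotypeFreqs(float(f[0, 0]), float(f[0, 1]), float(f[0, 2]), float(f[0, 3]), int(n[0]))


def r2_from_freqs(h: HaplotypeFreqs) -> float:
    """Squared allelic correlation r^2 = D^2 / (p_A p_a p_B p_b)."""
    p_A, p_B = h.p_A, h.p_B
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    if denom <= 0:
        raise DegeneratePairError("r^2 undefined: an allele frequency is 0")
    return float(min(1.0, max(0.0, h.D**2 / denom)))


def adjacent_pairs(snp_map: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Forward-looking pairs: each SNP with its next ``k`` same-chromosome SNPs.

    Returns integer row indices into ``snp_map`` (columns ``i``, ``j``,
    i < j in map order); no pair appears twice.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ii, jj = [], []
    for _, idx in snp_map.groupby("chromosome", sort=False).indices.items():
        m = len(idx)
        for off in range(1, min(k, m - 1) + 1):
            ii.append(idx[: m - off])
            jj.append(idx[off:])
    if not ii:
        return pd.DataFrame({"i": [], "j": []}, dtype=np.int64)
    return pd.DataFrame({"i": np.concatenate(ii), "j": np.concatenate(jj)})


def mb_to_cm(snp_map: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    """Fill ``position_morgans`` from chromosome-level cM/Mb rates.

    position_morgans = position_bp * rate_cm_per_mb / (1e6 * 100); pair
    genetic distance is then the simple difference of positions (uniform
    recombination rate within each chromosome).
    """
    missing = set(snp_map["chromosome"].unique()) - set(rates["chromosome"].astype(str))
    if missing:
        raise ConfigurationError(
            f"chromosomes absent from linkage-map table: {sorted(missing)}"
        )
    rate = snp_map["chromosome"].map(
        rates.set_index("chromosome")["rate_cm_per_mb"]
    ).to_numpy()
    out = snp_map.copy()
    out["position_morgans"] = out["position_bp"].to_numpy() * rate / 1e8
    return out


def compute_ld_table(
    G: GenotypeMatrix,
    snp_map: pd.DataFrame,
    k: int = 100,
    apply_correction: bool = True,
) -> pd.DataFrame:
    """r^2 for all adjacent pairs; one row per SNP pair.

    Requires complete (post-imputation) genotypes and a map with
    ``position_morgans`` filled.  Pairs with a monomorphic member are
    skipped with a logged count.  ``r2_corrected`` = max(0, r^2 - 1/(2n))
    when ``apply_correction``, else a copy of ``r2`` (the finite-sample
    correction subtracts the expected inflation from sampling n diploids).
    """
    if (G.values == -1).any():
        raise ValueError("genotypes must be imputed before LD computation")
    if snp_map["position_morgans"].isna().any():
        raise ValueError("snp_map lacks genetic positions; run mb_to_cm first")
    pairs = adjacent_pairs(snp_map, k=k)
    v = G.values
    poly = np.ptp(v, axis=0) > 0
    member_ok = poly[pairs["i"]] & poly[pairs["j"]]
    n_skipped = int((~member_ok).sum())
    if n_skipped:
        logger.info("compute_ld_table: skipped %d pairs with a monomorphic member", n_skipped)
    pairs = pairs.loc[member_ok].reset_index(drop=True)

    i_idx = pairs["i"].to_numpy()
    j_idx = pairs["j"].to_numpy()
    counts = np.zeros((len(pairs), 9))
    # batch pairs by offset so genotype-code counting stays vectorized
    offsets = j_idx - i_idx
    for off in np.unique(offsets):
        sel = offsets == off
        codes = 3 * v[:, i_idx[sel]].astype(np.int64) + v[:, j_idx[sel]].astype(np.int64)
        counts[sel] = np.stack([(codes == c).sum(axis=0) for c in range(9)], axis=1)

    freqs, _ = _em_core(counts)
    p_A = freqs[:, 0] + freqs[:, 1]
    p_B = freqs[:, 0] + freqs[:, 2]
    D = freqs[:, 0] - p_A * p_B
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    r2 = np.clip(np.divide(D**2, denom, out=np.zeros_like(D), where=denom > 0), 0.0, 1.0)

    bp = snp_map["position_bp"].to_numpy()
    morg = snp_map["position_morgans"].to_numpy()
    table = pd.DataFrame(
        {
            "snp_i": snp_map["id"].to_numpy()[i_idx],
            "snp_j": snp_map["id"].to_numpy()[j_idx],
            "chromosome": snp_map["chromosome"].to_numpy()[i_idx],
            "dist_bp": np.abs(bp[j_idx] - bp[i_idx]),
            "dist_morgans": np.abs(morg[j_idx] - morg[i_idx]),
            "r2": r2,
        }
    )
    correction = 1.0 / (2.0 * G.n)
    table["r2_corrected"] = np.maximum(0.0, r2 - correction) if apply_correction else r2
    return table


def bin_pairs(
    table: pd.DataFrame, class_spec: str | tuple[float, float, int] = "A", value_col: str = "r2"
) -> pd.DataFrame:
    """Summarize r^2 in equal-width half-open distance bins [lo, hi).

    ``class_spec`` is a named class ("A": 0-0.5 Mb / 0.01 Mb bins,
    "B": 0-5 Mb / 0.1 Mb bins) or a custom ``(lo_mb, hi_mb, n_bins)``.
    Pairs outside [lo, hi) are excluded; empty bins report NaN means.
    """
    if isinstance(class_spec, str):
        try:
            lo, hi, n_bins = BIN_CLASSES[class_spec]
        except KeyError:
            raise ValueError(f"unknown bin class {class_spec!r}") from None
    else:
        lo, hi, n_bins = class_spec
    if not (hi > lo and n_bins >= 1):
        raise ValueError("need hi > lo and n_bins >= 1")
    edges = np.linspace(lo, hi, n_bins + 1)
    dist_mb = table["dist_bp"].to_numpy() / 1e6
    inside = (dist_mb >= lo) & (dist_mb < hi)
    idx = np.minimum(
        np.searchsorted(edges, dist_mb[inside], side="right") - 1, n_bins - 1
    )
    r2 = table.loc[inside, value_col].to_numpy()
    n_pairs = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    sums2 = np.bincount(idx, weights=r2**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
        var = np.where(
            n_pairs > 1,
            (sums2 - np.maximum(n_pairs, 1) * mean**2) / np.maximum(n_pairs - 1, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "bin_index": np.arange(n_bins),
            "range_lo": edges[:-1],
            "range_hi": edges[1:],
            "median_of_range": (edges[:-1] + edges[1:]) / 2.0,
            "n_pairs": n_pairs,
            "mean_r2": mean,
            "var_r2": np.maximum(var, 0.0, where=~np.isnan(var), out=var),
        }
    )
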