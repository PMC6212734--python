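"""Marker quality control and imputation.

Filters mirror standard SNP-chip QC: autosome extraction, an exact
Hardy-Weinberg equilibrium test (exclude p <= 1e-6), per-SNP missingness
(exclude > 0.1) and minor allele frequency (exclude < 0.05), applied
sequentially in that order.  Because a SNP can fail several filters, the
report carries both sequential counts (each SNP charged to the first
filter that removes it) and marginal counts (each filter evaluated on
the full autosomal set), which need not be additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from ldne.io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Exclusion thresholds; comparison directions follow GWAS convention.

    A SNP is removed when HWE exact p <= ``hwe_p_max``, when its missing
    fraction is > ``missing_max``, or when its MAF is < ``maf_min``.
    """

    hwe_p_max: float = 1e-6
    missing_max: float = 0.1
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("hwe_p_max", "missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_input_snps: int
    n_autosomal: int
    removed_hwe: int
    removed_missing: int
    removed_maf: int
    n_retained: int
    marginal_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_input_snps),
            ("autosomal_snps", self.n_autosomal),
            ("removed_hwe_sequential", self.removed_hwe),
            ("removed_missing_sequential", self.removed_missing),
            ("removed_maf_sequential", self.removed_maf),
            ("retained", self.n_retained),
            ("removed_hwe_marginal", self.marginal_counts.get("hwe", 0)),
            ("removed_missing_marginal", self.marginal_counts.get("missing", 0)),
            ("removed_maf_marginal", self.marginal_counts.get("maf", 0)),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def _hwe_het_log_pmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    For n diploids carrying ``n_minor`` copies of the rarer allele, the
    heterozygote count under Hardy-Weinberg takes values of the parity of
    ``n_minor`` with

        P(n_het) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^{n_het}

    conditionally on the allele counts.  Returns the support and the
    normalized log-probabilities.
    """
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_hom_minor = (n_minor - hets) // 2
    n_hom_major = n - hets - n_hom_minor
    logw = (
        gammaln(n + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_major + 1)
        + hets * np.log(2.0)
    )
    logw -= _logsumexp(logw)
    return hets, logw


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value, conditional on allele counts.

    Two-sided in the classical sense: the p-value sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count.  Monomorphic SNPs return p = 1.

    Parameters are the three genotype counts; symmetric in the two
    homozygote classes.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        logger.debug("hwe_exact_test: monomorphic SNP, p = 1 by convention")
        return 1.0
    hets, logp = _hwe_het_log_pmf(n, n_minor)
    obs_logp = logp[hets == n_het]
    if obs_logp.size == 0:  # parity mismatch cannot occur with valid counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    # tolerate log-scale round-off when comparing tail membership
    in_tail = logp <= obs_logp[0] + 1e-12
    return float(min(1.0, np.exp(_logsumexp(logp[in_tail]))))


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (no continuity correction); sanity alternative."""
    n = n_hom_ref + n_het + n_hom_alt
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(sps.chi2.sf(chi2, df=1))


def snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, missing fraction and genotype counts (on observed calls)."""
    v = G.values
    observed = v != MISSING
    n_obs = observed.sum(axis=0)
    n_hom_major = np.sum(v == 0, axis=0)
    n_het = np.sum(v == 1, axis=0)
    n_hom_minor = np.sum(v == 2, axis=0)
    dosage_sum = n_het + 2 * n_hom_minor
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, dosage_sum / (2.0 * n_obs), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "maf": maf,
            "missing_fraction": 1.0 - n_obs / G.n,
            "n_hom_major": n_hom_major,
            "n_het": n_het,
            "n_hom_minor": n_hom_minor,
            "all_missing": n_obs == 0,
        }
    )


def _default_autosomes(chromosomes: pd.Series) -> set[str]:
    """Numeric chromosome labels; excludes X/Y/MT-style labels."""
    return {c for c in chromosomes.unique() if str(c).isdigit()}


def apply_filters(
    G: GenotypeMatrix,
    snp_map: pd.DataFrame,
    thresholds: QcThresholds,
    autosomes: set[str] | None = None,
    hwe_test: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Apply the marker QC cascade and report both bookkeeping modes.

    Non-autosomal SNPs are dropped first; then HWE, missingness and MAF
    filters run sequentially on the survivors.  Marginal counts evaluate
    each filter on the full autosomal set to expose filter overlap.
    """
    if hwe_test not in ("exact", "chisq"):
        raise ValueError(f"unknown hwe_test {hwe_test!r}")
    test = hwe_exact_test if hwe_test == "exact" else hwe_chisq_test

    n_input = G.n_snps
    auto_labels = autosomes if autosomes is not None else _default_autosomes(snp_map["chromosome"])
    is_auto = snp_map["chromosome"].isin(auto_labels).to_numpy()
    G_auto = G.subset_snps(np.flatnonzero(is_auto))
    map_auto = snp_map.loc[is_auto].reset_index(drop=True)

    stats = snp_stats(G_auto)
    hwe_p = np.array(
        [
            test(int(r.n_hom_major), int(r.n_het), int(r.n_hom_minor))
            for r in stats.itertuples()
        ]
    )
    fail_hwe = hwe_p <= thresholds.hwe_p_max
    fail_missing = stats["missing_fraction"].to_numpy() > thresholds.missing_max
    maf = stats["maf"].to_numpy()
    fail_maf = np.isnan(maf) | (maf < thresholds.maf_min)

    marginal = {
        "hwe": int(fail_hwe.sum()),
        "missing": int(fail_missing.sum()),
        "maf": int(fail_maf.sum()),
    }
    # sequential: charge each SNP to the first filter that removes it
    seq_hwe = fail_hwe
    seq_missing = fail_missing & ~seq_hwe
    seq_maf = fail_maf & ~seq_hwe & ~seq_missing
    keep = ~(seq_hwe | seq_missing | seq_maf)

    if not keep.any():
        raise ValueError(
            "QC removed every SNP; review thresholds "
            f"(hwe_p_max={thresholds.hwe_p_max}, missing_max={thresholds.missing_max}, "
            f"maf_min={thresholds.maf_min})"
        )

    report = QcReport(
        n_input_snps=n_input,
        n_autosomal=G_auto.n_snps,
        removed_hwe=int(seq_hwe.sum()),
        removed_missing=int(seq_missing.sum()),
        removed_maf=int(seq_maf.sum()),
        n_retained=int(keep.sum()),
        marginal_counts=marginal,
    )
    logger.info(
        "QC: %d input, %d autosomal, removed %d (HWE) + %d (missing) + %d (MAF), %d retained",
        report.n_input_snps,
        report.n_autosomal,
        report.removed_hwe,
        report.removed_missing,
        report.removed_maf,
        report.n_retained,
    )
    keep_idx = np.flatnonzero(keep)
    return (
        G_auto.subset_snps(keep_idx),
        map_auto.loc[keep].reset_index(drop=True),
        report,
    )


def impute_missing(
    G: GenotypeMatrix, method: str = "mode", seed: int | None = None
) -> GenotypeMatrix:
    """Replace missing calls so every entry is an observed-scale dosage.

    ``mode``
        deterministic per-SNP most frequent genotype (ties -> lower dosage);
    ``frequency_sample``
        seeded draw from the per-SNP Hardy-Weinberg genotype probabilities
        at the observed allele frequency.
    """
    if method not in ("mode", "frequency_sample"):
        raise ValueError(f"unknown imputation method {method!r}")
    v = G.values.copy()
    observed = v != MISSING
    if (~observed).sum() == 0:
        return GenotypeMatrix(v, list(G.sample_ids))
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(f"all-missing SNP columns {bad.tolist()} cannot be imputed")

    if method == "mode":
        counts = np.stack([(v == g).sum(axis=0) for g in (0, 1, 2)])
        modes = counts.argmax(axis=0).astype(np.int8)  # argmax ties -> lowest dosage
        rows, cols = np.nonzero(~observed)
        v[rows, cols] = modes[cols]
    else:
        rng = np.random.default_rng(seed)
        dosage_sum = np.where(observed, v, 0).sum(axis=0)
        p = dosage_sum / (2.0 * n_obs)
        rows, cols = np.nonzero(~observed)
        pc = p[cols]
        draws = rng.random((len(rows), 2))
        v[rows, cols] = ((draws < pc[:, None]).sum(axis=1)).astype(np.int8)
    return GenotypeMatrix(v, list(G.sample_ids))
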