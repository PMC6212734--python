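"""Marker QC: exact HWE test, per-SNP stats, filter cascade, imputation."""

import numpy as np
import pytest

from ldne.io_formats import MISSING, GenotypeMatrix, make_snp_map
from ldne.qc import (
    QcThresholds,
    apply_filters,
    hwe_chisq_test,
    hwe_exact_test,
    impute_missing,
    snp_stats,
)
from ldne.synthetic_data import inject_qc_defects


def hwe_exact_reference(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent oracle: recurrence over the conditional heterozygote pmf.

    Uses the ratio P(h+2)/P(h) = n_hom_minor * n_hom_major * 4 /
    ((h+2)(h+1)) implied by the conditional distribution, normalizes and
    sums the tail of configurations no more probable than the observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    h0 = n_minor % 2
    probs = {h0: 1.0}
    h = h0
    while h + 2 <= min(n_minor, 2 * n - n_minor):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[h + 2] = probs[h] * 4.0 * hom_minor * hom_major / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12)))


class TestHweExact:
    def test_modal_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_zero_heterozygotes_extreme_tail(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (40, 20, 40), (3, 5, 2), (90, 9, 1), (7, 0, 7), (1, 1, 1)],
    )
    def test_agrees_with_recurrence_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_reference(*counts), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_in_homozygote_classes(self, seed):
        rng = np.random.default_rng(seed)
        a, h, b = rng.integers(0, 60, size=3)
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), rel=1e-12)

    def test_close_to_chisq_for_large_balanced_counts(self):
        # sanity band, not equality: moderate deviation, n = 1000
        counts = (270, 480, 250)
        exact = hwe_exact_test(*counts)
        chisq = hwe_chisq_test(*counts)
        assert 0.5 < exact / chisq < 2.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSnpStats:
    def test_hand_counts(self):
        G = GenotypeMatrix(
            np.array(
                [[0, 2, 0], [0, 2, MISSING], [1, 2, 2], [1, 2, MISSING]], dtype=np.int8
            ),
            ["a", "b", "c", "d"],
        )
        stats = snp_stats(G)
        assert stats.loc[0, "maf"] == pytest.approx(0.25)
        assert stats.loc[0, "missing_fraction"] == 0.0
        assert stats.loc[1, "maf"] == pytest.approx(0.0)
        assert stats.loc[2, "maf"] == pytest.approx(0.5)
        assert stats.loc[2, "missing_fraction"] == pytest.approx(0.5)

    def test_all_missing_flagged(self):
        G = GenotypeMatrix(np.full((3, 1), MISSING, dtype=np.int8), ["a", "b", "c"])
        stats = snp_stats(G)
        assert bool(stats.loc[0, "all_missing"])
        assert stats.loc[0, "missing_fraction"] == 1.0
        assert np.isnan(stats.loc[0, "maf"])


def _clean_matrix(n=500, m=10, maf=0.3, seed=5) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    return GenotypeMatrix(rng.binomial(2, maf, size=(n, m)).astype(np.int8))


def _toy_map(m=10, chrom="1"):
    return make_snp_map(
        [f"s{i}" for i in range(m)], [chrom] * m, np.arange(m) * 1000 + 1
    )


class TestApplyFilters:
    def test_constructed_defects_bookkeeping(self):
        """2 HWE-violating + 1 high-missingness + 2 low-MAF (disjoint) -> 5 kept."""
        G = _clean_matrix()
        G = inject_qc_defects(
            G,
            _toy_map(),
            {
                "hwe_all_het": [0],
                "hwe_no_het": [1],
                "high_missing": [(2, 0.2)],
                "low_maf": [(3, 0.01), (4, 0.01)],
            },
            seed=9,
        )
        kept, kept_map, report = apply_filters(G, _toy_map(), QcThresholds())
        assert report.n_retained == 5
        assert (report.removed_hwe, report.removed_missing, report.removed_maf) == (2, 1, 2)
        assert list(kept_map["id"]) == ["s5", "s6", "s7", "s8", "s9"]

    def test_double_violation_charged_once_sequentially(self):
        """An all-het column with its MAF forced irrelevant still counts once."""
        G = _clean_matrix(n=200, m=4)
        v = G.values.copy()
        v[:, 0] = 1  # all-het: fails HWE; MAF = 0.5 passes
        v[:, 1] = 0
        v[: int(200 * 0.02), 1] = 1  # low MAF, HWE-compatible
        G = GenotypeMatrix(v)
        _, _, report = apply_filters(G, _toy_map(4), QcThresholds())
        assert report.removed_hwe == 1
        assert report.removed_maf == 1
        assert report.marginal_counts["hwe"] >= report.removed_hwe

    def test_disabled_thresholds_keep_everything(self):
        G = _clean_matrix()
        kept, _, report = apply_filters(
            G, _toy_map(), QcThresholds(hwe_p_max=0.0, missing_max=1.0, maf_min=0.0)
        )
        assert report.n_retained == G.n_snps
        assert (report.removed_hwe, report.removed_missing, report.removed_maf) == (0, 0, 0)

    def test_non_autosomes_dropped_first(self):
        G = _clean_matrix(m=6)
        snp_map = make_snp_map(
            [f"s{i}" for i in range(6)],
            ["1", "1", "X", "X", "2", "MT"],
            np.arange(6) * 100 + 1,
        )
        _, kept_map, report = apply_filters(G, snp_map, QcThresholds())
        assert report.n_autosomal == 3
        assert set(kept_map["chromosome"]) <= {"1", "2"}

    def test_idempotent(self, small_sample):
        G, snp_map = small_sample
        kept, kept_map, _ = apply_filters(G, snp_map, QcThresholds())
        again, _, report2 = apply_filters(kept, kept_map, QcThresholds())
        assert report2.n_retained == kept.n_snps
        np.testing.assert_array_equal(again.values, kept.values)

    def test_all_removed_is_hard_error(self):
        G = GenotypeMatrix(np.ones((100, 3), dtype=np.int8))  # all-het columns
        with pytest.raises(ValueError, match="threshold"):
            apply_filters(G, _toy_map(3), QcThresholds())


class TestImputeMissing:
    def test_mode_fills_most_frequent(self):
        G = GenotypeMatrix(np.array([[0], [0], [2], [MISSING]], dtype=np.int8))
        out = impute_missing(G, method="mode")
        assert out.values[3, 0] == 0

    def test_mode_tie_prefers_lower_dosage(self):
        G = GenotypeMatrix(np.array([[1], [1], [MISSING]], dtype=np.int8))
        assert impute_missing(G, method="mode").values[2, 0] == 1

    def test_frequency_sample_matches_hw_proportions(self):
        rng = np.random.default_rng(2)
        n = 20_000
        col = rng.binomial(2, 0.5, size=n).astype(np.int8)
        col[:10_000] = MISSING
        G = GenotypeMatrix(col[:, None])
        out = impute_missing(G, method="frequency_sample", seed=42)
        imputed = out.values[:10_000, 0]
        props = np.bincount(imputed, minlength=3) / 10_000
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert np.all(np.abs(props - [0.25, 0.5, 0.25]) < 3 * se + 0.01)

    def test_no_missing_left(self, small_sample):
        G, _ = small_sample
        out = impute_missing(G)
        assert not (out.values == MISSING).any()

    def test_all_missing_column_is_error(self):
        G = GenotypeMatrix(np.full((4, 1), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="all-missing"):
            impute_missing(G)
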