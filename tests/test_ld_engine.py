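"""Pairwise r^2: EM haplotype frequencies, adjacency, distances, binning."""

import numpy as np
import pandas as pd
import pytest

from ldne.io_formats import ConfigurationError, GenotypeMatrix, make_chrom_map_table, make_snp_map
from ldne.ld_engine import (
    DegeneratePairError,
    HaplotypeFreqs,
    _loglik,
    _pair_genotype_counts,
    adjacent_pairs,
    bin_pairs,
    compute_ld_table,
    em_haplotype_freqs,
    mb_to_cm,
    r2_from_freqs,
)


def closed_form_freqs(col_i, col_j):
    """Count-based haplotype frequencies, valid only without double heterozygotes."""
    c = _pair_genotype_counts(np.asarray(col_i), np.asarray(col_j))
    assert c[4] == 0, "closed form requires no double heterozygotes"
    two_n = 2 * c.sum()
    return np.array(
        [
            2 * c[8] + c[7] + c[5],
            2 * c[6] + c[7] + c[3],
            2 * c[2] + c[1] + c[5],
            2 * c[0] + c[1] + c[3],
        ]
    ) / two_n


class TestEmHaplotypeFreqs:
    def test_complete_coupling(self):
        col = np.array([2, 2, 2, 0, 0, 0])
        h = em_haplotype_freqs(col, col)
        assert h.p_AB == pytest.approx(0.5, abs=1e-9)
        assert h.p_ab == pytest.approx(0.5, abs=1e-9)
        assert h.D == pytest.approx(0.25, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_closed_form_without_double_hets(self, seed):
        rng = np.random.default_rng(seed)
        # make locus i heterozygous only where locus j is homozygous
        col_j = rng.binomial(2, 0.4, 80).astype(np.int8)
        col_i = rng.binomial(2, 0.3, 80).astype(np.int8)
        col_i[(col_i == 1) & (col_j == 1)] = 2
        if len(np.unique(col_i)) < 2 or len(np.unique(col_j)) < 2:
            pytest.skip("degenerate draw")
        h = em_haplotype_freqs(col_i, col_j)
        expected = closed_form_freqs(col_i, col_j)
        np.testing.assert_allclose([h.p_AB, h.p_Ab, h.p_aB, h.p_ab], expected, atol=1e-8)

    def test_monomorphic_column_rejected(self):
        with pytest.raises(DegeneratePairError):
            em_haplotype_freqs(np.array([1, 1, 1]), np.array([0, 1, 2]))

    def test_loglik_at_em_beats_perturbations(self):
        rng = np.random.default_rng(4)
        col_i = rng.binomial(2, 0.4, 50).astype(np.int8)
        col_j = np.where(rng.random(50) < 0.7, col_i, rng.binomial(2, 0.4, 50)).astype(np.int8)
        h = em_haplotype_freqs(col_i, col_j)
        counts = _pair_genotype_counts(col_i, col_j)
        f_hat = np.array([h.p_AB, h.p_Ab, h.p_aB, h.p_ab])
        ll_hat = _loglik(counts, f_hat)
        for _ in range(200):
            eps = rng.normal(0, 0.01, 4)
            f = np.clip(f_hat + eps - eps.mean(), 1e-9, 1)
            f /= f.sum()
            assert _loglik(counts, f) <= ll_hat + 1e-9


class TestR2FromFreqs:
    def test_complete_ld_is_one(self):
        h = HaplotypeFreqs(0.5, 0.0, 0.0, 0.5, 10)
        assert r2_from_freqs(h) == pytest.approx(1.0)

    def test_zero_d_is_zero(self):
        h = HaplotypeFreqs(0.12, 0.18, 0.28, 0.42, 10)  # p_A=0.3, p_B=0.4, D=0
        assert r2_from_freqs(h) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        h = HaplotypeFreqs(0.4, 0.1, 0.1, 0.4, 10)
        assert h.D == pytest.approx(0.15)
        assert r2_from_freqs(h) == pytest.approx(0.36)

    def test_fixed_allele_is_error(self):
        with pytest.raises(DegeneratePairError):
            r2_from_freqs(HaplotypeFreqs(0.6, 0.4, 0.0, 0.0, 10))

    @pytest.mark.parametrize("seed", range(8))
    def test_invariant_to_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        col_i = rng.binomial(2, 0.35, 60).astype(np.int8)
        col_j = np.where(rng.random(60) < 0.5, col_i, rng.binomial(2, 0.45, 60)).astype(np.int8)
        if len(np.unique(col_i)) < 2 or len(np.unique(col_j)) < 2:
            pytest.skip("degenerate draw")
        r2 = r2_from_freqs(em_haplotype_freqs(col_i, col_j))
        r2_flip_i = r2_from_freqs(em_haplotype_freqs(2 - col_i, col_j))
        r2_flip_j = r2_from_freqs(em_haplotype_freqs(col_i, 2 - col_j))
        perm = rng.permutation(60)
        r2_perm = r2_from_freqs(em_haplotype_freqs(col_i[perm], col_j[perm]))
        assert r2_flip_i == pytest.approx(r2, abs=1e-9)
        assert r2_flip_j == pytest.approx(r2, abs=1e-9)
        assert r2_perm == pytest.approx(r2, abs=1e-9)


class TestAdjacentPairs:
    def _map(self, counts):
        ids, chroms, pos = [], [], []
        for c, m in counts.items():
            ids += [f"{c}_{i}" for i in range(m)]
            chroms += [c] * m
            pos += list(range(1, m + 1))
        return make_snp_map(ids, chroms, pos)

    def test_small_chromosome_all_pairs(self):
        pairs = adjacent_pairs(self._map({"1": 5}), k=100)
        assert len(pairs) == 10

    def test_combinatorial_count(self):
        pairs = adjacent_pairs(self._map({"1": 200}), k=100)
        assert len(pairs) == 200 * 100 - 100 * 101 // 2  # 14,950

    def test_no_duplicates_and_no_cross_chromosome(self):
        snp_map = self._map({"1": 30, "2": 40})
        pairs = adjacent_pairs(snp_map, k=10)
        assert not pairs.duplicated().any()
        chrom = snp_map["chromosome"].to_numpy()
        assert (chrom[pairs["i"]] == chrom[pairs["j"]]).all()
        assert len(pairs) == (30 * 10 - 55) + (40 * 10 - 55)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            adjacent_pairs(self._map({"1": 5}), k=0)


class TestMbToCm:
    def _rates(self):
        return make_chrom_map_table(["1"], [100.0], [120.0])

    def test_unit_conversion(self):
        snp_map = make_snp_map(["a"], ["1"], [2_000_000])
        out = mb_to_cm(snp_map, self._rates())
        assert out.loc[0, "position_morgans"] == pytest.approx(0.024)

    def test_pair_distance_one_mb_at_unit_rate(self):
        rates = make_chrom_map_table(["1"], [50.0], [50.0])
        snp_map = make_snp_map(["a", "b"], ["1", "1"], [1_000_000, 2_000_000])
        out = mb_to_cm(snp_map, rates)
        d = out["position_morgans"].diff().iloc[1]
        assert d == pytest.approx(0.01)

    def test_translation_invariance_of_distances(self):
        snp_map = make_snp_map(["a", "b", "c"], ["1"] * 3, [10, 500, 900])
        shifted = make_snp_map(["a", "b", "c"], ["1"] * 3, [100_010, 100_500, 100_900])
        d1 = np.diff(mb_to_cm(snp_map, self._rates())["position_morgans"])
        d2 = np.diff(mb_to_cm(shifted, self._rates())["position_morgans"])
        np.testing.assert_allclose(d1, d2, atol=1e-15)

    def test_missing_chromosome_is_configuration_error(self):
        snp_map = make_snp_map(["a"], ["7"], [100])
        with pytest.raises(ConfigurationError):
            mb_to_cm(snp_map, self._rates())


class TestComputeLdTable:
    def _setup(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        cols = rng.binomial(2, 0.4, size=(n, 3)).astype(np.int8)
        values = np.column_stack([cols[:, 0], cols[:, 0], cols[:, 1], cols[:, 2]])
        G = GenotypeMatrix(values)
        snp_map = make_snp_map(
            ["s0", "s0dup", "s1", "s2"], ["1"] * 4, [1000, 5000, 9000, 20000]
        )
        snp_map = mb_to_cm(snp_map, make_chrom_map_table(["1"], [1.0], [1.0]))
        return G, snp_map

    def test_duplicated_column_has_r2_one(self):
        G, snp_map = self._setup()
        table = compute_ld_table(G, snp_map, k=100)
        row = table[(table.snp_i == "s0") & (table.snp_j == "s0dup")]
        assert row["r2"].iloc[0] == pytest.approx(1.0)

    def test_sample_size_correction_floored(self):
        G, snp_map = self._setup()
        table = compute_ld_table(G, snp_map, k=100, apply_correction=True)
        expected = np.maximum(0.0, table["r2"] - 1.0 / (2 * G.n))
        np.testing.assert_allclose(table["r2_corrected"], expected, atol=1e-12)

    def test_unimputed_input_rejected(self):
        G, snp_map = self._setup()
        v = G.values.copy()
        v[0, 0] = -1
        with pytest.raises(ValueError, match="imputed"):
            compute_ld_table(GenotypeMatrix(v), snp_map, k=10)

    def test_matches_per_pair_em(self, small_cohort):
        from ldne.qc import QcThresholds, apply_filters, impute_missing

        G, snp_map, _ = apply_filters(
            small_cohort.genotypes, small_cohort.snp_map, QcThresholds()
        )
        G = impute_missing(G)
        snp_map = mb_to_cm(snp_map, small_cohort.chrom_map)
        table = compute_ld_table(G, snp_map, k=5)
        idx = {sid: i for i, sid in enumerate(snp_map["id"])}
        sub = table.sample(20, random_state=1)
        for row in sub.itertuples():
            h = em_haplotype_freqs(G.values[:, idx[row.snp_i]], G.values[:, idx[row.snp_j]])
            assert row.r2 == pytest.approx(r2_from_freqs(h), abs=1e-9)


class TestBinPairs:
    def _table(self, dist_mb, r2):
        return pd.DataFrame(
            {
                "dist_bp": np.asarray(dist_mb) * 1e6,
                "dist_morgans": np.asarray(dist_mb) * 0.01,
                "r2": r2,
                "r2_corrected": r2,
            }
        )

    def test_half_open_bins_class_a(self):
        table = self._table([0.005, 0.010], [0.5, 0.7])
        bins = bin_pairs(table, "A")
        assert bins.loc[0, "n_pairs"] == 1  # 0.005 in [0, 0.01)
        assert bins.loc[1, "n_pairs"] == 1  # 0.010 lands in bin 1
        assert bins.loc[0, "mean_r2"] == pytest.approx(0.5)

    def test_constant_r2_gives_zero_variance(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.uniform(0, 5, 500), np.full(500, 0.3))
        bins = bin_pairs(table, "B")
        occupied = bins[bins["n_pairs"] > 0]
        np.testing.assert_allclose(occupied["mean_r2"], 0.3)
        np.testing.assert_allclose(occupied["var_r2"], 0.0, atol=1e-15)

    def test_empty_bins_report_nan_not_zero(self):
        table = self._table([0.005], [0.5])
        bins = bin_pairs(table, "A")
        assert np.isnan(bins.loc[10, "mean_r2"])
        assert bins.loc[10, "n_pairs"] == 0

    def test_pairs_outside_range_excluded(self):
        table = self._table([0.25, 0.75], [0.5, 0.9])
        bins = bin_pairs(table, "A")  # class A covers 0-0.5 Mb
        assert bins["n_pairs"].sum() == 1

    def test_fifty_bins_per_class(self):
        table = self._table([0.1], [0.5])
        for cls in ("A", "B"):
            assert len(bin_pairs(table, cls)) == 50

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            bin_pairs(self._table([0.1], [0.5]), "Z")
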