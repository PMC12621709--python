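"""Pseudo-bulk merging, ICE, O/E, compartment PC1, saddles, arm-scaled
averages and putative-deletion detection."""

import numpy as np
import pandas as pd
import pytest

from epistate3c import genome3d as g3


def checkerboard(n=40, block=5, strong=4.0, weak=1.0, decayless=True):
    """Block-alternating matrix: same-parity blocks interact strongly."""
    parity = (np.arange(n) // block) % 2
    same = parity[:, None] == parity[None, :]
    return np.where(same, strong, weak).astype(float)


class TestPseudoBulk:
    def _contacts(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "chrom1", "pos1", "chrom2", "pos2"])

    def test_disjoint_cells_sum_elementwise(self):
        c = self._contacts(
            [
                ("a", "chr1", 50, "chr1", 150),
                ("b", "chr1", 250, "chr1", 50),
            ]
        )
        m = g3.pseudo_bulk(c, pd.Index(["a", "b"]), "chr1", 300, resolution=100)
        ma = g3.pseudo_bulk(c, pd.Index(["a"]), "chr1", 300, resolution=100)
        mb = g3.pseudo_bulk(c, pd.Index(["b"]), "chr1", 300, resolution=100)
        assert np.allclose(m.matrix, ma.matrix + mb.matrix)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"c{i % 3}", "chr1", int(rng.integers(0, 1000)), "chr1",
             int(rng.integers(0, 1000)))
            for i in range(200)
        ]
        c = self._contacts(rows)
        m = g3.pseudo_bulk(c, pd.Index(["c0", "c1", "c2"]), "chr1", 1000, resolution=100)
        assert np.triu(m.matrix).sum() == pytest.approx(200)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            g3.pseudo_bulk(self._contacts([]), pd.Index([]), "chr1", 1000, 100)

    def test_grouped_variant_matches_single(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"c{i % 4}", "chr1", int(rng.integers(0, 1000)), "chr1",
             int(rng.integers(0, 1000)))
            for i in range(300)
        ]
        c = self._contacts(rows)
        membership = pd.Series(
            {"c0": "g0", "c1": "g0", "c2": "g1", "c3": "g1"}
        )
        grouped = g3.pseudo_bulk_by_group(c, membership, {"chr1": 1000}, 100)
        direct = g3.pseudo_bulk(c, pd.Index(["c0", "c1"]), "chr1", 1000, 100)
        assert np.allclose(grouped["g0"]["chr1"].matrix, direct.matrix)


class TestBalanceICE:
    def test_doubly_stochastic_like_input_unchanged(self):
        n = 10
        M = np.full((n, n), 1.0 / n)
        balanced, w = g3.balance_ice(M)
        assert np.allclose(w[~np.isnan(w)], w[0], rtol=1e-4)
        assert np.allclose(balanced / balanced[0, 0], M / M[0, 0], rtol=1e-4)

    def test_planted_bias_recovered_and_rows_equalized(self):
        """diag(b) K diag(b) balances back to equal row sums (Sinkhorn)."""
        rng = np.random.default_rng(2)
        K = rng.random((12, 12))
        K = K + K.T + 1.0
        b = rng.uniform(0.5, 2.0, 12)
        M = np.outer(b, b) * K
        balanced, w = g3.balance_ice(M, tol=1e-8, max_iter=500)
        s = balanced.sum(axis=1)
        assert np.ptp(s) / s.mean() < 1e-3

    def test_matches_explicit_sinkhorn_iterations(self):
        rng = np.random.default_rng(3)
        M = rng.random((8, 8))
        M = M + M.T + 0.5
        balanced, _ = g3.balance_ice(M, tol=1e-10, max_iter=1000)
        # independent oracle: alternating row/column scaling
        B = M.copy()
        for _ in range(5000):
            r = B.sum(axis=1, keepdims=True)
            B = B / r
            B = (B + B.T) / 2  # keep symmetric: simultaneous scaling
        np.testing.assert_allclose(
            balanced / balanced.sum(), B / B.sum(), atol=1e-3
        )

    def test_zero_row_masked(self):
        M = np.ones((5, 5))
        M[2, :] = 0.0
        M[:, 2] = 0.0
        balanced, w = g3.balance_ice(M)
        assert np.isnan(w[2])
        assert balanced[2].sum() == 0
        s = np.delete(balanced.sum(axis=1), 2)
        assert np.ptp(s) / s.mean() < 1e-3


class TestExpectedByBand:
    def test_two_by_two_worked_example(self):
        E = g3.expected_by_band(np.array([[4.0, 2.0], [2.0, 8.0]]))
        assert np.allclose(E, [[6.0, 2.0], [2.0, 6.0]])

    def test_band_constant_matrix_is_fixed_point(self):
        n = 10
        M = np.fromfunction(lambda i, j: 1.0 / (1 + abs(i - j)), (n, n))
        assert np.allclose(g3.expected_by_band(M), M)
        oe = g3.observed_over_expected(M)
        assert np.allclose(oe, 1.0)


class TestCompartmentPC1:
    def _gc_for(self, n, block, high_on_even=True):
        parity = (np.arange(n) // block) % 2
        gc = np.where(parity == 0, 0.46, 0.38)
        return gc if high_on_even else gc[::-1]

    def test_checkerboard_recovered_with_gc_orientation(self):
        n, block = 40, 5
        M = checkerboard(n, block)
        gc = self._gc_for(n, block)
        prof = g3.compartment_pc1(M, gc)
        parity = (np.arange(n) // block) % 2
        assert (prof.pc1[parity == 0] > 0).all()
        assert (prof.pc1[parity == 1] < 0).all()

    def test_sign_law_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 30))
            M = rng.random((n, n))
            M = M + M.T + 0.2
            gc = rng.uniform(0.3, 0.6, n)
            prof = g3.compartment_pc1(M, gc)
            ok = ~np.isnan(prof.pc1)
            if np.ptp(prof.pc1[ok]) > 0:
                assert np.corrcoef(prof.pc1[ok], gc[ok])[0, 1] >= -1e-12

    def test_flipping_gc_flips_pc1(self):
        n, block = 40, 5
        M = checkerboard(n, block)
        gc = self._gc_for(n, block)
        p1 = g3.compartment_pc1(M, gc).pc1
        p2 = g3.compartment_pc1(M, 0.9 - gc).pc1
        assert np.allclose(p1, -p2, atol=1e-9)

    def test_reversal_equivariance(self):
        """Reversing bin order (which preserves |i-j| band structure, unlike
        an arbitrary shuffle) reverses PC1."""
        rng = np.random.default_rng(5)
        n = 20
        M = rng.random((n, n))
        M = M + M.T + 0.2
        gc = rng.uniform(0.3, 0.6, n)
        p_orig = g3.compartment_pc1(M, gc).pc1
        p_rev = g3.compartment_pc1(M[::-1, ::-1].copy(), gc[::-1]).pc1
        assert np.allclose(np.abs(p_rev), np.abs(p_orig[::-1]), atol=1e-8)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            g3.compartment_pc1(np.zeros((6, 6)), np.full(6, 0.4))


class TestSaddle:
    def test_symmetric_and_checkerboard_corners(self):
        n, block = 40, 5
        M = checkerboard(n, block)
        gc = np.where((np.arange(n) // block) % 2 == 0, 0.46, 0.38)
        prof = g3.compartment_pc1(M, gc)
        S = g3.saddle(M, prof, n_quantiles=4)
        assert np.allclose(S, S.T, atol=1e-9)
        assert S[0, 0] > S[0, -1] and S[-1, -1] > S[0, -1]

    def test_identical_states_divide_to_ones(self):
        n, block = 40, 5
        M = checkerboard(n, block)
        gc = np.where((np.arange(n) // block) % 2 == 0, 0.46, 0.38)
        prof = g3.compartment_pc1(M, gc)
        S = g3.saddle(M, prof, n_quantiles=4)
        ratio = g3.saddle_state_ratio(S, S)
        assert np.allclose(ratio, 1.0, atol=1e-9)

    def test_scaling_ratio_and_shape_check(self):
        S = np.ones((4, 4))
        assert np.allclose(g3.saddle_state_ratio(2 * S, S), 2.0)
        with pytest.raises(ValueError):
            g3.saddle_state_ratio(S, np.ones((3, 3)))

    def test_constant_pc1_gives_global_mean(self):
        rng = np.random.default_rng(6)
        M = rng.random((30, 30))
        M = M + M.T + 0.5
        prof = np.zeros(30)
        S = g3.saddle(M, prof, n_quantiles=3)
        oe = g3.observed_over_expected(M)
        assert S.mean() == pytest.approx(oe.mean(), rel=0.15)


class TestCentromereAligned:
    def test_band_constant_matrix_averages_to_ones(self):
        n = 60
        M = np.fromfunction(lambda i, j: 2.0 / (1 + abs(i - j)), (n, n))
        out = g3.centromere_aligned_average(
            {"chr1": M}, {"chr1": 24 * 100_000}, 100_000, p_bins=20, q_bins=20
        )
        assert out.shape == (40, 40)
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_small_chromosome_excluded(self):
        n = 49
        M = np.ones((n, n))
        with pytest.raises(ValueError, match="no eligible"):
            g3.centromere_aligned_average(
                {"chr1": M}, {"chr1": 20 * 100_000}, 100_000, min_chrom_bins=50
            )

    def test_two_identical_chromosomes_average_to_either(self):
        n = 60
        rng = np.random.default_rng(7)
        M = rng.random((n, n))
        M = M + M.T + 0.5
        cen = {"chr1": 25 * 100_000, "chr2": 25 * 100_000}
        one = g3.centromere_aligned_average(
            {"chr1": M}, {"chr1": cen["chr1"]}, 100_000, p_bins=15, q_bins=15
        )
        two = g3.centromere_aligned_average(
            {"chr1": M, "chr2": M}, cen, 100_000, p_bins=15, q_bins=15
        )
        assert np.allclose(one, two, atol=1e-12)


class TestDeletionDetection:
    def _pseudo_bulks(self, n_bulks=12, n_bins=30, missing_bulks=10, deleted_bin=5):
        rng = np.random.default_rng(8)
        out = {}
        for i in range(n_bulks):
            M = rng.random((n_bins, n_bins)) + 0.5
            M = M + M.T
            if i < missing_bulks:
                M[deleted_bin, :] = 0.0
                M[:, deleted_bin] = 0.0
            out[f"pb{i:02d}"] = {"chr1": M}
        return out

    def test_threshold_boundary(self):
        calls10 = g3.detect_putative_deletions(
            self._pseudo_bulks(missing_bulks=10), {"chr1": 3_000_000}, 100_000
        )
        assert len(calls10) == 1
        assert calls10["n_missing"].iloc[0] == 10
        calls9 = g3.detect_putative_deletions(
            self._pseudo_bulks(missing_bulks=9), {"chr1": 3_000_000}, 100_000
        )
        assert len(calls9) == 0

    def test_entirely_missing_rows_dropped(self):
        calls = g3.detect_putative_deletions(
            self._pseudo_bulks(missing_bulks=12), {"chr1": 3_000_000}, 100_000
        )
        assert len(calls) == 0

    def test_telomere_distance_annotation(self):
        calls = g3.detect_putative_deletions(
            self._pseudo_bulks(deleted_bin=1), {"chr1": 3_000_000}, 100_000
        )
        assert calls["telomere_distance"].iloc[0] == 100_000

    def test_too_few_pseudo_bulks_warns_empty(self):
        with pytest.warns(UserWarning, match="min_missing"):
            calls = g3.detect_putative_deletions(
                self._pseudo_bulks(n_bulks=4), {"chr1": 3_000_000}, 100_000
            )
        assert len(calls) == 0
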