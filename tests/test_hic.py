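"""Hi-C matrix preparation, TAD calling, ACF, IS^m, compartments,
saddles, and pileups, each against closed forms or brute-force oracles."""

import itertools

import numpy as np
import pytest

from perichrom import hic, simulate
from perichrom.hic import ContactMatrix, TAD


def sym_random(rng, n, scale=10.0):
    a = rng.random((n, n)) * scale
    return (a + a.T) / 2


@pytest.fixture
def oe_uniform():
    return ContactMatrix("c", 2000, np.ones((20, 20)), balanced=True)


class TestShortRangeFilter:
    def test_2kb_bins_only_diagonal(self):
        m = np.full((5, 5), 3.0)
        out = hic.remove_short_range(ContactMatrix("c", 2000, m), 1000)
        assert (np.diag(out.matrix) == 0).all()
        assert out.matrix[0, 1] == 3.0

    def test_500bp_bins_first_offdiagonal_zeroed(self):
        m = np.full((6, 6), 3.0)
        out = hic.remove_short_range(ContactMatrix("c", 500, m), 1000)
        assert out.matrix[0, 1] == 0.0
        assert out.matrix[0, 2] == 3.0

    def test_min_zero_is_identity(self):
        m = np.full((4, 4), 2.0)
        out = hic.remove_short_range(ContactMatrix("c", 2000, m), 0)
        assert np.array_equal(out.matrix, m)


class TestDownsample:
    def test_identity_at_full_target(self):
        rng = np.random.default_rng(0)
        m = np.round(sym_random(rng, 10, 50))
        cm = ContactMatrix("c", 2000, m)
        out = hic.downsample(cm, cm.total(), seed=1)
        assert np.array_equal(out.matrix, m)

    def test_total_within_three_sigma(self):
        rng = np.random.default_rng(1)
        m = np.round(sym_random(rng, 50, 100))
        cm = ContactMatrix("c", 2000, m)
        total = cm.total()
        target = total / 2
        out = hic.downsample(cm, target, seed=2)
        sigma = np.sqrt(total * 0.5 * 0.5)
        assert abs(out.total() - target) < 3 * sigma

    def test_deterministic_and_error(self):
        rng = np.random.default_rng(2)
        m = np.round(sym_random(rng, 10, 20))
        cm = ContactMatrix("c", 2000, m)
        a = hic.downsample(cm, 100, seed=5)
        b = hic.downsample(cm, 100, seed=5)
        assert np.array_equal(a.matrix, b.matrix)
        with pytest.raises(ValueError):
            hic.downsample(cm, cm.total() + 1)


class TestIterativeCorrection:
    def test_row_sums_equalised(self):
        rng = np.random.default_rng(3)
        m = sym_random(rng, 100, 10.0) + 0.5
        bal = hic.iterative_correction(ContactMatrix("c", 2000, m))
        rows = np.nansum(np.where(np.isfinite(bal.matrix), bal.matrix, 0.0),
                         axis=1)[bal.valid_mask]
        assert np.abs(rows / rows.mean() - 1).max() <= 1e-6

    def test_equal_rows_unchanged_shape(self):
        n = 10
        m = np.ones((n, n))
        bal = hic.iterative_correction(ContactMatrix("c", 2000, m))
        sub = bal.matrix[np.ix_(bal.valid_mask, bal.valid_mask)]
        np.testing.assert_allclose(sub, sub[0, 0])

    def test_all_zero_row_masked(self):
        rng = np.random.default_rng(4)
        m = sym_random(rng, 20, 5.0) + 0.5
        m[7, :] = 0.0
        m[:, 7] = 0.0
        bal = hic.iterative_correction(ContactMatrix("c", 2000, m))
        assert not bal.valid_mask[7]
        assert np.isnan(bal.matrix[7]).all()


class TestObservedOverExpected:
    def test_diagonal_means_are_one(self):
        rng = np.random.default_rng(5)
        m = sym_random(rng, 60, 8.0) + 0.2
        bal = hic.iterative_correction(ContactMatrix("c", 2000, m))
        oe = hic.observed_over_expected(bal)
        n = oe.n_bins
        for s in range(0, n):
            d = oe.matrix[np.arange(n - s), np.arange(n - s) + s]
            if np.isfinite(d).any():
                assert np.nanmean(d) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_matrix_gives_all_ones(self, oe_uniform):
        oe = hic.observed_over_expected(oe_uniform)
        np.testing.assert_allclose(oe.matrix, 1.0)

    def test_synthetic_decay_recovered(self):
        n = 100
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
        c = 50.0
        with np.errstate(divide="ignore"):
            m = c / sep
        np.fill_diagonal(m, c)
        cm = ContactMatrix("c", 2000, m, balanced=True)
        exp = hic.expected_profile(cm)
        for s in range(1, 50):
            assert exp[s] == pytest.approx(c / s, rel=1e-9)


class TestArmatusPreprocess:
    def test_equal_values_identity_then_log(self):
        m = np.full((10, 10), np.e)
        out = hic.armatus_preprocess(ContactMatrix("c", 4000, m))
        np.testing.assert_allclose(out.matrix, 1.0)

    def test_missing_cell_interpolated(self):
        n = 10
        m = np.ones((n, n))
        # on the 2nd diagonal set neighbours 2 and 4 around a missing cell
        i = np.arange(n - 2)
        m[i, i + 2] = 3.0
        m[i + 2, i] = 3.0
        m[3, 5] = m[5, 3] = np.nan
        m[2, 4] = m[4, 2] = 2.0
        m[4, 6] = m[6, 4] = 4.0
        out = hic.armatus_preprocess(ContactMatrix("c", 4000, m))
        assert out.matrix[3, 5] == pytest.approx(np.log(3.0))

    def test_outlier_clipped_to_p99(self):
        rng = np.random.default_rng(6)
        m = sym_random(rng, 40, 1.0) + 1.0
        m[0, 30] = m[30, 0] = 1e6
        finite = ContactMatrix("c", 4000, m).matrix
        p99 = np.percentile(finite[np.isfinite(finite)], 99)
        out = hic.armatus_preprocess(ContactMatrix("c", 4000, m))
        assert out.matrix[0, 30] == pytest.approx(np.log(p99))


def brute_force_best_score(q, n):
    """Enumerate every partition into disjoint >=2-bin domains with gaps."""
    best = 0.0
    def rec(start):
        if start >= n - 1:
            return 0.0
        skip = rec(start + 1)
        top = skip
        for l in range(start + 1, n):
            v = q[start, l]
            if np.isfinite(v) and v > 0:
                top = max(top, v + rec(l + 1))
        return top
    return rec(0)


class TestCallTads:
    @pytest.mark.parametrize("gamma", [0.4, 0.6, 1.0])
    def test_dp_matches_exhaustive_enumeration(self, gamma):
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = int(rng.integers(4, 13))
            m = sym_random(rng, n, 1.0)
            cm = ContactMatrix("c", 4000, m)
            tads = hic.call_tads(cm, gamma)
            score = hic.tad_partition_score(cm, tads, gamma)
            q = hic.armatus_quality(m, gamma)
            assert score == pytest.approx(brute_force_best_score(q, n), abs=1e-9)

    def test_two_planted_blocks_recovered_exactly(self):
        n = 30
        m = np.ones((n, n))
        m[5:11, 5:11] = 3.0
        m[18:26, 18:26] = 3.0
        tads = hic.call_tads(hic.armatus_preprocess(ContactMatrix("c", 4000, m)),
                             1.0)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(5, 10), (18, 25)]

    def test_uniform_matrix_no_domains(self):
        m = np.ones((15, 15))
        assert hic.call_tads(ContactMatrix("c", 4000, m), 1.0) == []

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            hic.call_tads(ContactMatrix("c", 4000, np.ones((5, 5))), -1.0)


class TestMatchTads:
    def test_identical_sets_all_matched(self):
        a = [TAD(0, 5), TAD(6, 12)]
        assert len(hic.match_tads(a, list(a))) == 2

    def test_one_bin_shift_unmatched(self):
        assert hic.match_tads([TAD(0, 5)], [TAD(1, 6)]) == []

    def test_empty(self):
        assert hic.match_tads([], [TAD(0, 3)]) == []


class TestACF:
    def test_uniform_block(self, oe_uniform):
        assert hic.tad_acf(oe_uniform, TAD(3, 8)) == pytest.approx(1.0)

    def test_hand_mean_three_bin_tad(self):
        m = np.zeros((5, 5))
        m[1, 2] = m[2, 1] = 1.0
        m[1, 3] = m[3, 1] = 2.0
        m[2, 3] = m[3, 2] = 3.0
        oe = ContactMatrix("c", 2000, m)
        assert hic.tad_acf(oe, TAD(1, 3)) == pytest.approx(2.0)

    def test_identical_matrices_zero_log2fc(self):
        rng = np.random.default_rng(8)
        m = sym_random(rng, 20, 2.0) + 0.5
        oe = ContactMatrix("c", 2000, m)
        fc = hic.acf_log2fc(oe, oe, [TAD(2, 8), TAD(10, 18)])
        np.testing.assert_allclose(fc, 0.0)

    def test_one_bin_tad_undefined(self, oe_uniform):
        with pytest.warns(UserWarning):
            assert np.isnan(hic.tad_acf(oe_uniform, TAD(4, 4)))


class TestJaccardGroup:
    from perichrom.genome import GenomicInterval, IntervalSet

    def _record(self, x_cov, y_cov):
        from perichrom.genome import GenomicInterval, IntervalSet
        tad = TAD(0, 9)   # [0, 40000) at 4-kb bins
        lads = IntervalSet([GenomicInterval("c", 0, int(40_000 * x_cov))]) \
            if x_cov else IntervalSet()
        active = IntervalSet([GenomicInterval("c", 0, int(40_000 * y_cov))]) \
            if y_cov else IntervalSet()
        return hic.jaccard_group(tad, "c", 4000, lads, active)

    @pytest.mark.parametrize("x,y,jacc,group", [
        (1.0, 0.0, 1.0, "C"),
        (0.0, 1.0, -1.0, "A"),
        (0.5, 0.5, 0.0, "B"),
        (0.0, 0.0, 0.0, "B"),
    ])
    def test_closed_forms(self, x, y, jacc, group):
        rec = self._record(x, y)
        assert rec.jacc == pytest.approx(jacc)
        assert rec.group == group

    def test_antisymmetry(self):
        a = self._record(0.9, 0.02)
        b = self._record(0.02, 0.9)
        assert a.jacc == pytest.approx(-b.jacc)
        assert {a.group, b.group} == {"A", "C"}


class TestISm:
    def test_all_ones_interior(self):
        oe = ContactMatrix("c", 2000, np.ones((20, 20)))
        ism = hic.ism_profile(oe)
        assert np.isnan(ism[:4]).all() and np.isnan(ism[-4:]).all()
        np.testing.assert_allclose(ism[4:-4], 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = sym_random(rng, 30, 5.0)
            ism = hic.ism_profile(ContactMatrix("c", 2000, m))
            for i in range(4, 26):
                cells = [m[u, v] for u in range(i - 4, i)
                         for v in range(i + 1, i + 5)]
                assert ism[i] == pytest.approx(np.mean(cells))

    def test_wrong_resolution_rejected(self):
        with pytest.raises(ValueError, match="2000"):
            hic.ism_profile(ContactMatrix("c", 4000, np.ones((10, 10))))


class TestAveragedISm:
    def test_constant_flat(self):
        ism = np.full(100, 2.0)
        ism[:4] = np.nan
        ism[-4:] = np.nan
        offs, mean, n = hic.averaged_ism_around(ism, np.array([30, 50, 70]), 10)
        np.testing.assert_allclose(mean, 2.0)

    def test_single_gap_interpolated_midpoint(self):
        ism = np.arange(50, dtype=float)
        ism[20] = np.nan
        offs, mean, _ = hic.averaged_ism_around(ism, np.array([20]), 2)
        assert mean[2] == pytest.approx(20.0)   # midpoint of 19 and 21

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            hic.averaged_ism_around(np.ones(10), np.array([]), 2)


class TestCompartments:
    def _checkerboard_oe(self, seed=0, strength=0.4):
        n = 500
        lab = np.repeat(np.resize([1, -1], n // 25), 25)[:n]
        p = simulate.HiCSimParams(chrom_length=n * 2000,
                                  compartment_labels=lab,
                                  compartment_strength=strength,
                                  total_contacts=1_500_000, seed=seed)
        cm = simulate.simulate_hic(p)
        bal = hic.iterative_correction(hic.remove_short_range(cm))
        return hic.observed_over_expected(bal), lab

    def test_checkerboard_sign_recovered(self):
        oe, lab = self._checkerboard_oe()
        pc1 = hic.compartment_pc1(oe, orientation=lab.astype(float))
        ok = np.isfinite(pc1)
        assert (np.sign(pc1[ok]) == lab[ok]).mean() >= 0.95

    def test_orientation_contract(self):
        oe, lab = self._checkerboard_oe(seed=1)
        pc1 = hic.compartment_pc1(oe, orientation=lab.astype(float))
        ok = np.isfinite(pc1)
        assert np.corrcoef(pc1[ok], lab[ok].astype(float))[0, 1] >= 0

    def test_uniform_degenerate(self):
        oe = ContactMatrix("c", 10_000, np.ones((30, 30)))
        with pytest.raises(ValueError):
            hic.compartment_pc1(oe)

    def test_saddle_corners_exceed_off_corner(self):
        oe, lab = self._checkerboard_oe(seed=2)
        pc1 = hic.compartment_pc1(oe, orientation=lab.astype(float))
        sad = hic.saddle(oe, pc1, n_quantiles=40)
        g = sad.grid
        aa = np.nanmean(g[30:, 30:])
        bb = np.nanmean(g[:10, :10])
        ab = np.nanmean(g[:10, 30:])
        assert aa > ab and bb > ab

    def test_uniform_saddle_and_zero_difference(self):
        oe = ContactMatrix("c", 2000, np.ones((200, 200)), balanced=True)
        oe = hic.observed_over_expected(oe)
        pc1 = np.linspace(-1, 1, 200)   # arbitrary ordering on uniform map
        sad = hic.saddle(oe, pc1, n_quantiles=20)
        np.testing.assert_allclose(sad.grid, 1.0)
        diff = hic.saddle_difference_summary(sad, sad, k=5)
        for block in diff.values():
            assert block["median"] == 0.0
            assert block["p"] == 1.0

    def test_too_few_bins_rejected(self):
        oe = ContactMatrix("c", 2000, np.ones((10, 10)))
        with pytest.raises(ValueError):
            hic.saddle(oe, np.linspace(-1, 1, 10), n_quantiles=50)


class TestPileup:
    def test_all_ones(self):
        oe = ContactMatrix("c", 2000, np.ones((50, 50)))
        pile = hic.pileup_oe(oe, np.array([10, 25, 40]), 5)
        np.testing.assert_allclose(pile, 1.0)

    def test_single_anchor_identity(self):
        rng = np.random.default_rng(10)
        m = sym_random(rng, 30, 4.0)
        oe = ContactMatrix("c", 2000, m)
        pile = hic.pileup_oe(oe, np.array([15]), 4)
        np.testing.assert_allclose(pile, m[11:20, 11:20])

    def test_out_of_range_anchor_skipped(self):
        oe = ContactMatrix("c", 2000, np.ones((20, 20)))
        pile = hic.pileup_oe(oe, np.array([1, 10]), 5)   # first is skipped
        np.testing.assert_allclose(pile, 1.0)
        with pytest.raises(ValueError):
            hic.pileup_oe(oe, np.array([1]), 5)
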