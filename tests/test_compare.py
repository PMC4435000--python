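"""Random-window sampling, concordance, clustering, metagene and differences."""

import math

import numpy as np
import pytest

from dipscan.compare import (
    correlation_matrix,
    difference_track,
    metagene,
    pairwise_concordance,
    sample_random_windows,
)
from dipscan.genome import GeneModel, GenomicInterval, WindowGrid
from dipscan.window_quant import WindowTrack


def track(grid, values, sid="", units="cpm"):
    values = np.asarray(values, dtype=float)
    if units == "cpm":
        values = np.abs(values)
    return WindowTrack(grid, values, units=units, sample_id=sid)


GRID = WindowGrid({"chr1": 10_000}, 200)  # 50 windows


class TestSampleRandomWindows:
    def test_deterministic_given_seed(self):
        a = sample_random_windows(GRID, 10, seed=17)
        b = sample_random_windows(GRID, 10, seed=17)
        assert np.array_equal(a, b)
        assert len(set(a.tolist())) == 10

    def test_exhaustive_sample_is_full_index_set(self):
        idx = sample_random_windows(GRID, GRID.total_windows, seed=1)
        assert sorted(idx.tolist()) == list(range(GRID.total_windows))

    def test_oversampling_reports_maximum(self):
        with pytest.raises(ValueError, match=str(GRID.total_windows)):
            sample_random_windows(GRID, GRID.total_windows + 1, seed=0)

    def test_inclusion_frequency_is_binomial(self):
        grid = WindowGrid({"c": 4000}, 200)  # 20 windows
        n, trials = 5, 400
        freq = np.zeros(grid.total_windows)
        for seed in range(trials):
            freq[sample_random_windows(grid, n, seed=seed)] += 1
        p = n / grid.total_windows
        se = math.sqrt(p * (1 - p) / trials)
        assert np.all(np.abs(freq / trials - p) <= 3.5 * se)


class TestPairwiseConcordance:
    def test_self_correlation_is_one(self):
        t = track(GRID, np.arange(50), "t")
        r, r2 = pairwise_concordance(t, t, np.arange(50))
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_negated_track_gives_minus_one(self):
        values = np.arange(50, dtype=float)
        a = track(GRID, values, "a", units="log2_ratio")
        b = track(GRID, -values, "b", units="log2_ratio")
        r, r2 = pairwise_concordance(a, b, np.arange(50))
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        # hand computation: cov = 3.5, var_x = 5, var_y = 4.75
        grid = WindowGrid({"c": 800}, 200)
        a = track(grid, [1, 2, 3, 4])
        b = track(grid, [2, 4, 5, 4])
        r, r2 = pairwise_concordance(a, b, np.arange(4))
        expected = 3.5 / math.sqrt(5 * 4.75)
        assert r == pytest.approx(expected, rel=1e-12)
        assert r2 == pytest.approx(expected**2, rel=1e-12)

    def test_zero_variance_rejected(self):
        flat = track(GRID, np.ones(50), "flat")
        wavy = track(GRID, np.arange(50), "wavy")
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_concordance(flat, wavy, np.arange(50))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = track(GRID, rng.uniform(0, 10, 50), "a")
        b = track(GRID, rng.uniform(0, 10, 50), "b")
        idx = np.arange(50)
        rab = pairwise_concordance(a, b, idx)
        rba = pairwise_concordance(b, a, idx)
        assert rab[0] == pytest.approx(rba[0], rel=1e-12)
        assert rab[1] == pytest.approx(rba[1], rel=1e-12)


class TestCorrelationMatrix:
    def _tracks(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 100, 50)
        return [
            track(GRID, base, "rep1"),
            track(GRID, base + rng.normal(0, 0.01, 50), "rep2"),
            track(GRID, rng.uniform(0, 100, 50), "other"),
        ]

    def test_symmetric_unit_diagonal_bounded(self):
        mat = correlation_matrix(self._tracks(), np.arange(50))
        assert np.allclose(mat.r, mat.r.T)
        assert np.allclose(np.diag(mat.r), 1.0)
        assert np.all((mat.r >= -1) & (mat.r <= 1))

    def test_identical_pair_adjacent_after_clustering(self):
        mat = correlation_matrix(self._tracks(), np.arange(50))
        order = [mat.sample_ids[i] for i in mat.linkage_order]
        assert abs(order.index("rep1") - order.index("rep2")) == 1

    def test_permutation_equivariance(self):
        tracks = self._tracks()
        m1 = correlation_matrix(tracks, np.arange(50))
        m2 = correlation_matrix(tracks[::-1], np.arange(50))
        by_id1 = {
            (a, b): m1.r[i, j]
            for i, a in enumerate(m1.sample_ids)
            for j, b in enumerate(m1.sample_ids)
        }
        for i, a in enumerate(m2.sample_ids):
            for j, b in enumerate(m2.sample_ids):
                assert m2.r[i, j] == pytest.approx(by_id1[(a, b)], abs=1e-12)


class TestMetagene:
    GRID = WindowGrid({"chr1": 100_000}, 200)

    def _gene(self, start=40_000, length=10_000, strand="+", gid="g"):
        return GeneModel(gid, GenomicInterval("chr1", start, start + length, strand), strand)

    def test_constant_track_gives_flat_profile(self):
        t = track(self.GRID, np.full(500, 7.25), units="log2_ratio")
        profile = metagene(t, [self._gene()], n_body_bins=100)
        assert profile.values.shape == (150,)
        assert np.allclose(profile.values, 7.25, atol=1e-9)

    def test_step_signal_matches_brute_force_binning(self):
        gene = self._gene(40_000, 10_000)
        values = np.zeros(500)
        values[200:250] = 5.0  # exactly the gene body windows
        t = track(self.GRID, values, units="log2_ratio")
        profile = metagene(t, [gene], n_body_bins=100)
        # brute-force oracle: per-bin mean over a base-resolution signal
        base = np.zeros(100_000)
        base[40_000:50_000] = 5.0
        flank = 2_500
        edges = np.concatenate([
            np.linspace(40_000 - flank, 40_000, 26)[:-1],
            np.linspace(40_000, 50_000, 101)[:-1],
            np.linspace(50_000, 50_000 + flank, 26),
        ])
        oracle = [
            base[int(edges[i]) : int(edges[i + 1])].mean() for i in range(150)
        ]
        assert np.allclose(profile.values, oracle, atol=1e-9)
        assert np.allclose(profile.values[25:125], 5.0)
        assert np.allclose(profile.values[:25], 0.0)

    def test_minus_strand_mirrors_plus_strand(self):
        values = np.linspace(0, 10, 500)
        t = track(self.GRID, values, units="log2_ratio")
        plus = metagene(t, [self._gene(strand="+")], n_body_bins=40)
        minus = metagene(t, [self._gene(strand="-")], n_body_bins=40)
        assert np.allclose(plus.values, minus.values[::-1], atol=1e-9)

    def test_linearity_over_track_addition(self):
        rng = np.random.default_rng(5)
        genes = [self._gene(20_000, 8_000, "+", "g1"), self._gene(60_000, 12_000, "-", "g2")]
        a = track(self.GRID, rng.normal(size=500), units="log2_ratio")
        b = track(self.GRID, rng.normal(size=500), units="log2_ratio")
        summed = track(self.GRID, a.values + b.values, units="log2_ratio")
        pa = metagene(a, genes).values
        pb = metagene(b, genes).values
        ps = metagene(summed, genes).values
        assert np.allclose(ps, pa + pb, atol=1e-9)

    def test_flank_past_chromosome_end_drops_bins_only(self):
        gene = self._gene(start=500, length=10_000)  # upstream flank hits 0
        t = track(self.GRID, np.ones(500), units="log2_ratio")
        profile = metagene(t, [gene])
        assert profile.n_per_bin[0] == 0  # first upstream bin undefined
        assert profile.n_per_bin[30] == 1

    def test_empty_gene_set_rejected(self):
        t = track(self.GRID, np.ones(500), units="log2_ratio")
        with pytest.raises(ValueError, match="empty gene set"):
            metagene(t, [])


class TestDifferenceTrack:
    def _lr(self, values, sid=""):
        return WindowTrack(GRID, values, units="log2_ratio", sample_id=sid)

    def test_identity_difference_is_zero(self):
        a = self._lr(np.arange(50.0), "a")
        assert not difference_track(a, a).values.any()

    def test_antisymmetry_and_naming(self):
        rng = np.random.default_rng(6)
        a = self._lr(rng.normal(size=50), "pb")
        b = self._lr(rng.normal(size=50), "control")
        d1, d2 = difference_track(a, b), difference_track(b, a)
        assert np.allclose(d1.values, -d2.values)
        assert d1.sample_id == "pb_minus_control"

    def test_condition_specific_gain_dominates_positive_tail(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 0.2, 50)
        gained = slice(10, 20)  # the responsive locus' windows
        a_vals = noise + np.where(np.arange(50) >= 10, 0, 0)
        a_vals = a_vals.copy()
        a_vals[gained] += 2.0
        d = difference_track(self._lr(a_vals, "treated"), self._lr(noise, "control"))
        top10 = np.argsort(d.values)[-10:]
        assert set(top10) == set(range(10, 20))

    def test_units_mismatch_rejected(self):
        a = self._lr(np.arange(50.0))
        b = WindowTrack(GRID, np.arange(50.0), units="cpm", sample_id="b")
        with pytest.raises(ValueError, match="units"):
            difference_track(a, b)
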