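"""Generative model: determinism, protocol stages and the closed-form oracle."""

import dataclasses
import math

import numpy as np
import pytest

from dipscan.genome import GenomicInterval, WindowGrid
from dipscan.simulate import (
    EnrichedRegion,
    SimulationConfig,
    default_config,
    expected_window_enrichment,
    simulate_run,
    synthetic_gene_set,
)

from .conftest import small_sim_config


class TestConfigValidation:
    def test_disjoint_size_selection_rejected_before_generation(self):
        config = dataclasses.replace(
            small_sim_config(), size_select_min=600, size_select_max=700
        )
        with pytest.raises(ValueError, match="impossible config"):
            simulate_run(config)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="capture_efficiency"):
            dataclasses.replace(small_sim_config(), capture_efficiency=1.5).validate()

    def test_region_beyond_chromosome_rejected(self):
        config = dataclasses.replace(
            small_sim_config(),
            enriched_regions=(EnrichedRegion(GenomicInterval("simA", 0, 10**9), 5.0),),
        )
        with pytest.raises(ValueError, match="beyond"):
            config.validate()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_sam(self):
        config = dataclasses.replace(small_sim_config(3), n_fragments=50_000, n_reads=2_000)
        a, b = simulate_run(config), simulate_run(config)
        assert a.ip_sam == b.ip_sam
        assert a.input_sam == b.input_sam

    def test_different_seed_changes_output(self):
        config = dataclasses.replace(small_sim_config(3), n_fragments=50_000, n_reads=2_000)
        other = dataclasses.replace(config, seed=4)
        assert simulate_run(config).ip_sam != simulate_run(other).ip_sam

    def test_truth_reuse_keeps_marking_but_not_reads(self):
        config = dataclasses.replace(small_sim_config(3), n_fragments=50_000, n_reads=2_000)
        first = simulate_run(config)
        second = simulate_run(dataclasses.replace(config, seed=99), truth=first.truth)
        assert second.truth is first.truth
        assert second.ip_sam != first.ip_sam


class TestProtocolStages:
    def test_size_selection_bounds_all_fragments(self):
        # with an effectively unbounded read length, read length == fragment length
        config = dataclasses.replace(
            small_sim_config(8),
            n_fragments=50_000,
            n_reads=None,
            read_mean=5_000.0,
            read_sd=1.0,
        )
        result = simulate_run(config)
        for label in ("ip", "input"):
            lengths = result.diagnostics[label]["read_lengths"]
            assert lengths.min() >= config.size_select_min
            assert lengths.max() <= config.size_select_max

    def test_duplicates_flagged_when_resampling_exceeds_pool(self):
        config = dataclasses.replace(
            small_sim_config(8), n_fragments=40_000, n_reads=10_000
        )
        result = simulate_run(config)
        d = result.diagnostics["ip"]
        assert d["n_reads_emitted"] == 10_000
        assert d["n_duplicate_reads"] > 0
        # duplicate lines carry flag bit 1024
        flags = [int(l.split("\t")[1]) for l in result.ip_sam.splitlines()
                 if not l.startswith("@")]
        assert sum(1 for f in flags if f & 1024) == d["n_duplicate_reads"]

    def test_wga_without_bias_preserves_region_abundances(self):
        """Pre- vs post-amplification relative abundances agree when the
        per-fragment efficiency is constant (the in-silico no-WGA-bias check)."""
        config = dataclasses.replace(small_sim_config(12), n_fragments=400_000, n_reads=40_000)
        result = simulate_run(config)
        d = result.diagnostics["ip"]
        frac_pre = d["region_fragment_counts"] / d["n_distinct_fragments"]
        frac_post = d["region_read_counts"] / d["n_reads_emitted"]
        # binomial sampling tolerance: a few SE at these counts
        se = np.sqrt(frac_pre * (1 - frac_pre) / d["n_reads_emitted"])
        assert np.all(np.abs(frac_post - frac_pre) < 5 * se + 1e-4)

    def test_null_marking_gives_flat_ip(self):
        config = dataclasses.replace(
            small_sim_config(9), hmc_fraction=0.0, enriched_regions=(),
            n_fragments=200_000, n_reads=20_000,
        )
        result = simulate_run(config)
        assert all(len(v) == 0 for v in result.truth.marked_sites.values())


class TestExpectedEnrichment:
    def test_no_marked_sites_is_flat_at_unity(self):
        config = dataclasses.replace(
            small_sim_config(), hmc_fraction=0.0, enriched_regions=()
        )
        truth = simulate_run(
            dataclasses.replace(config, n_fragments=1_000, n_reads=10)
        ).truth
        grid = WindowGrid(config.genome, 200)
        exp = expected_window_enrichment(config, truth, grid)
        assert np.allclose(exp.values, 1.0)

    def test_single_site_plateau_matches_brute_force_enumeration(self):
        from dipscan.simulate import SimTruth

        config = SimulationConfig(
            seed=0, genome={"mini": 20_000}, n_fragments=1_000, n_reads=None,
            capture_efficiency=0.8, nonspecific_rate=0.05,
        )
        site = 10_000
        truth = SimTruth(marked_sites={"mini": np.array([site])}, region_multipliers={})
        grid = WindowGrid(config.genome, 200)
        exp = expected_window_enrichment(config, truth, grid, n_offsets=20, length_step=5)

        # independent brute force: every (midpoint, length) pair at 5 bp/5 bp
        lengths = np.arange(100, 251, 5)
        z = (lengths - 300.0) / 75.0
        wts = np.exp(-0.5 * z * z)
        wts /= wts.sum()
        oracle = np.zeros(grid.total_windows)
        for i in range(grid.total_windows):
            s, e = grid.window_bounds("mini", i)
            mids = np.arange(s, e, 10) + 5
            acc = 0.0
            for l, wt in zip(lengths, wts):
                starts = np.clip(mids - l // 2, 0, 20_000 - l)
                covers = (starts <= site) & (site < starts + l)
                acc += wt * np.mean(np.where(covers, 0.8, 0.05))
            oracle[i] = acc
        oracle /= oracle.mean()
        assert np.allclose(exp.values, oracle, rtol=0.05, atol=0.02)

        # plateau: windows within half the mean selected length are elevated
        peak_windows = exp.values[(site - 80) // 200 : (site + 80) // 200 + 1]
        assert np.all(peak_windows > 3.0)
        far = np.concatenate([exp.values[:10], exp.values[-10:]])
        assert np.allclose(far, far.mean(), rtol=0.05)

    def test_small_efficiency_regime_is_linear(self):
        from dipscan.simulate import SimTruth

        # nonspecific capture must be negligible for the doubling law: a
        # covering fragment's gain is e - ns, and the mean used for
        # normalization must stay floor-dominated, hence the large genome
        base = SimulationConfig(
            seed=0, genome={"mini": 500_000}, capture_efficiency=0.1,
            nonspecific_rate=0.001,
        )
        sites = np.array([100_000, 250_000, 400_000])
        truth = SimTruth(marked_sites={"mini": sites}, region_multipliers={})
        grid = WindowGrid(base.genome, 200)
        lo = expected_window_enrichment(base, truth, grid)
        hi = expected_window_enrichment(
            dataclasses.replace(base, capture_efficiency=0.2), truth, grid
        )
        # above-floor enrichment roughly doubles with capture efficiency
        # (1-(1-e)^1 = e exactly; normalization shifts cancel to first order)
        floor_lo, floor_hi = np.median(lo.values), np.median(hi.values)
        near = np.zeros(grid.total_windows, bool)
        for s in sites:
            near[s // 200] = True
        ratio = (hi.values[near] - floor_hi) / (lo.values[near] - floor_lo)
        assert np.all(np.abs(ratio - 2.0) < 0.2)


class TestMonteCarloAgainstOracle:
    def test_empirical_enrichment_tracks_expectation(self, small_sim):
        config, result = small_sim["config"], small_sim["result"]
        grid = small_sim["grid"]
        exp = expected_window_enrichment(config, result.truth, grid)
        ip = small_sim["ip"]
        emp = ip.values / ip.values.mean()
        enriched = np.zeros(grid.total_windows, bool)
        for region in result.truth.regions:
            off = grid.offset(region.chrom)
            for i in range(grid.n_windows(region.chrom)):
                s, e = grid.window_bounds(region.chrom, i)
                if s < region.end and region.start < e:
                    enriched[off + i] = True
        r = np.corrcoef(emp[enriched], exp.values[enriched])[0, 1]
        assert r > 0.8  # modest depth; the full-depth check lives in acceptance


def test_synthetic_gene_set_is_valid_annotation():
    genes = synthetic_gene_set({"simA": 200_000, "simB": 200_000}, n_genes=10)
    ids = [g.gene_id for g in genes]
    assert len(set(ids)) == len(ids)
    for g in genes:
        assert g.body.end <= 200_000
        assert g.body.start >= 0
    assert {g.strand for g in genes} == {"+", "-"}
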