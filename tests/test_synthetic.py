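"""Simulator unit tests: kinetic field, pooled/HU/ChIP/expression outputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replitimer.synthetic import (
    GenomeModel,
    OriginSpec,
    SimulationConfig,
    probe_grid,
    replication_field_one_cell,
    simulate_chip,
    simulate_expression,
    simulate_hu,
    simulate_pool,
)


def field(genome, times):
    return replication_field_one_cell(genome, times)


class TestReplicationField:
    def test_min_over_origins(self, two_origin_genome):
        cell = field(two_origin_genome, {("chrI", 0): 0.0, ("chrI", 100_000): 10.0})
        # halfway: left fork arrives at 50, right origin fork at 10 + 50 = 60
        assert cell.time_at("chrI", 50_000)[0] == pytest.approx(50.0)
        assert cell.time_at("chrI", 80_000)[0] == pytest.approx(30.0)

    def test_single_origin_linear(self):
        g = GenomeModel([("chrI", 100_000)], {"chrI": 50_000},
                        [OriginSpec("chrI", 0, 0.0)], 1_000.0, 200.0)
        cell = field(g, {("chrI", 0): 0.0})
        x = np.array([0, 10_000, 99_000])
        np.testing.assert_allclose(cell.time_at("chrI", x), x / 1_000.0)

    def test_passive_replication_silences_late_origin(self, two_origin_genome):
        cell = field(two_origin_genome, {("chrI", 0): 0.0, ("chrI", 100_000): 150.0})
        assert cell.fired[("chrI", 0)]
        assert not cell.fired[("chrI", 100_000)]
        # the fork from the left origin replicates the silenced one at 100 min
        assert cell.time_at("chrI", 100_000)[0] == pytest.approx(100.0)

    def test_tie_with_incoming_fork_fires(self, two_origin_genome):
        cell = field(two_origin_genome, {("chrI", 0): 0.0, ("chrI", 100_000): 100.0})
        assert cell.fired[("chrI", 100_000)]

    def test_missing_time_errors(self, two_origin_genome):
        with pytest.raises(ValueError, match="firing time"):
            field(two_origin_genome, {("chrI", 0): 0.0})

    def test_no_licensed_origin_errors(self):
        with pytest.raises(ValueError, match="chrI"):
            GenomeModel([("chrI", 100_000)], {},
                        [OriginSpec("chrI", 0, 0.0, licensed=False)],
                        1_000.0, 100.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        positions=st.lists(st.integers(0, 199_999), min_size=1, max_size=5,
                           unique=True),
        times=st.lists(st.floats(0, 100), min_size=5, max_size=5),
        x=st.integers(0, 199_999),
        y=st.integers(0, 199_999),
    )
    def test_field_is_lipschitz_in_position(self, positions, times, x, y):
        """|t(x) - t(y)| <= |x - y| / v: forks move at finite speed."""
        v = 1_000.0
        g = GenomeModel([("chrI", 200_000)], {},
                        [OriginSpec("chrI", p, 0.0) for p in positions],
                        v, 500.0)
        cell = field(g, {("chrI", p): t for p, t in zip(sorted(positions), times)})
        tx = cell.time_at("chrI", x)[0]
        ty = cell.time_at("chrI", y)[0]
        assert abs(tx - ty) <= abs(x - y) / v + 1e-9


class TestSimulatePool:
    def test_pooled_copy_matches_brute_force_enumeration(self, two_origin_genome,
                                                         noise_free_cfg):
        """Noise-free pooled log ratio equals the timepoint-enumeration oracle."""
        track = simulate_pool(two_origin_genome, noise_free_cfg)
        T = two_origin_genome.s_duration_T
        M = noise_free_cfg.n_timepoints
        tau = (np.arange(M) + 0.5) * T / M
        cell = field(two_origin_genome,
                     {("chrI", 0): 0.0, ("chrI", 100_000): 10.0})
        pos = track.positions("chrI")
        t = cell.time_at("chrI", pos)
        cbar = np.array([1.0 + np.mean(ti <= tau) for ti in t])
        expected = np.log2(cbar / cbar.mean())
        np.testing.assert_allclose(track.values("chrI"), expected, atol=1e-12)

    def test_closed_form_quarter_time(self):
        """A locus replicating at T/4 has pooled copy 1.75 (2 - t/T)."""
        g = GenomeModel([("chrI", 100_000)], {},
                        [OriginSpec("chrI", 0, 25.0)], 1e9, 100.0)
        cfg = SimulationConfig(probe_spacing=500, n_cells=1, n_timepoints=10_000,
                               noise_sd=0.0, rng_seed=0)
        track = simulate_pool(g, cfg)
        # infinite fork speed: every probe replicates at exactly t = 25 = T/4
        cbar_ratio = 2.0 ** track.values("chrI")
        assert np.allclose(cbar_ratio, 1.0)  # all equal to the genome mean
        # reconstruct absolute copy from the closed form at one locus
        M = 10_000
        tau = (np.arange(M) + 0.5) * 100.0 / M
        cbar = 1.0 + np.mean(25.0 <= tau)
        assert cbar == pytest.approx(1.75, abs=0.01)

    def test_extremes_of_replication_time(self):
        """t=0 loci pool to copy 2, t=T loci to copy 1."""
        g = GenomeModel([("chrA", 1_000), ("chrB", 1_000)],
                        {},
                        [OriginSpec("chrA", 500, 0.0), OriginSpec("chrB", 500, 100.0)],
                        1e9, 100.0)
        cfg = SimulationConfig(probe_spacing=500, n_cells=1, n_timepoints=2_000,
                               noise_sd=0.0, rng_seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            track = simulate_pool(g, cfg)
        ratio = 2.0 ** np.concatenate([track.values("chrA"), track.values("chrB")])
        copies = ratio * 1.5  # genome mean of {2, 1} is 1.5
        assert np.allclose(copies[:2], 2.0, atol=1e-3)
        assert np.allclose(copies[2:], 1.0, atol=1e-3)

    def test_pooled_value_monotone_in_replication_time(self, two_origin_genome,
                                                       noise_free_cfg):
        track = simulate_pool(two_origin_genome, noise_free_cfg)
        cell = field(two_origin_genome,
                     {("chrI", 0): 0.0, ("chrI", 100_000): 10.0})
        t = cell.time_at("chrI", track.positions("chrI"))
        v = track.values("chrI")
        order = np.argsort(t)
        assert np.all(np.diff(v[order]) <= 1e-12)


class TestSimulateHU:
    def make_genome(self, origins, length=200_000, v=1_000.0, T=100.0):
        return GenomeModel([("chrI", length)], {}, origins, v, T)

    def test_track_length_is_fork_travel(self):
        g = self.make_genome([OriginSpec("chrI", 100_000, 5.0)])
        cfg = SimulationConfig(probe_spacing=500, n_cells=1, noise_sd=0.0, rng_seed=0)
        track = simulate_hu(g, 15.0, cfg)
        pos = track.positions("chrI")
        vals = track.values("chrI")
        inside = np.abs(pos - 100_000) <= 10_000  # v * (15 - 5)
        assert len(np.unique(np.round(vals[inside], 9))) == 1
        assert vals[inside].max() > vals[~inside].max()
        # replicated set is exactly the fork interval on the probe grid
        expected = np.abs(pos.astype(float) - 100_000) / 1_000.0 + 5.0 <= 15.0
        assert np.array_equal(inside, expected)

    def test_origin_at_arrest_time_does_not_fire(self):
        g = self.make_genome([OriginSpec("chrI", 100_000, 15.0)])
        cfg = SimulationConfig(probe_spacing=500, n_cells=1, noise_sd=0.0, rng_seed=0)
        track = simulate_hu(g, 15.0, cfg)
        assert np.allclose(track.values("chrI"), 0.0)  # flat: copy 1 everywhere

    def test_two_plateaus_with_valley(self):
        g = self.make_genome([OriginSpec("chrI", 50_000, 0.0),
                              OriginSpec("chrI", 150_000, 0.0)])
        cfg = SimulationConfig(probe_spacing=500, n_cells=1, noise_sd=0.0, rng_seed=0)
        track = simulate_hu(g, 20.0, cfg)
        pos = track.positions("chrI")
        vals = track.values("chrI")
        mid = vals[np.abs(pos - 100_000) < 5_000]
        peaks = vals[(np.abs(pos - 50_000) < 5_000) | (np.abs(pos - 150_000) < 5_000)]
        assert peaks.min() > mid.max()
        # replicated fraction equals merged track length / genome length
        frac_probes = np.mean(vals > vals.min() + 0.5 * (vals.max() - vals.min()))
        assert frac_probes == pytest.approx(2 * 40_000 / 200_000, abs=0.01)

    def test_invalid_arrest_times(self):
        g = self.make_genome([OriginSpec("chrI", 100_000, 5.0)])
        cfg = SimulationConfig(noise_sd=0.0)
        with pytest.raises(ValueError):
            simulate_hu(g, 0.0, cfg)
        with pytest.raises(ValueError):
            simulate_hu(g, 100.0, cfg)

    def test_truth_fired_counts(self):
        g = self.make_genome([OriginSpec("chrI", 50_000, 5.0),
                              OriginSpec("chrI", 150_000, 50.0)])
        cfg = SimulationConfig(probe_spacing=500, n_cells=3, noise_sd=0.0, rng_seed=0)
        _, fired = simulate_hu(g, 15.0, cfg, return_truth=True)
        assert fired[("chrI", 50_000)] == 3
        assert fired[("chrI", 150_000)] == 0


class TestSimulateChip:
    def setup_method(self):
        self.genome = GenomeModel(
            [("chrI", 100_000)], {}, [OriginSpec("chrI", 0, 0.0)], 1_000.0, 60.0)
        self.sites = [("chrI", 20_000, 20_400), ("chrI", 60_000, 60_400)]

    def test_noise_free_plateaus(self):
        cfg = SimulationConfig(probe_spacing=500, noise_sd=0.0,
                               chip_log2_enrichment=2.0, chip_site_halfwidth=250)
        reps = simulate_chip(self.genome, self.sites, cfg)
        for rep in reps.replicates:
            pos, vals = rep.positions("chrI"), rep.values("chrI")
            in_site = np.zeros(pos.size, bool)
            for _, s, e in self.sites:
                in_site |= (pos >= s - 250) & (pos < e + 250)
            assert np.all(vals[in_site] == 2.0)
            assert np.all(vals[~in_site] == 0.0)

    def test_noisy_site_mean_within_clt_bound(self):
        cfg = SimulationConfig(probe_spacing=100, noise_sd=0.3,
                               chip_log2_enrichment=2.0, rng_seed=11)
        reps = simulate_chip(self.genome, self.sites, cfg)
        rep = reps.replicates[0]
        pos, vals = rep.positions("chrI"), rep.values("chrI")
        in_site = np.zeros(pos.size, bool)
        for _, s, e in self.sites:
            in_site |= (pos >= s - 250) & (pos < e + 250)
        n = in_site.sum()
        assert abs(vals[in_site].mean() - 2.0) < 3 * 0.3 / np.sqrt(n)

    def test_empty_site_list_is_pure_noise(self):
        cfg = SimulationConfig(probe_spacing=100, noise_sd=0.3, rng_seed=2)
        reps = simulate_chip(self.genome, [], cfg)
        vals = reps.replicates[0].values("chrI")
        assert abs(vals.mean()) < 3 * 0.3 / np.sqrt(vals.size)

    def test_overlapping_sites_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="overlap"):
            simulate_chip(self.genome,
                          [("chrI", 100, 500), ("chrI", 400, 900)], cfg)


class TestSimulateExpression:
    GENES = [("g1", "chrI", 0, 1000), ("g2", "chrI", 2000, 3000)]

    def test_zero_means_zero_noise(self):
        df = simulate_expression(self.GENES, SimulationConfig(noise_sd=0.0))
        assert np.all(df["condA"] == 0.0) and np.all(df["condB"] == 0.0)

    def test_shift_detected_within_clt_bound(self):
        genes = [(f"g{i}", "chrI", i * 100, i * 100 + 50) for i in range(400)]
        cfg = SimulationConfig(noise_sd=1.0, rng_seed=4)
        df = simulate_expression(genes, cfg, means_a=np.ones(400))
        diff = (df["condA"] - df["condB"]).mean()
        assert abs(diff - 1.0) < 3 * np.sqrt(2) / np.sqrt(400)

    def test_empty_gene_list(self):
        df = simulate_expression([], SimulationConfig())
        assert df.empty and list(df.columns)[:2] == ["gene", "chrom"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_expression([("g1", "chrI", 0, 10), ("g1", "chrI", 20, 30)],
                                SimulationConfig())


class TestDeterminism:
    def test_same_seed_identical_different_seed_not(self, two_origin_genome, tmp_path):
        cfg = SimulationConfig(probe_spacing=500, n_cells=3, noise_sd=0.2, rng_seed=9)
        a = simulate_pool(two_origin_genome, cfg)
        b = simulate_pool(two_origin_genome, cfg)
        assert a == b
        pa, pb = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        a.write(pa)
        b.write(pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = simulate_pool(two_origin_genome,
                          SimulationConfig(probe_spacing=500, n_cells=3,
                                           noise_sd=0.2, rng_seed=10))
        assert not (a == c)

    def test_pooled_copy_bounds(self, two_origin_genome):
        """Pooled copy stays in [1, 2] for any jitter/noise-free draw."""
        cfg = SimulationConfig(probe_spacing=1_000, n_cells=5, noise_sd=0.0,
                               rng_seed=3)
        g = GenomeModel(two_origin_genome.chromosomes,
                        two_origin_genome.centromere_pos,
                        [OriginSpec("chrI", 0, 10.0, 5.0),
                         OriginSpec("chrI", 100_000, 30.0, 5.0)],
                        two_origin_genome.fork_speed_v, 500.0)
        track = simulate_pool(g, cfg)
        ratio = 2.0 ** track.values("chrI")
        gm_lo, gm_hi = 1.0, 2.0
        # ratio * genome_mean must lie in [1, 2]; genome mean itself in [1, 2]
        assert ratio.min() * gm_lo <= 2.0 and ratio.max() * gm_hi >= 1.0
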