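"""Ground-truth verification scenarios built on the forward simulator.

Each constructor returns a simulated dataset together with the analytic
truth it encodes, so the downstream pipeline stages can be checked
against closed-form answers: a noise-free pooled profile whose relative
replication time is known exactly, a ChIP fixture with known site
positions, an HU arrest with a known fired-origin set, and a genome in
which centromere-proximal origins fire a fixed fraction of S phase
early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import ReplicateSet
from .sites import BindingSite
from .synthetic import (
    GenomeModel,
    OriginSpec,
    SimulationConfig,
    probe_grid,
    replication_field_one_cell,
    simulate_chip,
    simulate_hu,
    simulate_pool,
)

__all__ = [
    "PoolOracle",
    "noise_free_pool_scenario",
    "site_recovery_scenario",
    "hu_arrest_scenario",
    "centromere_timing_scenario",
]


@dataclass
class PoolOracle:
    """A pooled-S measurement with exact analytic replication times."""

    genome: GenomeModel
    config: SimulationConfig
    track: object                      # ProbeTable
    analytic_time: dict[str, np.ndarray]  # per-chromosome t(x) at probes, min
    s_duration: float                  # T used, = max unmasked analytic time

    def analytic_trep(self, chrom: str) -> np.ndarray:
        return self.analytic_time[chrom] / self.s_duration

    def unmasked_probe_mask(self, chrom: str, end_exclusion: int = 25_000) -> np.ndarray:
        pos = self.track.positions(chrom)
        length = self.genome.lengths[chrom]
        return (pos >= end_exclusion) & (pos < length - end_exclusion)


def noise_free_pool_scenario(n_chrom: int = 4, length: int = 1_000_000,
                             probe_spacing: int = 500,
                             n_timepoints: int = 200) -> PoolOracle:
    """Noise-free, jitter-free pooled profile with exact t(x).

    Two origins per chromosome (at 25% and 75% of the length) with firing
    times staggered across chromosomes so replication time spans the
    whole of S; fork speed 10 kb/min.  The S-phase duration is set to
    the latest analytic replication time outside the 25 kb end-exclusion
    zones, so relative time t(x)/T spans exactly [0, 1] on the unmasked
    genome and the pipeline's min-max trep is directly comparable.
    """
    fork_speed = 10_000.0
    chroms = [(f"chr{i + 1}", length) for i in range(n_chrom)]
    origins = []
    for i, (name, _) in enumerate(chroms):
        origins.append(OriginSpec(name, length // 4, 60.0 * i, 0.0))
        origins.append(OriginSpec(name, 3 * length // 4, 60.0 * i + 30.0, 0.0))
    centromeres = {name: length // 2 for name, _ in chroms}
    provisional = GenomeModel(chroms, centromeres, origins, fork_speed, 1e9)
    cfg = SimulationConfig(probe_spacing=probe_spacing, n_cells=1,
                           n_timepoints=n_timepoints, noise_sd=0.0, rng_seed=0)
    times = {(o.chromosome, o.position): o.mean_firing_time for o in origins}
    cell = replication_field_one_cell(provisional, times)
    grid = probe_grid(provisional, probe_spacing)
    analytic = {c: cell.time_at(c, p) for c, p in grid.items()}
    t_max = 0.0
    for name, ln in chroms:
        pos = grid[name]
        keep = (pos >= 25_000) & (pos < ln - 25_000)
        t_max = max(t_max, float(analytic[name][keep].max()))
    genome = GenomeModel(chroms, centromeres, origins, fork_speed, t_max)
    with warnings.catch_warnings():
        # loci inside the end-exclusion zones replicate after T by design
        warnings.simplefilter("ignore", UserWarning)
        track = simulate_pool(genome, cfg)
    return PoolOracle(genome, cfg, track, analytic, t_max)


def site_recovery_scenario(n_sites: int = 40, noise_sd: float = 0.5,
                           enrichment: float = 2.0, seed: int = 0,
                           probe_spacing: int = 500):
    """ChIP fixture with known site positions at the given signal-to-noise.

    ``n_sites`` sites of 400 bp are spread over four chromosomes at the
    yeast-like spacing of one origin per 60 kb; three replicate tracks
    carry the plateau enrichment over Gaussian background noise.
    Returns ``(reps, true_sites, cfg)`` where ``true_sites`` are
    (chromosome, start, end) tuples.
    """
    per_chrom = n_sites // 4
    length = 60_000 * per_chrom + 30_000
    chroms = [(f"chr{i + 1}", length) for i in range(4)]
    sites = []
    for i, (name, _) in enumerate(chroms):
        for j in range(per_chrom):
            mid = 30_000 + 60_000 * j
            sites.append((name, mid - 200, mid + 200))
    # simulate_chip needs a genome only for its probe grid
    dummy = [OriginSpec(name, 1_000, 0.0) for name, _ in chroms]
    genome = GenomeModel(chroms, {n: length // 2 for n, _ in chroms},
                         dummy, 1_000.0, 60.0)
    cfg = SimulationConfig(probe_spacing=probe_spacing, noise_sd=noise_sd,
                           chip_log2_enrichment=enrichment,
                           chip_site_halfwidth=250, n_replicates=3,
                           rng_seed=seed)
    reps = simulate_chip(genome, sites, cfg)
    return reps, sites, cfg


def hu_arrest_scenario(n_early: int = 12, n_origins: int = 40,
                       noise_sd: float = 0.0, seed: int = 0):
    """HU arrest in which exactly ``n_early`` of ``n_origins`` origins fire.

    Origins sit 120 kb apart on four chromosomes; the early subset fires
    at 5 min, the rest at 30 min, and the arrest at 20 min lets each
    early fork run 30 kb — tracks are separated by more than two track
    widths, so no origin is passively covered.  Returns
    ``(genome, track, sites, early_keys, arrest_time)`` where ``sites``
    are BindingSites at every origin and ``early_keys`` the set of site
    keys expected to be called replicated.
    """
    length = 1_200_000
    per_chrom = n_origins // 4
    early_per_chrom = n_early // 4
    arrest = 20.0
    chroms = [(f"chr{i + 1}", length) for i in range(4)]
    origins, early_positions = [], set()
    for i, (name, _) in enumerate(chroms):
        for j in range(per_chrom):
            pos = 60_000 + 120_000 * j
            # spread the early origins across the chromosome
            is_early = j % max(per_chrom // early_per_chrom, 1) == 0 and \
                sum(1 for c, _p in early_positions if c == name) < early_per_chrom
            mu = 5.0 if is_early else 30.0
            if is_early:
                early_positions.add((name, pos))
            origins.append(OriginSpec(name, pos, mu, 0.0))
    genome = GenomeModel(chroms, {n: length // 2 for n, _ in chroms},
                         origins, 2_000.0, 100.0)
    cfg = SimulationConfig(probe_spacing=500, n_cells=1, noise_sd=noise_sd,
                           rng_seed=seed)
    track = simulate_hu(genome, arrest, cfg)
    sites = [BindingSite(o.chromosome, o.position - 200, o.position + 200,
                         o.position) for o in origins]
    early_keys = {s.key for s in sites
                  if (s.chromosome, s.anchor) in early_positions}
    return genome, track, sites, early_keys, arrest


def centromere_timing_scenario(advance_fraction: float = 0.2, seed: int = 0,
                               noise_sd: float = 0.1):
    """Genome in which centromere-proximal origins fire earlier in S.

    Origins every 100 kb on four 1 Mb chromosomes; the centromere sits
    at 480 kb so exactly one origin per chromosome lies within 50 kb of
    it.  Near-centromere origins fire ``advance_fraction`` of the
    S-phase duration earlier than the 30-min baseline.  Returns
    ``(genome, track, sites, distances_truth)``.
    """
    length = 1_000_000
    t_total = 70.0
    chroms = [(f"chr{i + 1}", length) for i in range(4)]
    centromeres = {name: 480_000 for name, _ in chroms}
    origins = []
    for name, _ in chroms:
        for pos in range(50_000, length, 100_000):
            near = abs(pos - centromeres[name]) <= 50_000
            mu = 30.0 - (advance_fraction * t_total if near else 0.0)
            origins.append(OriginSpec(name, pos, mu, 2.0))
    genome = GenomeModel(chroms, centromeres, origins, 2_000.0, t_total)
    cfg = SimulationConfig(probe_spacing=500, n_cells=50, n_timepoints=200,
                           noise_sd=noise_sd, rng_seed=seed)
    track = simulate_pool(genome, cfg)
    sites = [BindingSite(o.chromosome, o.position - 200, o.position + 200,
                         o.position) for o in origins]
    return genome, track, sites
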