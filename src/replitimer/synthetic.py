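"""Forward simulator of S-phase replication and the array measurements.

The kinetic model is the standard one for population replication timing:
each licensed origin i at position ``o_i`` fires at a per-cell time
``t_i`` (Gaussian around its mean, truncated at 0), forks move outward at
constant speed ``v``, and the time at which locus x replicates in one
cell is

    t(x) = min_i [ t_i + |x - o_i| / v ]

over the licensed origins of the chromosome.  An origin whose position is
reached by an incoming fork strictly before its own firing time is
passively replicated and never fires.

Measurements are emulated on a deterministic probe grid:

* pooled S/G1 copy number — cells sampled at uniform times through S are
  pooled, so the expected copy number at x is ``2 - t(x)/T`` and the
  emitted log2 ratio (vs the genome mean copy) is affine-invertible back
  to replication time;
* hydroxyurea (HU) arrest — only origins firing before the arrest time
  fire, forks travel ``v * (tau_HU - t_i)`` bp and stall;
* ChIP enrichment — site-shaped plateaus of fixed log2 enrichment over a
  Gaussian background, in replicate;
* expression tables — per-gene log-expression around configured means.

All outputs are deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import ProbeTable, ReplicateSet

__all__ = [
    "OriginSpec",
    "GenomeModel",
    "SimulationConfig",
    "CellField",
    "replication_field_one_cell",
    "realized_firing_times",
    "simulate_pool",
    "simulate_hu",
    "simulate_chip",
    "simulate_expression",
    "probe_grid",
]


@dataclass(frozen=True)
class OriginSpec:
    """A licensed (or unlicensed) replication origin."""

    chromosome: str
    position: int            # bp
    mean_firing_time: float  # min
    firing_jitter: float = 0.0  # per-cell Gaussian sd, min
    licensed: bool = True

    def __post_init__(self):
        if self.mean_firing_time < 0:
            raise ValueError("mean firing time must be >= 0")
        if self.firing_jitter < 0:
            raise ValueError("firing jitter must be >= 0")


@dataclass
class GenomeModel:
    """Chromosome geometry plus origin firing kinetics (simulation truth)."""

    chromosomes: list[tuple[str, int]]
    centromere_pos: dict[str, int]
    origins: list[OriginSpec]
    fork_speed_v: float   # bp/min
    s_duration_T: float   # min

    def __post_init__(self):
        if self.fork_speed_v <= 0:
            raise ValueError("fork speed must be > 0")
        if self.s_duration_T <= 0:
            raise ValueError("S-phase duration must be > 0")
        lengths = dict(self.chromosomes)
        for o in self.origins:
            if o.chromosome not in lengths:
                raise ValueError(f"origin on unknown chromosome {o.chromosome}")
            if not 0 <= o.position < lengths[o.chromosome]:
                raise ValueError(f"origin position {o.position} outside {o.chromosome}")
        for c, p in self.centromere_pos.items():
            if c not in lengths or not 0 <= p < lengths[c]:
                raise ValueError(f"centromere position {p} outside {c}")
        order = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        self.origins = sorted(self.origins, key=lambda o: (order[o.chromosome], o.position))
        for name, _ in self.chromosomes:
            if not any(o.chromosome == name and o.licensed for o in self.origins):
                raise ValueError(f"chromosome {name} has no licensed origin")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def licensed_origins(self, chrom: str) -> list[OriginSpec]:
        return [o for o in self.origins if o.chromosome == chrom and o.licensed]


@dataclass
class SimulationConfig:
    """Knobs of the measurement model.

    Defaults emulate a yeast tiled array sampled every 500 bp, with three
    replicate hybridizations, per-probe log2 noise of 0.1, and ChIP peaks
    of log2 enrichment 2 spanning about 500 bp.
    """

    probe_spacing: int = 500         # bp
    n_cells: int = 100
    n_timepoints: int = 200          # uniform through [0, T]
    noise_sd: float = 0.1            # log2 units per probe
    chip_site_halfwidth: int = 250   # bp
    chip_log2_enrichment: float = 2.0
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def probe_grid(genome: GenomeModel, spacing: int) -> dict[str, np.ndarray]:
    """Deterministic probe positions: ``spacing*k + spacing//2`` per chromosome."""
    return {
        name: np.arange(spacing // 2, length, spacing, dtype=np.int64)
        for name, length in genome.chromosomes
    }


@dataclass
class CellField:
    """Single-cell replication-time field t(x) and realized origin fates."""

    genome: GenomeModel
    firing_times: dict[tuple[str, int], float]  # (chrom, position) -> realized t_i
    fired: dict[tuple[str, int], bool]

    def time_at(self, chrom: str, x) -> np.ndarray:
        """Evaluate t(x) = min_i [t_i + |x - o_i| / v] at positions x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        origins = self.genome.licensed_origins(chrom)
        v = self.genome.fork_speed_v
        times = np.stack([
            self.firing_times[(chrom, o.position)] + np.abs(x - o.position) / v
            for o in origins
        ])
        return times.min(axis=0)


def realized_firing_times(genome: GenomeModel,
                          rng: np.random.Generator) -> dict[tuple[str, int], float]:
    """Draw per-cell firing times: Gaussian(mu, sigma) truncated at 0."""
    out = {}
    for o in genome.origins:
        if not o.licensed:
            continue
        if o.firing_jitter == 0:
            t = o.mean_firing_time
        else:
            a = (0.0 - o.mean_firing_time) / o.firing_jitter
            t = float(stats.truncnorm.rvs(
                a, np.inf, loc=o.mean_firing_time, scale=o.firing_jitter,
                random_state=rng))
        out[(o.chromosome, o.position)] = t
    return out


def replication_field_one_cell(
    genome: GenomeModel,
    firing_times: dict[tuple[str, int], float],
) -> CellField:
    """Resolve one cell's replication-time field and origin fates.

    An origin fires iff its own firing time is not strictly preceded by
    the arrival of a fork from any other licensed origin on the
    chromosome; a tie fires the origin.
    """
    fired: dict[tuple[str, int], bool] = {}
    for name, _ in genome.chromosomes:
        origins = genome.licensed_origins(name)
        if not origins:
            raise ValueError(f"chromosome {name} has no licensed origin")
        for t in origins:
            key = (name, t.position)
            if key not in firing_times or not np.isfinite(firing_times[key]):
                raise ValueError(f"missing realized firing time for origin at {key}")
        v = genome.fork_speed_v
        for o in origins:
            t_o = firing_times[(name, o.position)]
            arrivals = [
                firing_times[(name, q.position)] + abs(o.position - q.position) / v
                for q in origins if q.position != o.position
            ]
            fired[(name, o.position)] = not any(a < t_o for a in arrivals)
    return CellField(genome, dict(firing_times), fired)


def _ratio_track(genome: GenomeModel, copy: dict[str, np.ndarray],
                 grid: dict[str, np.ndarray], noise_sd: float,
                 rng: np.random.Generator) -> ProbeTable:
    """log2(copy / genome-mean copy) + Gaussian probe noise."""
    genome_mean = float(np.mean(np.concatenate(list(copy.values()))))
    data = {}
    for chrom, pos in grid.items():
        val = np.log2(copy[chrom] / genome_mean)
        if noise_sd > 0:
            val = val + rng.normal(0.0, noise_sd, size=val.shape)
        data[chrom] = (pos, val)
    return ProbeTable(data)


def simulate_pool(genome: GenomeModel, cfg: SimulationConfig,
                  *, return_truth: bool = False):
    """Pooled S-phase vs G1 copy-number measurement.

    Cells are sampled at ``n_timepoints`` uniform times through [0, T]
    (midpoint grid, so the noise-free pooled copy number equals
    ``2 - t(x)/T`` to within ``T / (2 n_timepoints)``); a locus counts
    copy 2 in a sample iff it has replicated by the sample time.  Probe
    values are log2 of pooled copy over the genome-mean copy, plus
    Gaussian noise.
    """
    rng = cfg.rng()
    grid = probe_grid(genome, cfg.probe_spacing)
    T = genome.s_duration_T
    tau = (np.arange(cfg.n_timepoints) + 0.5) * T / cfg.n_timepoints
    copy = {c: np.zeros(p.size) for c, p in grid.items()}
    cells = []
    clipped = False
    for _ in range(cfg.n_cells):
        cell = replication_field_one_cell(genome, realized_firing_times(genome, rng))
        cells.append(cell)
        for chrom, pos in grid.items():
            t = cell.time_at(chrom, pos)
            if t.max() >= T:
                clipped = True
            # fraction of pool samples in which the locus has copy 2
            frac = (cfg.n_timepoints - np.searchsorted(tau, t, side="left")) / cfg.n_timepoints
            copy[chrom] += 1.0 + frac
    if clipped:
        warnings.warn(
            "some loci replicate after T; their pooled copy is clipped at 1",
            stacklevel=2,
        )
    copy = {c: v / cfg.n_cells for c, v in copy.items()}
    table = _ratio_track(genome, copy, grid, cfg.noise_sd, rng)
    if return_truth:
        return table, cells
    return table


def simulate_hu(genome: GenomeModel, arrest_time: float, cfg: SimulationConfig,
                *, return_truth: bool = False):
    """Partial replication under HU arrest at ``arrest_time`` minutes.

    Only origins with realized firing time strictly before the arrest
    fire; each fork travels ``v * (arrest - t_i)`` bp and stalls.  Copy
    number at a probe is 2 if any fired fork has passed it, else 1,
    averaged over cells.
    """
    if arrest_time <= 0:
        raise ValueError("arrest time must be > 0")
    if arrest_time >= genome.s_duration_T:
        raise ValueError("arrest time must precede the end of S phase")
    rng = cfg.rng()
    grid = probe_grid(genome, cfg.probe_spacing)
    copy = {c: np.zeros(p.size) for c, p in grid.items()}
    fired_counts: dict[tuple[str, int], int] = {
        (o.chromosome, o.position): 0 for o in genome.origins if o.licensed
    }
    for _ in range(cfg.n_cells):
        times = realized_firing_times(genome, rng)
        early = {k: t for k, t in times.items() if t < arrest_time}
        for chrom, pos in grid.items():
            chrom_early = {k: t for k, t in early.items() if k[0] == chrom}
            if chrom_early:
                t = np.min(np.stack([
                    t_i + np.abs(pos - k[1]) / genome.fork_speed_v
                    for k, t_i in chrom_early.items()
                ]), axis=0)
                replicated = t <= arrest_time
            else:
                replicated = np.zeros(pos.size, dtype=bool)
            copy[chrom] += np.where(replicated, 2.0, 1.0)
        for k, t_i in early.items():
            arrivals = [
                t_j + abs(k[1] - q[1]) / genome.fork_speed_v
                for q, t_j in early.items() if q != k and q[0] == k[0]
            ]
            if not any(a < t_i for a in arrivals):
                fired_counts[k] += 1
    copy = {c: v / cfg.n_cells for c, v in copy.items()}
    table = _ratio_track(genome, copy, grid, cfg.noise_sd, rng)
    if return_truth:
        return table, fired_counts
    return table


def simulate_chip(genome: GenomeModel, sites, cfg: SimulationConfig) -> ReplicateSet:
    """Replicated ChIP tracks: plateaus of ``chip_log2_enrichment`` within
    each site extended by ``chip_site_halfwidth``, Gaussian noise elsewhere.

    ``sites`` is an iterable of (chromosome, start, end) half-open
    intervals, non-overlapping per track.
    """
    site_list = sorted(sites, key=lambda s: (s[0], s[1]))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in site_list:
        if start >= end:
            raise ValueError(f"site with start >= end on {chrom}")
        prev = by_chrom.setdefault(chrom, [])
        if prev and start < prev[-1][1]:
            raise ValueError(f"overlapping sites on {chrom} at {start}")
        prev.append((int(start), int(end)))
    rng = cfg.rng()
    grid = probe_grid(genome, cfg.probe_spacing)
    reps = []
    for _ in range(cfg.n_replicates):
        data = {}
        for chrom, pos in grid.items():
            mean = np.zeros(pos.size)
            for start, end in by_chrom.get(chrom, []):
                lo = start - cfg.chip_site_halfwidth
                hi = end + cfg.chip_site_halfwidth
                mean[(pos >= lo) & (pos < hi)] = cfg.chip_log2_enrichment
            if cfg.noise_sd > 0:
                mean = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
            data[chrom] = (pos, mean)
        reps.append(ProbeTable(data))
    return ReplicateSet("chip", reps)


def simulate_expression(genes, cfg: SimulationConfig,
                        means_a=None, means_b=None,
                        labels: tuple[str, str] = ("condA", "condB")) -> pd.DataFrame:
    """Two-condition log-expression table for the given genes.

    ``genes`` is an iterable of (id, chromosome, start, end); per-gene
    means default to 0 and noise is ``cfg.noise_sd``.
    """
    genes = list(genes)
    ids = [g[0] for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {', '.join(map(str, dup))}")
    rng = cfg.rng()
    n = len(genes)
    mu_a = np.zeros(n) if means_a is None else np.asarray(means_a, float)
    mu_b = np.zeros(n) if means_b is None else np.asarray(means_b, float)
    if mu_a.shape != (n,) or mu_b.shape != (n,):
        raise ValueError("per-gene means must match the number of genes")
    noise = rng.normal(0.0, cfg.noise_sd, size=(2, n)) if cfg.noise_sd > 0 else np.zeros((2, n))
    return pd.DataFrame({
        "gene": ids,
        "chrom": [g[1] for g in genes],
        "start": [g[2] for g in genes],
        "end": [g[3] for g in genes],
        labels[0]: mu_a + noise[0],
        labels[1]: mu_b + noise[1],
    })


def write_ground_truth(path, genome: GenomeModel, cells: list[CellField]) -> None:
    """JSON sidecar with per-cell realized firing times and fired flags."""
    payload = {
        "fork_speed_v": genome.fork_speed_v,
        "s_duration_T": genome.s_duration_T,
        "cells": [
            {
                "firing_times": {f"{c}:{p}": t for (c, p), t in cell.firing_times.items()},
                "fired": {f"{c}:{p}": bool(f) for (c, p), f in cell.fired.items()},
            }
            for cell in cells
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
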