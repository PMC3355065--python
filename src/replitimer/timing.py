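"""Replication-timing profiles and the meiS/mitS scaling model.

The pooled-S/G1 log2 ratio track is smoothed per chromosome by local
linear (loess-style) regression with tricube weights, predicted on a
fixed 50 bp grid.  Because pooling over uniform sample times makes the
expected copy number affine in replication time (``2 - t/T``), the
smoothed log ratio is inverted to the linear copy scale and min-max
rescaled into a relative replication time ``trep`` in [0, 1]
(0 = earliest locus, 1 = latest).  The 25 kb at each chromosome end are
excluded from all genome-wide statistics: the smoother cannot anchor
predictions beyond the data edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import ProbeTable
from .sites import BindingSite

__all__ = [
    "ChromosomeProfile",
    "TimingProfile",
    "OriginTiming",
    "ScalingModel",
    "smooth_profile",
    "signal_to_trep",
    "site_timing",
    "call_hu_replicated",
    "compare_conditions",
    "fit_scaling_model",
    "timing_distribution",
]

END_EXCLUSION_BP = 25_000
GRID_STEP_BP = 50
LOESS_SPAN = 0.025


def _loess_chromosome(pos: np.ndarray, val: np.ndarray, grid: np.ndarray,
                      k: int) -> np.ndarray:
    """Tricube-weighted local linear regression at each grid point.

    For each evaluation point the ``k`` nearest probes (a contiguous
    window in the sorted positions) are fitted with weights
    ``(1 - (d/dmax)^3)^3``; the fitted value at the point is returned.
    Reproduces constants exactly and degree-1 polynomials to rounding.
    """
    n = pos.size
    k = min(k, n)
    x = pos.astype(float)
    # window starts: choose the contiguous k-window whose extremes bracket
    # the evaluation point most tightly (midpoint of extremes closest).
    m = n - k + 1
    mids = (x[:m] + x[k - 1:]) / 2.0
    j = np.searchsorted(mids, grid.astype(float))
    j0 = np.clip(j - 1, 0, m - 1)
    j1 = np.clip(j, 0, m - 1)
    cost0 = np.maximum(np.abs(grid - x[j0]), np.abs(x[j0 + k - 1] - grid))
    cost1 = np.maximum(np.abs(grid - x[j1]), np.abs(x[j1 + k - 1] - grid))
    starts = np.where(cost0 <= cost1, j0, j1)

    idx = starts[:, None] + np.arange(k)[None, :]
    px = x[idx]
    pv = val[idx]
    g = grid.astype(float)[:, None]
    d = np.abs(px - g)
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (d / dmax) ** 3) ** 3
    xc = px - g  # centre so the intercept is the fitted value at the grid point
    sw = w.sum(axis=1)
    swx = (w * xc).sum(axis=1)
    swy = (w * pv).sum(axis=1)
    swxx = (w * xc * xc).sum(axis=1)
    swxy = (w * xc * pv).sum(axis=1)
    denom = sw * swxx - swx * swx
    safe = denom > np.finfo(float).tiny * 1e6
    slope = np.where(safe, (sw * swxy - swx * swy) / np.where(safe, denom, 1.0), 0.0)
    return (swy - slope * swx) / sw


@dataclass
class ChromosomeProfile:
    grid: np.ndarray          # bp, every GRID_STEP_BP
    signal: np.ndarray        # smoothed log2 ratio
    mask: np.ndarray          # True where excluded (chromosome ends)
    trep: np.ndarray | None = None

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask


@dataclass
class TimingProfile:
    """Smoothed per-chromosome profiles on a fixed grid plus derived trep."""

    chromosomes: dict[str, ChromosomeProfile]
    lengths: dict[str, int]
    step: int = GRID_STEP_BP
    end_exclusion: int = END_EXCLUSION_BP

    def unmasked_values(self, which: str = "signal") -> np.ndarray:
        parts = []
        for cp in self.chromosomes.values():
            arr = cp.signal if which == "signal" else cp.trep
            if arr is None:
                raise ValueError(f"profile has no {which!r} values yet")
            parts.append(arr[cp.unmasked])
        return np.concatenate(parts)

    def nearest_index(self, chrom: str, position: int) -> int:
        """Nearest grid index to a position; exact midpoints round down."""
        cp = self.chromosomes[chrom]
        g0 = int(cp.grid[0])
        r = (position - g0) / self.step
        idx = int(np.floor(r))
        if r - idx > 0.5:
            idx += 1
        return int(np.clip(idx, 0, cp.grid.size - 1))

    def value_at(self, chrom: str, position: int, which: str = "signal") -> float:
        cp = self.chromosomes[chrom]
        arr = cp.signal if which == "signal" else cp.trep
        if arr is None:
            raise ValueError(f"profile has no {which!r} values yet")
        return float(arr[self.nearest_index(chrom, position)])

    def is_masked(self, chrom: str, position: int) -> bool:
        length = self.lengths[chrom]
        return position < self.end_exclusion or position >= length - self.end_exclusion

    def write_bedgraph(self, path, which: str = "signal") -> None:
        with open(path, "w") as fh:
            for chrom, cp in self.chromosomes.items():
                arr = cp.signal if which == "signal" else cp.trep
                if arr is None:
                    raise ValueError(f"profile has no {which!r} values yet")
                for g, v in zip(cp.grid, arr):
                    fh.write(f"{chrom}\t{g}\t{g + self.step}\t{v:.6f}\n")


def smooth_profile(track: ProbeTable, lengths: dict[str, int],
                   span: float = LOESS_SPAN, step: int = GRID_STEP_BP,
                   end_exclusion: int = END_EXCLUSION_BP) -> TimingProfile:
    """Smooth a probe track per chromosome onto a ``step`` bp grid.

    ``span`` is the fraction of the chromosome's probes entering each
    local fit (at least 4).  Chromosomes are smoothed independently;
    the end-exclusion mask flags grid points within ``end_exclusion``
    bp of either chromosome end.
    """
    profiles: dict[str, ChromosomeProfile] = {}
    for chrom in track.chromosomes:
        length = int(lengths[chrom])
        if length < 2 * step:
            raise ValueError(f"chromosome {chrom} shorter than two grid steps")
        pos = track.positions(chrom)
        k = max(int(np.ceil(span * pos.size)), 4)
        if pos.size < 4:
            raise ValueError(f"chromosome {chrom}: need at least 4 probes to smooth")
        grid = np.arange(0, length, step, dtype=np.int64)
        signal = _loess_chromosome(pos, track.values(chrom), grid, k)
        mask = (grid < end_exclusion) | (grid >= length - end_exclusion)
        profiles[chrom] = ChromosomeProfile(grid=grid, signal=signal, mask=mask)
    return TimingProfile(profiles, {c: int(lengths[c]) for c in track.chromosomes},
                         step=step, end_exclusion=end_exclusion)


def signal_to_trep(profile: TimingProfile) -> TimingProfile:
    """Convert the smoothed log2 ratio to relative replication time.

    The smoothed signal is mapped back to the linear copy scale
    (``2**signal``), in which pooled enrichment is affine in replication
    time, then min-max rescaled over the unmasked genome:
    the most enriched (earliest) locus gets trep 0, the least enriched
    (latest) gets 1.  Masked grid points receive extrapolated values.
    """
    ratios = {c: np.exp2(cp.signal) for c, cp in profile.chromosomes.items()}
    unmasked = np.concatenate([
        ratios[c][cp.unmasked] for c, cp in profile.chromosomes.items()
    ])
    r_max, r_min = float(unmasked.max()), float(unmasked.min())
    if r_max == r_min:
        raise ValueError("flat genome signal: cannot rescale to replication time")
    for c, cp in profile.chromosomes.items():
        cp.trep = (r_max - ratios[c]) / (r_max - r_min)
    return profile


@dataclass
class OriginTiming:
    """Per-site relative replication time in one or two conditions."""

    site: BindingSite
    trep: dict[str, float] = field(default_factory=dict)
    excluded: bool = False


def site_timing(profile: TimingProfile, sites: list[BindingSite],
                condition: str, into: list[OriginTiming] | None = None) -> list[OriginTiming]:
    """Assign each site the trep of the grid point nearest its anchor.

    Anchors within the end-exclusion zone are flagged excluded and carry
    no trep.  Pass ``into`` to accumulate a second condition onto an
    existing assignment (site identity by list order).
    """
    if into is None:
        into = [OriginTiming(site=s) for s in sites]
    for ot, site in zip(into, sites):
        if profile.is_masked(site.chromosome, site.anchor):
            ot.excluded = True
            continue
        ot.trep[condition] = profile.value_at(site.chromosome, site.anchor, "trep")
    return into


def call_hu_replicated(hu_profile: TimingProfile, sites: list[BindingSite],
                       frac: float = 0.5) -> dict[tuple[str, int, int], bool]:
    """Half-max rule for HU-replicated origins.

    A site counts replicated when its smoothed HU value (nearest grid
    point to the anchor) is strictly greater than ``frac`` times the
    maximum smoothed value over the unmasked genome.  Sites with masked
    anchors are not called (absent from the result).
    """
    genome_max = float(hu_profile.unmasked_values("signal").max())
    out: dict[tuple[str, int, int], bool] = {}
    for site in sites:
        if hu_profile.is_masked(site.chromosome, site.anchor):
            continue
        v = hu_profile.value_at(site.chromosome, site.anchor, "signal")
        out[site.key] = v > frac * genome_max
    return out


def compare_conditions(calls_by_condition: dict[str, set]) -> dict[str, int]:
    """Venn counts of replicated-site identities across conditions.

    Returns a mapping from membership pattern (condition names joined
    with ``&``, e.g. ``"meiS&mitS"``) to the count of sites replicated in
    exactly those conditions, plus ``<name>_total`` entries.
    """
    names = list(calls_by_condition)
    universe = set().union(*calls_by_condition.values()) if names else set()
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        from itertools import combinations

        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= calls_by_condition[n]
            for n in names:
                if n not in combo:
                    inside -= calls_by_condition[n]
            counts["&".join(combo)] = len(inside)
    for n in names:
        counts[f"{n}_total"] = len(calls_by_condition[n])
    return counts


@dataclass
class ScalingModel:
    """Quadratic map from mitS trep (x) to meiS trep (y).

    ``y = beta0 + beta1*x + beta2*x**2`` fitted by ordinary least
    squares, with two reference lines: linear scaling ``y = x`` (timing
    order preserved, stretched with S-phase length) and same absolute
    kinetics ``y = x / duration_ratio`` (each origin fires at the same
    minute, meiS being ``duration_ratio`` times longer).
    """

    beta: tuple[float, float, float]
    duration_ratio: float
    n_sites: int
    fraction_later: float
    fraction_before_mean: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        b0, b1, b2 = self.beta
        return b0 + b1 * x + b2 * x * x

    def linear_scaling_line(self, x) -> np.ndarray:
        return np.asarray(x, float)

    def same_kinetics_line(self, x) -> np.ndarray:
        return np.asarray(x, float) / self.duration_ratio


def fit_scaling_model(x, y, duration_ratio: float = 2.0,
                      genome_mean: dict[str, float] | None = None) -> ScalingModel:
    """Fit the second-order polynomial relating timing in two conditions.

    ``x`` and ``y`` are trep values of shared, unmasked sites in the
    reference (mitS) and test (meiS) condition.  ``fraction_later`` is
    the share of sites strictly above the ``y = x`` line;
    ``fraction_before_mean`` is, per condition, the share of sites with
    trep below the genome-mean trep when ``genome_mean`` provides
    ``{"x": ..., "y": ...}``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 sites to fit a quadratic")
    if np.ptp(x) == 0:
        raise ValueError("all x equal: rank-deficient design")
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    frac_before = {}
    if genome_mean is not None:
        frac_before = {
            "x": float(np.mean(x < genome_mean["x"])),
            "y": float(np.mean(y < genome_mean["y"])),
        }
    return ScalingModel(
        beta=tuple(float(b) for b in beta),
        duration_ratio=duration_ratio,
        n_sites=int(x.size),
        fraction_later=float(np.mean(y > x)),
        fraction_before_mean=frac_before,
        residual_sd=float(resid.std(ddof=3)) if x.size > 3 else 0.0,
    )


@dataclass
class TimingDistribution:
    bin_edges: np.ndarray
    genome_density: np.ndarray
    origin_density: np.ndarray
    genome_mean: float
    origin_mean: float


def timing_distribution(profile: TimingProfile, sites: list[BindingSite],
                        n_bins: int = 50) -> TimingDistribution:
    """Densities of trep over the unmasked genome grid and over site anchors."""
    genome = profile.unmasked_values("trep")
    origin_vals = []
    for s in sites:
        if not profile.is_masked(s.chromosome, s.anchor):
            origin_vals.append(profile.value_at(s.chromosome, s.anchor, "trep"))
    origin = np.asarray(origin_vals)
    if origin.size == 0:
        raise ValueError("no unmasked sites for a timing distribution")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    gd, _ = np.histogram(np.clip(genome, 0, 1), bins=edges, density=True)
    od, _ = np.histogram(np.clip(origin, 0, 1), bins=edges, density=True)
    return TimingDistribution(edges, gd, od, float(genome.mean()), float(origin.mean()))
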