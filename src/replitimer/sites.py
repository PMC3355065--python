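"""Binding-site calling from replicated ChIP tracks.

Mcm2-7 binding sites mark licensed replication origins; they are called
as probes significantly enriched (upper-tail P below a threshold) in all
replicates, merged when within 500 bp, optionally assigned to known
origins and rescued from the other cell cycle's calls.  Meiotic axis
association sites are the triple overlap of Rec8, Hop1 and Red1 binding
called the same way at a looser threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_io import FeatureSet, ProbeTable, ReplicateSet

__all__ = [
    "BindingSite",
    "AxisSite",
    "feature_pvalues",
    "call_binding_sites",
    "assign_known_origins",
    "rescue_sites",
    "classify_differential",
    "inter_site_distances",
    "call_axis_sites",
]


@dataclass
class BindingSite:
    """A merged run of significantly enriched probes."""

    chromosome: str
    start: int
    end: int
    anchor: int                      # ACS when a known origin provides one, else midpoint
    pvalues: tuple[float, ...] = ()  # per-replicate minimum p over member probes
    origin_id: str | None = None
    provenance: str = "called"       # called | rescued
    cycle_class: str | None = None   # shared | meiosis_specific | mitosis_specific
    n_probes: int = 0

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


@dataclass
class AxisSite:
    """Three-way overlap of Rec8/Hop1/Red1 binding intervals."""

    chromosome: str
    position: int  # midpoint of the three-way intersection
    intersection: tuple[int, int]
    components: dict[str, tuple[int, int]] = field(default_factory=dict)


def feature_pvalues(track: ProbeTable) -> dict[str, np.ndarray]:
    """Per-probe upper-tail P-values from a robust z-score.

    The z-score uses the median and the Gaussian-consistent MAD
    (``1.4826 * MAD``) of the whole track, so the background sets the
    null; P is the standard-normal upper tail.
    """
    all_vals = track.all_values()
    if all_vals.size < 100:
        raise ValueError("feature_pvalues needs at least 100 probes")
    med = float(np.median(all_vals))
    mad = float(np.median(np.abs(all_vals - med)))
    if mad == 0:
        raise ValueError("MAD is 0: degenerate track, no background spread")
    scale = 1.4826 * mad
    return {c: stats.norm.sf((track.values(c) - med) / scale) for c in track.chromosomes}


def _merge_runs(positions: np.ndarray, merge_bp: int) -> list[tuple[int, int]]:
    """Index runs of sorted positions whose successive gaps are <= merge_bp."""
    if positions.size == 0:
        return []
    breaks = np.nonzero(np.diff(positions) > merge_bp)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [positions.size - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def call_binding_sites(reps: ReplicateSet, alpha: float = 0.05,
                       merge_bp: int = 500, min_run: int = 1) -> list[BindingSite]:
    """Call binding sites from replicate tracks.

    A probe seeds a site when its P-value is below ``alpha`` in every
    replicate; qualifying probes within ``merge_bp`` of each other are
    merged transitively into one site (``min_run`` sets the minimum
    number of qualifying probes a merged site must contain).  The anchor
    is the interval midpoint until a known origin reassigns it.
    """
    if reps.n_replicates < 2:
        raise ValueError("site calling requires at least 2 replicates")
    pvals = [feature_pvalues(rep) for rep in reps.replicates]
    sites: list[BindingSite] = []
    for chrom in reps.chromosomes:
        pos = reps.positions(chrom)
        qual = np.all([pv[chrom] < alpha for pv in pvals], axis=0)
        qpos = pos[qual]
        qp = [pv[chrom][qual] for pv in pvals]
        for i0, i1 in _merge_runs(qpos, merge_bp):
            if i1 - i0 + 1 < min_run:
                continue
            start = int(qpos[i0])
            end = int(qpos[i1]) + 1
            sites.append(BindingSite(
                chromosome=chrom,
                start=start,
                end=end,
                anchor=(start + end) // 2,
                pvalues=tuple(float(p[i0:i1 + 1].min()) for p in qp),
                n_probes=int(i1 - i0 + 1),
            ))
    return sites


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_known_origins(sites: list[BindingSite],
                         known_origins: FeatureSet) -> list[BindingSite]:
    """Assign sites to known origins they overlap (>= 1 bp, half-open).

    Ties go to the largest overlap, then the leftmost origin.  When the
    origin record carries an ``anchor`` column (the ARS consensus
    sequence position), the site anchor is replaced by it.
    """
    df = known_origins.df
    has_anchor = "anchor" in df.columns
    for site in sites:
        cand = df[df["chrom"] == site.chromosome]
        best = None
        for row in cand.itertuples(index=False):
            ov = _overlap(site.start, site.end, int(row.start), int(row.end))
            if ov <= 0:
                continue
            rank = (-ov, int(row.start))
            if best is None or rank < best[0]:
                best = (rank, row)
        if best is not None:
            row = best[1]
            site.origin_id = str(getattr(row, "name", f"{row.chrom}:{row.start}"))
            if has_anchor and not np.isnan(float(getattr(row, "anchor"))):
                site.anchor = int(getattr(row, "anchor"))
    return sites


def rescue_sites(sites_this: list[BindingSite], sites_other: list[BindingSite],
                 known_origins: FeatureSet, reps_this: ReplicateSet,
                 alpha: float = 0.05, min_reps: int = 2) -> list[BindingSite]:
    """Rescue known origins called in the other cell cycle but missed here.

    A rescued site is added when (a) a known origin overlaps a called
    site in the other cycle, (b) no site here overlaps that origin, and
    (c) this cycle still shows a clear peak: some probe inside the origin
    interval is significant (p < alpha) in at least ``min_reps``
    replicates.  Rescued sites take the origin's extent and anchor and
    are flagged ``provenance='rescued'``.
    """
    pvals = [feature_pvalues(rep) for rep in reps_this.replicates]
    out = list(sites_this)
    df = known_origins.df
    has_anchor = "anchor" in df.columns
    for row in df.itertuples(index=False):
        chrom, o_start, o_end = str(row.chrom), int(row.start), int(row.end)
        hit_other = any(
            s.chromosome == chrom and _overlap(s.start, s.end, o_start, o_end) > 0
            for s in sites_other
        )
        if not hit_other:
            continue
        hit_here = any(
            s.chromosome == chrom and _overlap(s.start, s.end, o_start, o_end) > 0
            for s in sites_this
        )
        if hit_here:
            continue
        if chrom not in reps_this.chromosomes:
            continue
        pos = reps_this.positions(chrom)
        inside = (pos >= o_start) & (pos < o_end)
        if not inside.any():
            continue
        sig_count = np.sum([pv[chrom][inside] < alpha for pv in pvals], axis=0)
        if sig_count.max() < min_reps:
            continue
        anchor = (o_start + o_end) // 2
        if has_anchor and not np.isnan(float(getattr(row, "anchor"))):
            anchor = int(getattr(row, "anchor"))
        out.append(BindingSite(
            chromosome=chrom, start=o_start, end=o_end, anchor=anchor,
            pvalues=tuple(float(pv[chrom][inside].min()) for pv in pvals),
            origin_id=str(getattr(row, "name", f"{chrom}:{o_start}")),
            provenance="rescued",
            n_probes=int(inside.sum()),
        ))
    out.sort(key=lambda s: (s.chromosome, s.start))
    return out


def classify_differential(mei_sites: list[BindingSite], mit_sites: list[BindingSite],
                          overlap_bp: int = 500) -> None:
    """Label each site shared or cycle-specific (in place).

    Sites from the two cycles are matched when their intervals overlap or
    come within ``overlap_bp`` (edge-to-edge) of each other.
    """
    def gap(a: BindingSite, b: BindingSite) -> int | None:
        if a.chromosome != b.chromosome:
            return None
        if _overlap(a.start, a.end, b.start, b.end) > 0:
            return 0
        return max(a.start, b.start) - min(a.end, b.end)

    for a in mei_sites:
        near = any((g := gap(a, b)) is not None and g <= overlap_bp for b in mit_sites)
        a.cycle_class = "shared" if near else "meiosis_specific"
    for b in mit_sites:
        near = any((g := gap(b, a)) is not None and g <= overlap_bp for a in mei_sites)
        b.cycle_class = "shared" if near else "mitosis_specific"


@dataclass
class DistanceSummary:
    per_chromosome: dict[str, np.ndarray]
    mean: float
    max: float

    @property
    def all_gaps(self) -> np.ndarray:
        gaps = [g for g in self.per_chromosome.values() if g.size]
        return np.concatenate(gaps) if gaps else np.empty(0)


def inter_site_distances(sites: list[BindingSite]) -> DistanceSummary:
    """Anchor-to-anchor gaps between consecutive sites per chromosome."""
    per: dict[str, np.ndarray] = {}
    for s in sites:
        per.setdefault(s.chromosome, [])
    for chrom in per:
        anchors = np.sort([s.anchor for s in sites if s.chromosome == chrom])
        per[chrom] = np.diff(anchors)
    gaps = [g for g in per.values() if g.size]
    if gaps:
        flat = np.concatenate(gaps)
        return DistanceSummary(per, float(flat.mean()), float(flat.max()))
    return DistanceSummary(per, float("nan"), float("nan"))


def call_axis_sites(rec8: ReplicateSet, hop1: ReplicateSet, red1: ReplicateSet,
                    alpha: float = 0.15, merge_bp: int = 500,
                    min_run: int = 2) -> list[AxisSite]:
    """Axis association sites: triple overlap of Rec8/Hop1/Red1 intervals.

    Per-protein intervals are called like binding sites but at the looser
    ``alpha`` and requiring at least ``min_run`` qualifying probes
    ("more than one adjacent feature").  An axis site is emitted where
    one interval from each protein mutually intersects; its position is
    the midpoint of the three-way intersection.
    """
    tracks = {"rec8": rec8, "hop1": hop1, "red1": red1}
    for name, reps in tracks.items():
        if reps is None:
            raise ValueError(f"missing axis track: {name}")
    calls = {
        name: call_binding_sites(reps, alpha=alpha, merge_bp=merge_bp, min_run=min_run)
        for name, reps in tracks.items()
    }
    out: list[AxisSite] = []
    for a in calls["rec8"]:
        for b in calls["hop1"]:
            if b.chromosome != a.chromosome:
                continue
            ab_start, ab_end = max(a.start, b.start), min(a.end, b.end)
            if ab_start >= ab_end:
                continue
            for c in calls["red1"]:
                if c.chromosome != a.chromosome:
                    continue
                start, end = max(ab_start, c.start), min(ab_end, c.end)
                if start >= end:
                    continue
                out.append(AxisSite(
                    chromosome=a.chromosome,
                    position=(start + end) // 2,
                    intersection=(start, end),
                    components={
                        "rec8": (a.start, a.end),
                        "hop1": (b.start, b.end),
                        "red1": (c.start, c.end),
                    },
                ))
    out.sort(key=lambda s: (s.chromosome, s.position))
    return out


def sites_to_features(sites: list[BindingSite]) -> FeatureSet:
    """BindingSites as a FeatureSet (extra columns preserved)."""
    import pandas as pd

    return FeatureSet(pd.DataFrame({
        "chrom": [s.chromosome for s in sites],
        "start": [s.start for s in sites],
        "end": [s.end for s in sites],
        "name": [s.origin_id or f"{s.chromosome}:{s.start}" for s in sites],
        "anchor": [s.anchor for s in sites],
        "provenance": [s.provenance for s in sites],
        "cycle_class": [s.cycle_class or "" for s in sites],
    }))
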