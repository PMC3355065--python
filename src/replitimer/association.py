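"""Associations between replication timing and chromosomal features.

Covers centromere distance, origin-proximal gene expression, hotspot and
axis-site timing, plus the small statistical toolkit used throughout
(Welch's t-test, 2x2 chi-squared, Pearson correlation of profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_io import FeatureSet
from .sites import BindingSite
from .timing import TimingProfile

__all__ = [
    "AssociationResult",
    "distance_to_centromere",
    "timing_by_distance",
    "normalize_expression",
    "origin_proximal_expression",
    "feature_timing",
    "chi_squared_2x2",
    "welch_t_test",
    "profile_correlation",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class AssociationResult:
    """Grouped summary plus a test statistic."""

    groups: dict[str, dict[str, float]]  # label -> {n, mean, sd}
    test: str = ""
    statistic: float = float("nan")
    pvalue: float = float("nan")
    n_excluded: int = 0
    extra: dict = field(default_factory=dict)


def _group_summary(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, float)
    return {
        "n": int(values.size),
        "mean": float(values.mean()) if values.size else float("nan"),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
    }


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test (Satterthwaite degrees of freedom).

    Degenerate inputs with zero variance in both groups but different
    means report the p-value at the numerical floor instead of 0.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t-test needs at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), _P_FLOOR
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(max(p, _P_FLOOR))


def chi_squared_2x2(a: int, b: int, c: int, d: int,
                    yates: bool = False) -> tuple[float, float]:
    """Chi-squared test of a 2x2 table [[a, b], [c, d]].

    Uncorrected: ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; the Yates
    variant replaces ``|ad - bc|`` by ``|ad - bc| - n/2`` (floored at 0).
    P from the chi-squared distribution with 1 df.
    """
    a, b, c, d = (float(v) for v in (a, b, c, d))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("2x2 table with a zero margin")
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    stat = n * det * det / margins
    return float(stat), float(stats.chi2.sf(stat, df=1))


def profile_correlation(profile_a: TimingProfile, profile_b: TimingProfile,
                        which: str = "signal") -> float:
    """Pearson correlation over the shared unmasked grid of two profiles."""
    vals_a, vals_b = [], []
    for chrom, cp_a in profile_a.chromosomes.items():
        if chrom not in profile_b.chromosomes:
            continue
        cp_b = profile_b.chromosomes[chrom]
        n = min(cp_a.grid.size, cp_b.grid.size)
        if not np.array_equal(cp_a.grid[:n], cp_b.grid[:n]):
            raise ValueError(f"profiles on different grids for {chrom}")
        keep = cp_a.unmasked[:n] & cp_b.unmasked[:n]
        arr_a = cp_a.signal if which == "signal" else cp_a.trep
        arr_b = cp_b.signal if which == "signal" else cp_b.trep
        vals_a.append(arr_a[:n][keep])
        vals_b.append(arr_b[:n][keep])
    x = np.concatenate(vals_a)
    y = np.concatenate(vals_b)
    r, _ = stats.pearsonr(x, y)
    return float(r)


def distance_to_centromere(sites: list[BindingSite],
                           centromeres: FeatureSet | dict[str, int]) -> np.ndarray:
    """Distance (bp) from each site anchor to its chromosome's centromere.

    A centromere interval is reduced to its midpoint.  A chromosome with
    more than one centromere record is an error.
    """
    if isinstance(centromeres, FeatureSet):
        cen: dict[str, int] = {}
        for row in centromeres.df.itertuples(index=False):
            if row.chrom in cen:
                raise ValueError(f"multiple centromeres for chromosome {row.chrom}")
            cen[row.chrom] = (int(row.start) + int(row.end)) // 2
    else:
        cen = dict(centromeres)
    out = []
    for s in sites:
        if s.chromosome not in cen:
            raise ValueError(f"no centromere for chromosome {s.chromosome}")
        out.append(abs(s.anchor - cen[s.chromosome]))
    return np.asarray(out, dtype=np.int64)


def timing_by_distance(trep: np.ndarray, distances: np.ndarray,
                       bin_edges_kb=(0, 50, 100, np.inf),
                       test_pair: tuple[int, int] = (0, -1)) -> AssociationResult:
    """Bin site timing by centromere distance; Welch t-test between bins.

    ``bin_edges_kb`` are half-open distance bins in kb; ``test_pair``
    names the two bin indices compared (default first vs last).
    """
    trep = np.asarray(trep, float)
    distances = np.asarray(distances, float) / 1000.0
    edges = np.asarray(bin_edges_kb, float)
    labels = [
        f"{edges[i]:g}-{edges[i + 1]:g}kb" if np.isfinite(edges[i + 1]) else f">{edges[i]:g}kb"
        for i in range(edges.size - 1)
    ]
    groups = {}
    binned = []
    for i, lab in enumerate(labels):
        sel = (distances >= edges[i]) & (distances < edges[i + 1])
        binned.append(trep[sel])
        groups[lab] = _group_summary(trep[sel])
    i, j = test_pair
    a, b = binned[i], binned[j]
    if a.size >= 2 and b.size >= 2:
        t, p = welch_t_test(a, b)
        test = f"welch_t({labels[i]} vs {labels[j]})"
    else:
        t, p, test = float("nan"), float("nan"), "none (empty bin)"
    return AssociationResult(groups=groups, test=test, statistic=t, pvalue=p)


def normalize_expression(set_a, set_b):
    """Join two expression tables on shared gene ids and z-score each.

    Each input is a DataFrame with columns ``gene`` and ``value``.
    Returns a DataFrame ``gene, value_a, value_b`` where each column has
    mean 0 and sd 1 over the shared genes.
    """
    import pandas as pd

    a = set_a[["gene", "value"]].rename(columns={"value": "value_a"})
    b = set_b[["gene", "value"]].rename(columns={"value": "value_b"})
    joined = pd.merge(a, b, on="gene", how="inner")
    if joined.empty:
        raise ValueError("no shared genes between expression sets")
    if len(joined) < 2:
        raise ValueError("only one shared gene: standard deviation undefined")
    for col in ("value_a", "value_b"):
        sd = joined[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate expression column {col}: sd = 0")
        joined[col] = (joined[col] - joined[col].mean()) / sd
    return joined


def _site_gene_distance(site: BindingSite, g_start: int, g_end: int) -> int:
    """Minimum edge distance between a gene interval and a site interval."""
    if g_start < site.end and site.start < g_end:
        return 0
    return max(site.start, g_start) - min(site.end, g_end)


def origin_proximal_expression(
    sites_by_group: dict[str, list[BindingSite]],
    genes: FeatureSet,
    expression,
    value_column: str,
    window: int = 500,
) -> AssociationResult:
    """Mean expression of genes within ``window`` bp of each site, by group.

    A gene qualifies for a site when the edge-to-edge distance between
    the gene interval and the site interval is at most ``window``
    (overlap counts as 0).  Each site contributes the mean expression of
    its proximal genes; the two groups are compared by Welch's t-test.
    """
    expr = expression.set_index("gene")[value_column]
    gene_rows = genes.df
    per_group: dict[str, np.ndarray] = {}
    n_without = 0
    for label, sites in sites_by_group.items():
        means = []
        for site in sites:
            sub = gene_rows[gene_rows["chrom"] == site.chromosome]
            vals = [
                expr[row.name]
                for row in sub.itertuples(index=False)
                if _site_gene_distance(site, int(row.start), int(row.end)) <= window
                and row.name in expr.index
            ]
            if vals:
                means.append(float(np.mean(vals)))
            else:
                n_without += 1
        per_group[label] = np.asarray(means)
    groups = {lab: _group_summary(v) for lab, v in per_group.items()}
    labels = list(per_group)
    if len(labels) == 2 and all(per_group[l].size >= 2 for l in labels):
        t, p = welch_t_test(per_group[labels[0]], per_group[labels[1]])
        test = f"welch_t({labels[0]} vs {labels[1]})"
    else:
        t, p, test = float("nan"), float("nan"), "none"
    return AssociationResult(groups=groups, test=test, statistic=t, pvalue=p,
                             n_excluded=n_without)


def feature_timing(features: FeatureSet, profile: TimingProfile,
                   rank_quintiles: bool = False) -> AssociationResult:
    """Replication timing of features vs the genome.

    Each feature is assigned the trep of the grid point nearest its
    midpoint (end-mask applied); the feature distribution is compared to
    the unmasked genome grid by Welch's t-test.  With ``rank_quintiles``
    the features are split into five groups by their ``score`` column
    (ties broken by genomic order) and per-quintile summaries are added.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    mids = features.midpoints()
    chroms = features.df["chrom"].to_numpy()
    vals, kept_idx = [], []
    n_excluded = 0
    for i, (chrom, mid) in enumerate(zip(chroms, mids)):
        if chrom not in profile.chromosomes or profile.is_masked(chrom, int(mid)):
            n_excluded += 1
            continue
        vals.append(profile.value_at(chrom, int(mid), "trep"))
        kept_idx.append(i)
    feat = np.asarray(vals)
    if feat.size < 2:
        raise ValueError("fewer than 2 unmasked features")
    genome = profile.unmasked_values("trep")
    t, p = welch_t_test(feat, genome)
    groups = {"features": _group_summary(feat), "genome": _group_summary(genome)}
    extra = {}
    if rank_quintiles:
        if "score" not in features.df.columns:
            raise ValueError("rank_quintiles requires a score column")
        scores = features.df["score"].to_numpy(float)[kept_idx]
        order = np.lexsort((np.asarray(kept_idx), scores))  # ties by genomic order
        splits = np.array_split(order, 5)
        extra["quintiles"] = [
            _group_summary(feat[idx]) for idx in splits
        ]
    return AssociationResult(groups=groups, test="welch_t(features vs genome)",
                             statistic=t, pvalue=p, n_excluded=n_excluded,
                             extra=extra)
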