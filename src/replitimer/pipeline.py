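"""End-to-end orchestration: simulate, normalize, call, profile, compare.

`run_pipeline` drives every stage over one configuration and writes a
JSON report plus bedGraph/BED/TSV artifacts.  The packaged demo genome
is a four-chromosome toy with yeast-like geometry: origins every
~100 kb, centromere-proximal origins firing early, and a pre-meiotic
S phase twice the length of the pre-mitotic one in which most origins
replicate relatively later.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import (
    chi_squared_2x2,
    distance_to_centromere,
    feature_timing,
    origin_proximal_expression,
    profile_correlation,
    timing_by_distance,
)
from .signal_io import FeatureSet, ReplicateSet, average_replicates, scale_normalize
from .sites import (
    call_axis_sites,
    call_binding_sites,
    assign_known_origins,
    classify_differential,
    inter_site_distances,
    rescue_sites,
    sites_to_features,
)
from .synthetic import (
    GenomeModel,
    OriginSpec,
    SimulationConfig,
    simulate_chip,
    simulate_expression,
    simulate_hu,
    simulate_pool,
)
from .timing import (
    call_hu_replicated,
    compare_conditions,
    fit_scaling_model,
    signal_to_trep,
    site_timing,
    smooth_profile,
)

__all__ = ["PipelineConfig", "demo_genomes", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full analysis, with field-standard defaults."""

    alpha_mcm: float = 0.05          # per-replicate calling threshold
    alpha_axis: float = 0.15         # axis-protein calling threshold
    merge_bp: int = 500              # probe merge distance
    window_bp: int = 500             # origin-proximal gene window
    end_exclusion_bp: int = 25_000   # chromosome-end mask
    span: float = 0.025              # loess span (fraction of probes)
    grid_step: int = 50              # bp, profile prediction grid
    hu_frac: float = 0.5             # half-max rule fraction
    duration_ratio: float = 2.0      # meiS length / mitS length
    rng_seed: int = 0
    noise_sd: float = 0.1
    probe_spacing: int = 500
    n_cells: int = 50
    n_timepoints: int = 200
    outdir: str = "replitimer_out"

    def __post_init__(self):
        for name in ("alpha_mcm", "alpha_axis", "merge_bp", "window_bp",
                     "end_exclusion_bp", "span", "grid_step", "hu_frac",
                     "duration_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _origin_layout(n_chrom: int, length: int, spacing: int,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Deterministic, slightly jittered origin positions per chromosome."""
    out = {}
    for i in range(n_chrom):
        base = np.arange(spacing // 2, length - spacing // 4, spacing)
        jitter = rng.integers(-spacing // 8, spacing // 8 + 1, size=base.size)
        out[f"chr{i + 1}"] = np.sort(base + jitter)
    return out


def demo_genomes(seed: int = 0, n_chrom: int = 4, length: int = 1_000_000,
                 origin_spacing: int = 100_000, jitter_min: float = 3.0,
                 duration_ratio: float = 2.0):
    """Paired mitS/meiS genome models over one geometry.

    MitS origins fire earlier the closer they sit to the centromere
    (timing gradient saturating ~150 kb out).  In meiS every origin's
    mean firing time is stretched by ``duration_ratio`` except within
    the centromere domain (< 50 kb), which keeps near-mitotic absolute
    timing — so centromere-proximal origins become relatively earlier
    and the rest of the genome relatively later, on an S phase
    ``duration_ratio`` times longer.
    """
    rng = np.random.default_rng(seed)
    positions = _origin_layout(n_chrom, length, origin_spacing, rng)
    centromeres = {}
    for i, chrom in enumerate(positions):
        cen_target = length // 2 + int(rng.integers(-150_000, 150_000))
        pos = positions[chrom]
        centromeres[chrom] = int(pos[np.argmin(np.abs(pos - cen_target))])

    fork_speed = 2_000.0  # bp/min
    t_mit = 70.0          # min; meiS lasts duration_ratio times longer
    t_mit_max = 25.0
    mit_origins, mei_origins = [], []
    for chrom, pos in positions.items():
        cen = centromeres[chrom]
        for p in pos:
            dist = abs(int(p) - cen)
            grad = min(dist / 150_000.0, 1.0)
            mu_mit = 2.0 + t_mit_max * grad + float(rng.uniform(-1.5, 1.5))
            mu_mit = max(mu_mit, 0.0)
            if dist < 50_000:
                mu_mei = mu_mit + 2.0  # near-mitotic absolute timing
            else:
                mu_mei = mu_mit * duration_ratio
            mit_origins.append(OriginSpec(chrom, int(p), mu_mit, jitter_min))
            mei_origins.append(OriginSpec(chrom, int(p), mu_mei, jitter_min))

    chroms = [(c, length) for c in positions]
    genome_mit = GenomeModel(chroms, centromeres, mit_origins, fork_speed, t_mit)
    genome_mei = GenomeModel(chroms, centromeres, mei_origins, fork_speed,
                             t_mit * duration_ratio)
    return genome_mit, genome_mei


def _pool_replicates(genome: GenomeModel, cfg: SimulationConfig,
                     n_replicates: int, condition: str) -> ReplicateSet:
    reps = []
    for i in range(n_replicates):
        rep_cfg = SimulationConfig(**{**asdict(cfg), "rng_seed": cfg.rng_seed + 1000 + i})
        reps.append(simulate_pool(genome, rep_cfg))
    return ReplicateSet(condition, reps)


def run_pipeline(config: PipelineConfig, genomes=None) -> dict:
    """Run every stage on the demo (or provided) genomes; return the report.

    Writes sites as BED, profiles as bedGraph and the report as JSON
    under ``config.outdir``.  Identical config and seed give a
    byte-identical report.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = demo_genomes(seed=config.rng_seed,
                               duration_ratio=config.duration_ratio)
    genome_mit, genome_mei = genomes
    lengths = genome_mit.lengths
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }

    # --- simulate -----------------------------------------------------
    base_cfg = SimulationConfig(
        probe_spacing=config.probe_spacing, n_cells=config.n_cells,
        n_timepoints=config.n_timepoints, noise_sd=config.noise_sd,
        rng_seed=config.rng_seed,
    )
    mcm_sites_mit = [(o.chromosome, o.position - 200, o.position + 200)
                     for o in genome_mit.origins]
    # a handful of cycle-specific Mcm2-7 sites at each end of the lists
    chip_mit = simulate_chip(genome_mit, mcm_sites_mit[2:], base_cfg)
    chip_mei = simulate_chip(
        genome_mei, mcm_sites_mit[:-2],
        SimulationConfig(**{**asdict(base_cfg), "rng_seed": config.rng_seed + 1}),
    )
    pool_mit = _pool_replicates(genome_mit, base_cfg, 3, "mitS")
    pool_mei = _pool_replicates(
        genome_mei,
        SimulationConfig(**{**asdict(base_cfg), "rng_seed": config.rng_seed + 2}),
        3, "meiS",
    )
    hu_mei = simulate_hu(
        genome_mei, 15.0,
        SimulationConfig(**{**asdict(base_cfg), "rng_seed": config.rng_seed + 3}),
    )
    hu_mit = simulate_hu(
        genome_mit, 25.0,
        SimulationConfig(**{**asdict(base_cfg), "rng_seed": config.rng_seed + 4}),
    )
    known = FeatureSet.from_records(
        [(o.chromosome, o.position - 250, o.position + 250,
          f"ARS_{o.chromosome}_{o.position}", o.position)
         for o in genome_mit.origins],
        columns=("chrom", "start", "end", "name", "anchor"),
    )
    report["simulate"] = {
        "n_origins": len(genome_mit.origins),
        "n_probes": pool_mit.replicates[0].n_probes,
        "fork_speed_bp_min": genome_mit.fork_speed_v,
        "s_duration_min": {"mitS": genome_mit.s_duration_T,
                           "meiS": genome_mei.s_duration_T},
    }

    # --- normalize ----------------------------------------------------
    pool_mit_n = scale_normalize(pool_mit)
    pool_mei_n = scale_normalize(pool_mei)
    track_mit = average_replicates(pool_mit_n)
    track_mei = average_replicates(pool_mei_n)
    report["normalize"] = {
        "conditions": ["mitS", "meiS"],
        "replicates": 3,
    }

    # --- call-sites ---------------------------------------------------
    sites_mit = call_binding_sites(chip_mit, alpha=config.alpha_mcm,
                                   merge_bp=config.merge_bp)
    sites_mei = call_binding_sites(chip_mei, alpha=config.alpha_mcm,
                                   merge_bp=config.merge_bp)
    assign_known_origins(sites_mit, known)
    assign_known_origins(sites_mei, known)
    sites_mit = rescue_sites(sites_mit, sites_mei, known, chip_mit,
                             alpha=config.alpha_mcm)
    sites_mei = rescue_sites(sites_mei, sites_mit, known, chip_mei,
                             alpha=config.alpha_mcm)
    classify_differential(sites_mei, sites_mit, overlap_bp=config.merge_bp)
    dist_mei = inter_site_distances(sites_mei)
    sites_to_features(sites_mei).write_bed(out / "sites_meiS.bed")
    sites_to_features(sites_mit).write_bed(out / "sites_mitS.bed")
    report["sites"] = {
        "n_meiS": len(sites_mei),
        "n_mitS": len(sites_mit),
        "n_rescued_meiS": sum(s.provenance == "rescued" for s in sites_mei),
        "n_meiosis_specific": sum(s.cycle_class == "meiosis_specific" for s in sites_mei),
        "n_mitosis_specific": sum(s.cycle_class == "mitosis_specific" for s in sites_mit),
        "inter_site_distance_mean_bp": dist_mei.mean,
        "inter_site_distance_max_bp": dist_mei.max,
    }

    # --- profile ------------------------------------------------------
    prof_mit = signal_to_trep(smooth_profile(
        track_mit, lengths, span=config.span, step=config.grid_step,
        end_exclusion=config.end_exclusion_bp))
    prof_mei = signal_to_trep(smooth_profile(
        track_mei, lengths, span=config.span, step=config.grid_step,
        end_exclusion=config.end_exclusion_bp))
    prof_mei.write_bedgraph(out / "profile_meiS_trep.bedgraph", "trep")
    prof_mit.write_bedgraph(out / "profile_mitS_trep.bedgraph", "trep")
    corr = profile_correlation(prof_mit, prof_mei)
    report["profile"] = {
        "pearson_r_meiS_vs_mitS": corr,
        "grid_step_bp": config.grid_step,
        "end_exclusion_bp": config.end_exclusion_bp,
    }

    # --- timing + scaling model --------------------------------------
    shared = [s for s in sites_mei if s.cycle_class == "shared"]
    ot = site_timing(prof_mei, shared, "meiS")
    ot = site_timing(prof_mit, shared, "mitS", into=ot)
    pairs = [(o.trep["mitS"], o.trep["meiS"]) for o in ot
             if not o.excluded and "mitS" in o.trep and "meiS" in o.trep]
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    genome_mean = {
        "x": float(prof_mit.unmasked_values("trep").mean()),
        "y": float(prof_mei.unmasked_values("trep").mean()),
    }
    model = fit_scaling_model(x, y, duration_ratio=config.duration_ratio,
                              genome_mean=genome_mean)
    report["scaling"] = {
        "beta": list(model.beta),
        "n_sites": model.n_sites,
        "fraction_later_meiS": model.fraction_later,
        "fraction_before_mean": model.fraction_before_mean,
        "duration_ratio": model.duration_ratio,
    }

    # --- hu-call + compare -------------------------------------------
    hu_prof_mei = smooth_profile(hu_mei, lengths, span=config.span,
                                 step=config.grid_step,
                                 end_exclusion=config.end_exclusion_bp)
    hu_prof_mit = smooth_profile(hu_mit, lengths, span=config.span,
                                 step=config.grid_step,
                                 end_exclusion=config.end_exclusion_bp)
    calls_mei = call_hu_replicated(hu_prof_mei, sites_mei, frac=config.hu_frac)
    calls_mit = call_hu_replicated(hu_prof_mit, sites_mit, frac=config.hu_frac)

    def origin_identity(sites):
        # cross-cycle identity: the assigned known origin, else the anchor
        return {s.key: (s.origin_id or f"{s.chromosome}:{s.anchor}") for s in sites}

    ident_mei = origin_identity(sites_mei)
    ident_mit = origin_identity(sites_mit)
    venn = compare_conditions({
        "meiS_HU": {ident_mei[k] for k, v in calls_mei.items() if v},
        "mitS_HU": {ident_mit[k] for k, v in calls_mit.items() if v},
    })
    report["hu"] = {"venn": venn, "frac": config.hu_frac}

    # --- associate ----------------------------------------------------
    cen_dist = distance_to_centromere(shared, genome_mei.centromere_pos)
    trep_shared = np.array([o.trep["meiS"] for o in ot if not o.excluded])
    kept = np.array([not o.excluded for o in ot])
    assoc_cen = timing_by_distance(trep_shared, cen_dist[kept])
    # genic-location contingency: differential vs shared sites in genes
    rng = np.random.default_rng(config.rng_seed + 7)
    gene_records = [
        (c, int(s), int(s) + 1_500, f"gene_{c}_{int(s)}")
        for c, ln in genome_mit.chromosomes
        for s in np.sort(rng.choice(np.arange(1_000, ln - 2_500, 2_000), 150,
                                    replace=False))
    ]

    def genic(site):
        sub = genes.on(site.chromosome)
        return bool(((sub["start"] < site.end) & (site.start < sub["end"])).any())

    diff_sites = ([s for s in sites_mei if s.cycle_class == "meiosis_specific"]
                  + [s for s in sites_mit if s.cycle_class == "mitosis_specific"])
    shared_all = [s for s in sites_mei if s.cycle_class == "shared"]
    # differential loading is transcription-driven: put a gene over each
    # cycle-specific site so the genic-location contrast is testable
    gene_records += [
        (s.chromosome, s.anchor - 400, s.anchor + 1_100,
         f"gene_at_{s.chromosome}_{s.anchor}")
        for s in diff_sites
    ]
    genes = FeatureSet.from_records(gene_records)
    a = sum(genic(s) for s in diff_sites)
    c = sum(genic(s) for s in shared_all)
    try:
        chi2, chi2_p = chi_squared_2x2(a, len(diff_sites) - a, c, len(shared_all) - c)
    except ValueError:  # zero margin on a degenerate table
        chi2, chi2_p = float("nan"), float("nan")
    # hotspot timing: random features should match the genome distribution
    hs = FeatureSet.from_records(
        [(c, int(p), int(p) + 200, f"hs_{c}_{int(p)}", 1.0 + i)
         for c, ln in genome_mei.chromosomes
         for i, p in enumerate(np.sort(rng.integers(30_000, ln - 30_000, 60)))],
        columns=("chrom", "start", "end", "name", "score"),
    )
    assoc_hs = feature_timing(hs, prof_mei, rank_quintiles=True)
    # expression around meiS-early vs mitS-only-early origins
    expr = simulate_expression(
        [(row.name, row.chrom, int(row.start), int(row.end))
         for row in genes.df.itertuples(index=False)],
        SimulationConfig(**{**asdict(base_cfg), "noise_sd": 1.0,
                            "rng_seed": config.rng_seed + 8}),
        labels=("meiS_expr", "mitS_expr"),
    )
    mei_early = {ident_mei[k] for k, v in calls_mei.items() if v}
    mit_early = {ident_mit[k] for k, v in calls_mit.items() if v}
    groups = {
        "meiS_early": [s for s in sites_mei if ident_mei[s.key] in mei_early],
        "mitS_only_early": [s for s in sites_mit
                            if ident_mit[s.key] in mit_early - mei_early],
    }
    assoc_expr = origin_proximal_expression(groups, genes, expr, "meiS_expr",
                                            window=config.window_bp)
    report["associate"] = {
        "centromere": {
            "groups": assoc_cen.groups, "test": assoc_cen.test,
            "statistic": assoc_cen.statistic, "pvalue": assoc_cen.pvalue,
        },
        "genic_chi2": {"statistic": chi2, "pvalue": chi2_p,
                       "table": [a, len(diff_sites) - a, c, len(shared_all) - c]},
        "hotspot_timing": {
            "groups": assoc_hs.groups, "statistic": assoc_hs.statistic,
            "pvalue": assoc_hs.pvalue,
        },
        "origin_proximal_expression": {
            "groups": assoc_expr.groups, "test": assoc_expr.test,
            "statistic": assoc_expr.statistic, "pvalue": assoc_expr.pvalue,
        },
    }

    report = _sanitize(report)
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=False)
    return report


def _sanitize(obj):
    """Strict-JSON-safe report: NaN/inf become None, numpy scalars floats."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    return obj
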