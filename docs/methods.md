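# Methods

## The measurement model

In budding yeast, potential replication origins are marked in G1 by
Mcm2-7 loading; in S phase a subset fires, and forks from fired origins
passively replicate the rest. Population replication timing is measured
by copy number: when DNA samples are collected at uniform intervals
through a synchronous S phase and pooled, a locus that replicates at
time `t` out of an S phase of length `T` is present at two copies in the
fraction `1 - t/T` of samples, so its expected pooled copy number is

    c(x) = 2 - t(x)/T,   c in [1, 2].

Co-hybridizing the pool against a non-replicating G1 sample and taking
log2 ratios (against the genome-mean copy, emulating equal-total-DNA
two-channel hybridization) gives the raw probe signal the pipeline
consumes. Enrichment is therefore *affine in replication time on the
linear copy scale* — this identity drives both the simulator and the
inversion back to relative time.

## The forward simulator (`replitimer.synthetic`)

Per cell, each licensed origin `i` at position `o_i` draws a firing time
from a Gaussian centred on its mean with per-origin jitter, truncated at
zero (the data constrain no particular kinetic law; truncated-Gaussian
jitter is the simplest model that reproduces smooth population timing
curves). Forks move at constant speed `v`, so the single-cell
replication-time field is

    t(x) = min_i [ t_i + |x - o_i| / v ].

An origin reached by an incoming fork strictly before its own firing
time is passively replicated (a tie fires the origin). The pooled
measurement averages indicator copy numbers over cells and over a
deterministic midpoint grid of `M` sample times, which pins the
noise-free pooled copy to `2 - t/T` within `T/(2M)`. Hydroxyurea (HU)
arrest is modelled by letting only origins with realized `t_i` strictly
before the arrest time fire and stalling each fork after
`v * (tau - t_i)` bp. ChIP tracks are plateaus of fixed log2 enrichment
(site extended by a half-width) over Gaussian background; expression
tables are Gaussian around configurable per-gene means. All outputs are
byte-deterministic under the configured seed.

What the simulator does *not* emulate: chromatin or sequence context,
replication re-initiation, dNTP kinetics, dye bias, spatial probe
correlation, or the heavy-tailed noise of real arrays. Tests passing on
these fixtures certify the algebra and the calling rules, not robustness
to every artifact of real microarray data.

## Probe tables and normalization (`replitimer.signal_io`)

Probe positions are feature midpoints; coordinates are 0-based,
half-open, BED semantics at file boundaries. Replicates must share a
probe grid. Scale normalization recentres each replicate to median 0
and rescales it so each replicate's MAD equals the geometric mean of the
replicate MADs — a robust reading of across-replicate scale
normalization for two-channel log ratios (the historical array package
this emulates does not document closed formulas). The step is
idempotent and order-preserving within each replicate; a replicate with
zero MAD is rejected as degenerate.

## Site calling (`replitimer.sites`)

Per-probe significance is an upper-tail normal P-value of the robust
z-score `(x - median) / (1.4826 * MAD)` computed over the whole track:
the enriched fraction of a ChIP track is small, so median/MAD estimate
the background null. The calling threshold (default P < 0.05) applies
*per replicate*, and a probe seeds a site only when significant in every
replicate — the replicate intersection, not a multiplicity correction,
controls false calls, which is why none is applied. Qualifying probes
within 500 bp (edge-to-edge, inclusive) merge transitively into one
site. Sites are assigned to known origins they overlap by at least 1 bp
(largest overlap, then leftmost, wins) and take the origin's ACS point
as anchor when one is provided, else the interval midpoint.

The rescue rule re-admits known origins that were called in the other
cell cycle but missed here, provided the local data still show a clear
peak; "clear" is codified as P < alpha in at least 2 of 3 replicates at
some probe inside the origin interval. Differential classification
marks sites shared when their intervals come within 500 bp across
cycles. Axis association sites are called per protein (Rec8, Hop1,
Red1) like binding sites but at P < 0.15 and requiring runs of at least
2 qualifying probes; an axis site is the midpoint of each mutual
three-way interval intersection.

## Timing profiles (`replitimer.timing`)

Smoothing is tricube-weighted local *linear* regression evaluated every
50 bp, with the window holding the nearest `ceil(span * n)` probes of
the chromosome (span 0.025, at least 4 probes), each chromosome fitted
independently. This is the classical loess estimator; it reproduces
constants exactly and straight lines to rounding, and was cross-checked
against an independent local-regression implementation to ~1e-8 during
development. (The profile literature sometimes quotes a loess span
together with a `spar` value, which belongs to a different smoother;
only the span is meaningful here and `spar` is ignored.) The 25 kb at
each chromosome end are masked from all genome-wide statistics because
a one-sided window cannot anchor predictions beyond the data edge.

Relative replication time inverts the measurement model: the smoothed
log2 ratio is mapped back to the linear copy scale (`2**signal`), where
enrichment is affine in `t`, and min-max rescaled over the unmasked
genome so the most enriched locus gets `trep = 0` and the least enriched
`trep = 1`. Rescaling on the log scale instead would bow the map by up
to ~0.09 at mid-S, so the linear-scale inversion is the package's
definition of trep. Sites take the trep of the grid point nearest their
anchor (exact midpoints round down); anchors inside the end mask are
flagged excluded and carry no timing.

An origin counts replicated in HU when its smoothed value strictly
exceeds half the genome-wide maximum of the unmasked smoothed HU
profile ("greater than half of the maximum"); the rule is invariant to
positive rescaling of the profile. The max is taken on the smoothed
profile, matching how HU profiles are plotted and called.

The meiS/mitS scaling model is an ordinary-least-squares quadratic
`y = b0 + b1 x + b2 x^2` mapping mitS trep to meiS trep over shared,
unmasked sites, reported alongside two reference lines: `y = x` (timing
order preserved, stretched with S-phase length) and `y = x / r` with
duration ratio `r = 2` (every origin fires at the same absolute minute).
`fraction_later` counts sites strictly above `y = x`.

## Associations (`replitimer.association`)

Centromere distance is anchor-to-centromere-midpoint on the same
chromosome; timing is summarized in distance bins (defaults 0–50, 50–100,
>100 kb) and compared by Welch's t-test. Gene proximity is measured
interval-to-interval (overlap counts as zero; a gene qualifies within
500 bp of the site), and each site contributes the mean expression of
its proximal genes. Feature timing uses the feature midpoint, applies
the end mask, and compares features to the unmasked genome grid by
Welch's t-test, with optional score quintiles (ties broken by genomic
order for determinism). The 2x2 chi-squared is provided uncorrected
(`n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`) and with the Yates correction;
all tests are two-sided and no multiple-testing correction is applied
anywhere. Degenerate Welch inputs (both groups constant, means differ)
report the p-value at the numerical floor rather than zero.

## Verification scenarios (`replitimer.validation`)

- **Timing oracle** — four 1 Mb chromosomes, two jitter-free origins
  each, probes every 500 bp, 200 pool timepoints, no noise; `T` is set
  to the latest unmasked analytic replication time so `t(x)/T` spans
  [0, 1] exactly. Pipeline trep agrees with the analytic value to
  ~0.003 everywhere unmasked (tolerance 0.02): residual error is pool
  discretization (~1/400) plus the smoothing bias at fork-collision
  kinks (~0.32 * half-window / (v*T)).
- **Site recovery** — 40 sites of 400 bp at one per 60 kb over four
  chromosomes, enrichment 2.0 over noise 0.5 (SNR 4), three replicates.
- **HU arrest** — 40 origins 120 kb apart; 12 fire at 5 min, the rest at
  30 min, arrest at 20 min, so fired tracks are 60 kb wide and separated
  by more than two track widths; the half-max rule must flag exactly the
  fired 12.
- **Centromere effect** — origins every 100 kb; the one origin per
  chromosome within 50 kb of the centromere fires 20% of S earlier.

Problem sizes (1 Mb-scale chromosomes, 500 bp probes, tens of cells) are
chosen so every scenario runs in seconds while leaving each effect many
standard errors above its detection threshold.

## The demo pipeline (`replitimer.pipeline`)

`demo_genomes` builds paired mitS/meiS models on one geometry: four 1 Mb
chromosomes, ~10 origins each at ~100 kb spacing, fork speed 2 kb/min
(yeast-like), mitS 70 min with a centromere-distance timing gradient
saturating at 150 kb, and firing jitter 3 min. In meiS every origin's
mean firing time stretches by the duration ratio (default 2) *except*
origins within 50 kb of the centromere, which keep near-mitotic absolute
timing (a 2 min entry lag) — encoding the design that centromeres anchor
early replication while the rest of the genome is delayed. The two HU
stages arrest meiS at 15 min and mitS at 25 min, reflecting the stronger
meiotic arrest. `run_pipeline` chains simulate → normalize → call-sites
→ profile → timing/scaling → hu-call/compare → associate, embeds the
package version and a config hash in the report, and is byte-identical
under a fixed config and seed.

## Numerical choices and edge cases

- Merging threshold is inclusive (a 500 bp gap merges); site extents are
  `[first probe, last probe + 1)`.
- Nearest-grid lookups round exact midpoints down.
- Loess windows fall back to pure local means when the weighted design
  is numerically singular (cannot occur with distinct probe positions).
- `simulate_pool` warns, rather than fails, when loci replicate after
  `T`; their pooled copy is clipped at 1 (this is routine inside masked
  chromosome ends).
- Truncated-Gaussian firing times are sampled exactly (no clipping
  atom at 0).

## Known limitations

- trep is a *relative* scale per condition; cross-condition comparisons
  assume both profiles span their S phase, which the min-max anchoring
  cannot itself verify.
- The per-probe significance model assumes a unimodal background; tracks
  whose enriched fraction approaches half the probes would inflate the
  MAD and lose power.
- Fork speed is constant and uniform; no fork stalling outside HU, no
  re-replication, no heterogeneous origin efficiency beyond firing-time
  jitter.
- The half-max HU rule calls passively replicated origins inside a
  neighbouring fork track "replicated", as any copy-number method must.
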