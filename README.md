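# replitimer

Genome-wide DNA replication-timing analysis for tiled-array copy-number
data, built around the comparison of pre-meiotic (meiS) and pre-mitotic
(mitS) S phase in budding yeast — plus a forward simulator of S-phase
replication that makes every stage verifiable against ground truth.

## What it does

When synchronous S-phase DNA samples are pooled and co-hybridized
against a G1 sample, a locus replicating at time `t` of an S phase of
length `T` has expected copy number `c(x) = 2 − t(x)/T`: enrichment is
inversely proportional to replication time. `replitimer` takes
probe-level log2 ratio tracks and

- **calls Mcm2-7 binding sites** (licensed origins) from replicate ChIP
  tracks — robust-z upper-tail P < 0.05 in every replicate, 500 bp
  merging, known-origin assignment and cross-cycle rescue — and
  classifies sites as shared or cycle-specific;
- **builds timing profiles**: loess smoothing (tricube local linear
  regression, span 0.025) predicted every 50 bp per chromosome, with
  25 kb chromosome-end exclusion, inverted to relative replication time
  `trep ∈ [0, 1]` on the linear copy scale;
- **identifies early origins under hydroxyurea (HU)** with the half-max
  rule (site value strictly greater than half the genome maximum) and
  compares conditions as Venn counts;
- **fits the timing scaling model** between conditions: a second-order
  polynomial `y = β₀ + β₁x + β₂x²` of meiS trep against mitS trep, with
  reference lines for linear scaling (`y = x`) and identical absolute
  kinetics (`y = x/r`, S-phase duration ratio `r = 2`);
- **relates timing to chromosomal features**: centromere distance,
  origin-proximal gene expression (500 bp window), DSB-hotspot and
  Rec8/Hop1/Red1 triple-overlap axis-site timing, with Welch t-tests
  and 2×2 chi-squared utilities;
- **simulates all of it**: stochastic origin firing (truncated-Gaussian
  per-cell times), constant-speed fork progression
  `t(x) = minᵢ [tᵢ + |x − oᵢ|/v]`, pooled-S/G1 and HU-arrest copy-number
  measurement, ChIP peak tracks and expression tables, byte-reproducible
  under a seed.

## Worked example

Run the packaged demo — paired meiS/mitS genomes on four 1 Mb
chromosomes with yeast-like origin spacing, in which meiS is twice as
long as mitS and centromere-proximal origins keep near-mitotic absolute
timing:

```python
import replitimer as rt

cfg = rt.PipelineConfig(rng_seed=1, outdir="demo_out")
report = rt.run_pipeline(cfg)
print(report["sites"]["n_meiS"], "meiS sites,",
      report["sites"]["n_mitS"], "mitS sites")
print("profile correlation:", round(report["profile"]["pearson_r_meiS_vs_mitS"], 3))
print("scaling beta:", [round(b, 3) for b in report["scaling"]["beta"]])
print("fraction later in meiS:", report["scaling"]["fraction_later_meiS"])
print("HU venn:", report["hu"]["venn"])
```

prints (seed 1):

```
39 meiS sites, 38 mitS sites
profile correlation: 0.908
scaling beta: [0.002, 1.459, -0.158]
fraction later in meiS: 1.0
HU venn: {'meiS_HU': 0, 'mitS_HU': 8, 'meiS_HU&mitS_HU': 4, 'meiS_HU_total': 4, 'mitS_HU_total': 12}
```

Reading it: ~40 origins are recovered in each cycle and the two
smoothed profiles correlate strongly (r = 0.91), but the fitted scaling
curve lies above the identity line (β₁ ≈ 1.46 at the origin) — shared
origins replicate relatively later in meiS, exactly as the demo genome
encodes. Under HU, only the 4 centromere-proximal early origins
replicate in meiS while 12 replicate in mitS, and the meiS set nests
inside the mitS set. The centromere association in
`report["associate"]` shows near-centromere origins at mean trep ≈ 0.01
versus ≈ 0.64 beyond 100 kb (Welch p ≈ 5e-26).

The same stages are exposed as subcommands:

```
repli-timer simulate --seed 1 --out demo_out
repli-timer normalize rep1.bedgraph rep2.bedgraph rep3.bedgraph --out avg.bedgraph
repli-timer profile demo_out/pool_meiS.bedgraph --genome genome.tsv --out trep.bedgraph
repli-timer hu-call demo_out/hu_meiS.bedgraph sites.bed --genome genome.tsv --out calls.json
repli-timer report --seed 1 --out demo_out
```

## Layout

```
src/replitimer/
  synthetic.py    forward simulator (origins, forks, pooling, HU, ChIP)
  signal_io.py    probe tables, BED/bedGraph/TSV I/O, scale normalization
  sites.py        binding-site and axis-site calling
  timing.py       loess profiles, trep, HU calls, scaling model
  association.py  centromere/expression/hotspot associations, statistics
  validation.py   ground-truth verification scenarios
  pipeline.py     end-to-end orchestration and the demo genome
  cli.py          repli-timer subcommands
docs/methods.md   model, assumptions, parameter choices, limitations
```
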