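# Methods

## Scope and data model

`ccmkit` consumes per-cell centroid tracks (pixel coordinates, frames at
a fixed interval, image convention: origin top-left, y down, frames
0-based) as produced by segmentation + tracking pipelines; it does not
segment or track images itself. Downstream it consumes condition
networks as SIF edge lists (typed, directed triples, as emitted by
causal-network inference) with a per-node log-fold-change table, and
long-format phenotype score tables for screen statistics.

## Phenotype metrics

**QC jump filter.** A track is discarded whole when any
consecutive-frame displacement strictly exceeds `jump_threshold`
(default 200 px per 30-min interval); such steps are characteristic of
identity-swap tracking errors. The filter applies to the
displacement-based metrics (MSD, cosine) but not to cell counts or
nearest-neighbour distances: a mis-linked track still represents a
correctly detected cell position, and the count/NN definitions refer to
all cells in the field. Displacements spanning a frame gap never count
as jumps (and never contribute to any metric): interpolating unobserved
motion is less safe than dropping the pair.

**Cell count.** Cells observed per frame divided by the frame-0 count.
Uses tracked cells per frame; reported at the final frame in the
phenotype table.

**MSD slope.** For each lag `τ` between `msd_min_lag` and `msd_max_lag`
(defaults 30–360 min) in frame-interval steps, the squared displacements
of all overlapping start points of all gap-free track runs are pooled
across the field (ensemble-time average), and the slope of an ordinary
least-squares fit of `MSD(τ)` on `τ` *with intercept* is reported. The
intercept absorbs the constant offset produced by localisation noise;
only the slope is the motility estimate (`4D` for 2D Brownian motion,
px²/min). Pooling before the fit weights every displacement pair
equally; per-track slopes are available separately as a diagnostic
(`per_track_msd_slopes`). With a single usable lag the slope through the
origin is returned.

**Nearest-neighbour index.** Observed mean distance to the
`nn_order`-th nearest cell (default 2nd) at one frame, divided by the
CSR expectation at intensity `ρ = n/area`:
`E[r_k] = Γ(k+½)/(Γ(k)√(πρ))`, so `E[r_1] = 1/(2√ρ)` and
`E[r_2] = 3/(4√ρ)`. Two normalisation modes are exposed because the
published rule mixes ranks: `"first"` (default) divides the observed
2nd-neighbour distance by `E[r_1]` — on CSR this converges to
`E[r_2]/E[r_1] = 3/2 `— while `"matched"` divides by `E[r_k]` of the same
rank and converges to 1 on CSR. Which of the two the original wording
intended is unresolvable from the text; both are implemented, neither is
asserted as "the" definition, and outputs should state the mode. No
edge correction is applied (none is used in the source procedure);
boundary effects bias the index upward by ~1% at n = 2000 in a field,
which the test tolerances accommodate. The phenotype table reports the
time-average over frames and the final-frame value side by side (the
per-cell boxplot usage and the %-change usage respectively).

**Cosine collectivity.** For every consecutive frame pair, each cell
with a nonzero displacement is paired with its `n_neighbors_cosine`
(default 10) nearest cells at the pair's first frame, among cells that
also have a nonzero displacement; the metric is the grand mean of the
focal–neighbour displacement cosines over all (focal, neighbour, frame)
triples. This focal-vs-each-neighbour pairing (rather than all 45
pairs among a 10-neighbour set) weights every focal cell equally; the
source wording is ambiguous between the two. Zero-length displacement
vectors are excluded (cosine undefined) and counted in the log. When
fewer than 10 neighbours exist, all available are used, never padded.
Neighbour self-matches are excluded by identity, not by sort order, so
coincident points cannot pair a cell with itself.

## Screen statistics

Scores are normalised per (treatment, metric) stratum by the mean of the
scrambled-control (siSCR) replicates, so control rows average 1 and each
knockdown's normalised deviation from 1 is its effect. Ligand-level
comparisons use Dunnett's many-to-one procedure (EGF control, two-sided,
`scipy.stats.dunnett`); note Dunnett pools the within-group variance
across *all* groups, so its adjusted p can legitimately fall below a
two-group Student t that estimates variance from 4–6 observations — the
dominance property (adjusted ≥ unadjusted) holds, and is tested, against
the marginal pooled-variance t. Knockdown-level comparisons are
unadjusted two-sided Student t-tests vs siSCR per treatment × metric
(Welch available behind a flag), labelled unadjusted in the output.

**Effect-magnitude enrichment.** Per knockdown, the effect under a
treatment is aggregated across the four metrics as the Euclidean norm of
the normalised-score deviations from 1 (a max-abs alternative is
provided; no formula is prescribed by the source, so the rule is
explicit and configurable). A knockdown is a "success" when
|effect under OSM| / |effect under IFNG| > 1, and the one-sided exact
binomial tail at p₀ = 0.5 is reported. The test is discrete: with 14
knockdowns the smallest attainable rejection level below 0.05 is
11/14 → p = 0.0287. The type-I calibration study therefore simulates
screens of 100 knockdowns, where the attainable size is 0.0443 (closed
form) and the empirical rejection rate can meaningfully be compared to
the nominal 0.05; the discreteness at n = 14 is a property of the exact
test, not of the implementation.

**PCA.** Rows are replicate means per knockdown × treatment (replicate
level behind a flag), columns the four metrics, centred and unit-scaled;
components come from `sklearn.decomposition.PCA`. Sign indeterminacy is
removed by orienting each loading vector so its largest-magnitude entry
is positive. Per-treatment mean scores summarise how strongly each
treatment projects on each component. Missing entries are imputed with
the metric mean and logged.

## Network rewiring

Edge identity is the full `(source, relation, target)` triple: relations
are signed and directed, so a change from activation to inhibition costs
one removal plus one addition. A node's raw rewiring score is the size
of the symmetric difference of its incident-edge sets between the two
networks; nodes present in only one network score their full degree
(the score's meaning — edits needed to transform connectivity — covers
them). The normalised score (raw / union degree) is reported alongside
but the *raw* count feeds the default ranking, matching the edit-count
definition taken as normative. Weighting multiplies the raw score by
`max(LFC, 0)` under the condition of interest (upregulated-and-rewired
prioritisation); signed and normalised weightings are flags. Feature
integration keeps the proteomic record when both assays report a node
and then filters at signed `LFC ≥ 1` by default — the literal reading,
which excludes downregulated features; `|LFC|` filtering is a flag since
the intended behaviour is not stated. Ties in the ranking break by raw
score, then node name, making nominations (top 14 by default)
deterministic.

## Synthetic data

The simulator emulates the statistical structure the metrics assume, not
cell biology: per frame, each cell takes an isotropic Gaussian step with
per-axis variance `2·D·Δt`, plus `drift_speed·Δt` along a per-cluster
heading fixed at T0 (persistent collective drift — the signal the cosine
metric must detect), plus a pull of at most `cohesion_strength·Δt`
toward its cluster centroid. The pull is capped at the remaining
distance, which prevents overshoot oscillation and makes cluster
contraction monotone in the deterministic limit; with `D > 0` clusters
relax to a diffusive equilibrium radius instead. Boundaries reflect
(confined field of view, no wrap-around neighbour pairs). Divisions are
per-cell Bernoulli with probability `division_rate·Δt` and spawn a new
track id at the parent position starting the next frame — the tracker
behaviour for divisions is not documented in the source, so this
convention is an explicit assumption. Jump artifacts hit a track with
probability `jump_fraction`: one step is re-pointed to a magnitude drawn
uniformly in (200, 400] px toward the field centre (guaranteeing an
in-bounds landing without reflection, which could otherwise shrink the
step below the QC threshold) and the rest of the track is translated,
folding stray tail positions back into the field — folding is
1-Lipschitz per axis, so it cannot create spurious above-threshold
steps. A single seeded generator drives each run; identical config and
seed give bit-identical tables.

Regime presets (2000×2000 px field, 250 cells, 96 frames at 30 min,
division 0.01 /cell/h, jump fraction 0.02): *EGF_like* `D = 5 px²/min`,
no drift or cohesion; *IFNG_like* the same with `D = 25` (fast dispersed
motion); *OSM_like* `D = 5` with 5 clusters, drift 0.3 px/min and
cohesion 0.3 px/min (cohesive co-drifting clusters, initial scatter
SD 100 px). The values are chosen so the three regimes reproduce the
qualitative phenotype directions (clustering index far below baseline
and elevated cosine under OSM-like; elevated MSD under IFNG-like) at
comfortably separated effect sizes, with realistic cell densities
(~60 µm-scale neighbour spacing at 1 px ≈ 1 µm) and ~2× growth over
48 h. The OSM-like preset's drift also elevates its MSD slope — a known
infidelity to the real OSM phenotype (no motility change), accepted
because no direction-of-effect claim is made for OSM motility.

What the generator does *not* emulate: cell shape and contact mechanics,
density-dependent motility, chemotaxis, heterogeneous per-cell
diffusivity, track fragmentation and missed detections (other than the
injected jump artifacts), and segmentation noise. Passing tests
therefore demonstrate correctness of the estimators on data satisfying
their assumptions, not robustness to every real-imaging artifact.

Point patterns: CSR (uniform), Thomas clusters (uniform parents,
Gaussian daughters folded into the field), square lattices (closed-form
index oracles: 2.0 at rank 1, 4/3 at rank 2, matched mode). Network
pairs: an Erdős–Rényi-style typed directed base network; network B
applies a known set of edge deletions and additions, and the returned
truth table counts the edits touching each node — by construction equal
to the incident-set symmetric difference. The planted-regulator
benchmark adds extra incident edges to one node and gives it the top
LFC (2.5 vs background U(0, 1.5)). Phenotype tables draw
`baseline·(1+effect) + N(0, (noise_sd·baseline)²)` per replicate with
fixed per-metric baselines; `noise_sd` is relative (default 0.05, a
tight in-vitro replicate CV), and the planted OSM-specific disruptor
used in recovery studies has ±0.6 effects on motility/collectivity under
OSM only against a 0.05-SD background.

## Problem sizes and numerical choices

Verification studies run at desk scale: Brownian recovery uses 3
replicate fields of 500 tracks × 96 frames (mirroring triplicate
experimental design; the slope estimator is unbiased with ~2% SD per
field) on a 60000-px field, where reflections are negligible — in a
2000-px field reflections suppress the apparent slope by ~2% at
`D = 25`, which is why boundary-free geometry is used when comparing to
the `4Dτ` closed form. CSR convergence uses 20 patterns of 2000 points;
regime separation 10 seeds per preset in tests (3 in the acceptance
script); screen recovery 50 simulated screens; null calibration 2000
screens. OLS uses `numpy.polyfit`; neighbour queries use
`scipy.spatial.cKDTree`; exact binomials use `scipy.stats.binomtest`.
Degenerate inputs are defined behaviours, not crashes: too few cells for
the NN rank, all-zero displacements, and empty lag windows yield NaN
with warnings (or raise where no result is representable), and the
phenotype table propagates per-metric NaN without aborting.

## Known limitations

Metrics are 2D only. No velocity autocorrelation/persistence analysis
beyond the four metrics. The NN index applies no edge correction. The
rewiring score treats the two networks as fixed inputs — inference
uncertainty in the networks is not propagated. The daughter-track and
jump-artifact conventions in the simulator are assumptions, flagged
above. Dunnett p-values come from numerical multivariate-t integration
and carry ~1% relative error.
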