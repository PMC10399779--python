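# Methods

This note documents the models, defaults and numerical choices behind
`colonynet`, and what the synthetic-data experiments do and do not show.

## Interaction detection

Head and body regions are modelled as disks derived from the tag pose: the
head disk centre sits `head_offset` ahead of the tag along the body axis
with radius `head_radius`; the body disk is centred on the tag. Defaults
scale from a mean body length of 8 mm (`head_offset = 0.4 L`,
`head_radius = 0.2 L`, `body_radius = 0.35 L`); real annotation tools use
per-ant polygons, so the disk model is a deliberate simplification whose
parameters are exposed.

An edge weight counts contact *bouts* — maximal runs of contact frames —
rather than contact frames, since "number of interactions" is an event
count. Runs separated by at most `gap_bridge` non-contact frames are merged
(default 0; exposed because tracking pipelines differ on whether an
interrupted contact is one event). A frame in which either worker is
undetected is a non-contact frame. In mode `head_or_body`, contact
additionally occurs when either head disk intersects the other worker's
body disk; this strictly dominating definition serves as a
false-positive-enriched comparison channel and the two channels'
pairwise counts are strongly correlated on simulated colonies.

## Spatial fidelity

Positions are binned into flat-top hexagons whose internal diameter
(distance between parallel sides) equals the mean body length, via
fractional axial coordinates and cube rounding with the largest-residual
correction — verified in tests against an exhaustive nearest-centre search.
The grid is anchored at the coordinate origin; occupancy row sums equal
each worker's detection count by construction.

## Soft community detection and social maturity

The interaction matrix is normalised to total mass 1 and factorised as
`W ≈ X Λ Xᵀ` by minimising `D_KL(W ‖ XΛXᵀ)`. The multiplicative updates

    x_ic ∝ x_ic Σ_j [w_ij / (XΛXᵀ)_ij] λ_c x_jc      (column-normalised)
    λ_c  ∝ λ_c Σ_ij [w_ij / (XΛXᵀ)_ij] x_ic x_jc     (normalised to Σλ = 1)

are the M-step of an EM algorithm on the mixture-over-communities model of
edge mass (both updates share one set of responsibilities), so the KL
objective is non-increasing at every iteration — asserted in tests. The
static (single-snapshot) variant is implemented because the analysis
aggregates each colony's network over the whole observation window;
temporal smoothing is out of scope.

Membership is `M_ic ∝ X_ic Λ_c` with rows normalised; with `k = 2`, the
column correlating best with the foraging fraction is labelled the forager
community and its membership is the social maturity. Exact correlation ties
fall back to the column whose top-decile members forage most. Defaults:
10 Dirichlet random restarts, `tol 1e-9`, `max_iter 2000`, an `1e-12` guard
inside ratios, and uniform membership (flagged) for isolated zero-strength
workers, which are normally removed earlier by the detection filter.

A caveat surfaced by simulation: at very low network density (expected
node strength ≈ 20 on 100 workers) the membership estimate is limited by
the information in the counts themselves — truth-initialised fits do no
better than random restarts, with recovery r ≈ 0.89 against the latent
trait. Recovery is excellent (r ≥ 0.93) from strength ≈ 30 upward; the
trajectory-derived networks of the default generator are far denser still.

## Differential expression engine

A desk-scale NB GLM chain: median-of-ratios size factors over genes
expressed everywhere (≥ 90 % fallback); per-gene dispersions by
design-aware method of moments — Poisson-fitted means, estimator
`Σ[(y−μ̂)² − μ̂]/μ̂² / (n − p)`, floored at `1e-8` — shrunk on the log scale
(weight 0.25) toward a decreasing isotonic trend in mean expression; Wald
tests from vectorised IRLS with a small ridge (`1e-8`) and `±30` clamp on
the linear predictor; BH correction; non-convergent genes flagged with
p = 1 (conservative). Compared with full empirical-Bayes frameworks there
is no Cox–Reid adjustment, independent filtering or LFC shrinkage; the
conclusions drawn here rest on DE *counts*, and the engine's type-I error
and effect recovery are directly verified: null rejection at p < 0.05
within [0.03, 0.07], BH-significant fraction ≤ 0.05 under permutation, and
planted |log2FC| = 1 recovered within ±0.1 at n = 200. Effect-size
calibration uses balanced up/down effects, the standard design that keeps
median-of-ratios normalisation valid; with all effects in one direction
size-factor absorption attenuates estimates by a few percent, which is a
property of the normalisation, not the estimator.

The controlled accounting reads "remain differentially expressed" as the
intersection of the uncontrolled DE set with the controlled one; the
companion tables also report the controlled-only percentages and
fractions of all tested genes. Near-collinear controls (|r| > 0.999,
including a variable against itself) return an empty controlled set.

## Layers, reduction and the R² network

Distances are plain Euclidean on: within-colony min-max-normalised
behaviour profiles; size-factor-normalised, `log2(x+1)`, gene-centred
expression; relative ASV abundances after endosymbiont exclusion
(endosymbiont-only workers keep an all-zero profile so worker sets stay
aligned); row-proportion hexagon occupancy. Quartile thresholds use linear
interpolation of order statistics and strict inequality, so an all-equal
weight distribution yields no edges. Distance layers threshold at the
*lower* quartile since distance is a dissimilarity.

Layer scores: social maturity for the social layer; otherwise centred PCA
(full SVD for determinism), sign-fixed against the foraging fraction. For
expression, the component used is chosen by comparing each component's
one-way R² against extraction batch with its best R² against the
biological variables, picking the smallest-index component where biology
wins — on the default generator batch effects dominate the leading
component and the second is selected. PCA is per colony for the
correlation analysis and pooled for prediction. The interlayer network
averages per-colony R² matrices with equal weight; node strength is the
sum of incident R² and the argmax is the hub.

The random-intercept regressions (maturity against age and foraging with
colony as the grouping factor) are maximum-likelihood fits via statsmodels
MixedLM; R² is defined as the squared correlation between the
fixed-effect fitted values and the response, a marginal-style definition
reported alongside the Wald t of the slope.

## Prediction

Features are the genes DE for the target (BH < 0.05, pooled model
colony + target), following the convention of selecting on all samples;
because that leaks target information across the split, `strict_cv=True`
re-selects within each training half for leakage-free estimates. Counts
are size-factor-normalised, `log2(x+1)`, z-scored on training-half
statistics; the regressor is epsilon-insensitive SVR with linear kernel,
cost 1, epsilon 0.1; splits are stratified by colony so colony terms stay
estimable. The permutation null keeps the informative feature set and
permutes the target — the standard permutation test, used because DE
selection on a permuted target correctly returns an empty gene set.
Out-of-sample accuracy is the squared Pearson correlation between
predicted and observed, so recorded values lie in [0, 1]; constant
predictions score 0 with a warning.

## Synthetic colony generator

The generator emulates a 4-colony, ~100-workers-per-colony study with a
latent per-worker maturity `m ~ Beta(0.5, 0.5)` (the simplest
two-parameter bimodal family for the observed U-shape) driving every
layer:

- **Age**: `r·z(m) + √(1−r²)·ε` mapped to 1–52 weeks, so the population
  correlation equals the target (default 0.7).
- **Trajectories** (900 frames at 2 fps by default — a deliberately
  scaled-down observation window relative to week-long recordings):
  workers re-draw a task role at rate 0.08/frame, taking the forager role
  with probability `m`. Both roles congregate at *shared* sites (brood
  area in the nest, food source in the arena), so position reveals chamber
  choice but not role; the network's maturity signal comes from directed
  encounter events (rate 0.35/frame, cross-community acceptance 0.10) in
  which a worker engages a partner head-to-head — mirroring the fact that
  most real contacts are directed interactions (trophallaxis, grooming,
  antennation) rather than passive overlap. Forager-role workers enter the
  arena at 0.8 vs 0.05 for nurse-role. Idiosyncratic, maturity-independent
  structure — shared landmarks visited by worker-specific preference,
  per-worker site-fidelity offsets, chamber-wide excursions — keeps space
  use from being a perfect readout of role, as in real colonies where the
  physical environment is a comparatively weak correlate. A small
  fraction of workers carries poorly detected tags, exercising the
  detection filter.
- **Behaviour**: five manual behaviours as binomial counts out of 80
  annotated frames with a per-worker behavioural disposition (sd 0.30 on
  the maturity scale) shared across behaviours — individual idiosyncrasy
  that sparse annotation cannot average away — plus Beta jitter; nursing
  and queen-tending decrease with maturity, guarding/cleaning/trophallaxis
  depend on it weakly; the foraging fraction is Beta-distributed around an
  increasing function of maturity (the pipeline replaces it with the
  trajectory-derived fraction).
- **Expression**: `count ~ NB(s_w · q_g · 2^(β_g m_w + B_{g,batch}), α)`
  with `β_g = 1` (a 2-fold nurse-to-forager change) for 120 of 1200 genes,
  dispersion 0.3, and gene-specific batch effects (sd 1.0 on the log2
  scale) — gene-specific because a gene-independent batch shift is a pure
  depth effect that size factors absorb and could never dominate the
  leading expression component the way extraction batches do in practice.
- **Microbiota**: Dirichlet-multinomial over 40 ASVs; the endosymbiont's
  Dirichlet weight is pinned to 90 % of the concentration so its expected
  relative abundance equals the configured fraction; 5 minor taxa have
  weights rising exponentially with maturity (forager-associated
  facultative species).

A fast path draws interaction counts directly from
`w_ij ~ Poisson(λ·[m_i m_j + (1−m_i)(1−m_j) + 0.05])` with λ set from the
target expected node strength, for tests that exercise community recovery
without trajectories.

**What passing tests show — and don't.** The generator realises the causal
structure the analysis is designed to detect: one latent axis drives all
layers, measured with layer-specific noise. Passing the hub, asymmetry and
ranking checks shows the pipeline recovers a planted structure through
every stage, not that real colonies are organised this way; real data add
id-swap tracking errors, temporal non-stationarity (light cycles,
senescence), non-NB expression artefacts, compositional microbiota effects
and annotation bias that the generator deliberately omits.

## Determinism and scale

Every stage is seeded; a master seed fans out through `SeedSequence`
spawning so stages are independently reproducible, and two runs with one
master seed produce byte-identical artifacts. PCA uses full SVD
(the randomised solver is not deterministic across runs without a fixed
state). Default problem sizes — 4 × 100 workers, 900 frames, 1200 genes,
40 ASVs, 100 prediction iterations — are chosen so a full analysis
completes in minutes on a single CPU while keeping every statistical
regime (count noise, multiple testing, half-split variance) represented.
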