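# Methods

`restdyn` implements a resting-state functional-connectivity pipeline for
parcellated BOLD cohorts — static network aggregation, time-resolved
coupling and graph cartography, two-state brain-state dynamics,
receptor-density spatial mapping, and group / longitudinal / survival
inference — together with a synthetic cohort generator that plants every
effect the pipeline is meant to recover. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Static connectivity

Functional connectivity (FC) between two regions is the Pearson correlation
of their BOLD series over the full scan. Aggregates are computed from the
region × region matrix with the diagonal always excluded:

- **whole-cortex FC** — mean over all unordered distinct cortical pairs;
- **network-to-cortex FC** of network *N* — for each node in *N*, the mean
  correlation to every other cortical node (the network's own pairs
  included), averaged over the network's nodes;
- **internetwork FC** — mean over all node pairs of two distinct networks;
  the self-pair is the within-network mean over unordered distinct pairs,
  undefined (flagged) for single-region networks;
- **seed-to-network FC** — mean correlation from each subcortical seed
  (NBM, LC, BG) to the nodes of each of the eight networks.

Averages are taken on raw r by default; Fisher-z averaging is available via
a flag (`fisher_z=True`). Raw-r averaging is the primary contract and the
exact pair-count-weighted decomposition of whole-cortex FC into block means
holds on it identically.

## Configuration similarity

The T × T matrix of Pearson correlations between whole-brain spatial
activity vectors at pairs of timepoints yields **local similarity** S_L
(mean over consecutive-pair entries; high values mean a stationary
configuration) and **global similarity** S_G (mean over all off-diagonal
entries; high values mean low configuration variability). A constant
spatial vector at any timepoint makes the correlation undefined and raises
with the timepoint named.

## MTD coupling

Time-resolved coupling uses the multiplication of temporal derivatives:
each region's series is z-scored, first-differenced, the derivative is
demeaned (this makes the time-averaged self-coupling exactly 1), and the
pointwise product of two regions' derivatives is divided by the product of
their derivative standard deviations (population SD over the whole scan).
The raw score is smoothed with a centred simple moving average, window
**15 TRs** by default. Edge handling: windows are truncated at the scan
edges by default (`edge_mode="truncate"`); `"valid"` drops the first and
last ⌊w/2⌋ windows instead. Note that truncation reweights edge points, so
the time-mean of the smoothed self-coupling is ≈1 rather than exactly 1.

## Graph cartography and brain states

Each coupling slice is partitioned by **signed Louvain**: the quality
function is `Q* = Q+ − (w−/(w+ + w−)) Q−`, rewarding positive weight and
penalising negative weight inside modules with the penalty down-weighted by
the negative weight share. The optimiser is the standard two-phase Louvain
heuristic with a configurable resolution γ (default 1), 10 random restarts
per slice keeping the best Q*, and full seed provenance. Local-move sweeps
are capped at 100 per level to guard against near-tie micro-gain cycling.
An all-zero slice gets the all-singletons partition with Q = 0, flagged.
No module-label matching is done across time: every downstream quantity
(Q, B, W) is label-invariant.

Cartography uses **positive couplings only** (the participation formula is
undefined for negative strengths):

- participation coefficient `B(i,t) = 1 − Σ_s (κ_is / k_i)²` with κ_is the
  positive strength from node i into module s; B = 0 (flagged) for a node
  with zero positive strength;
- module degree z-score `W(i,t)` — within-module strength standardised
  against the node's module (population SD); 0 for singleton or uniform
  modules.

**State classification**: the per-window feature vector (node-mean B,
node-mean W) is z-scored across time and clustered with k-means (k = 2,
50 restarts, fixed seed). The cluster with the higher raw mean-B centroid
is *integrated*; exact ties break to the lower mean-W. Because module
degree z-scores sum to zero within every module, the node-mean W feature
is identically (or numerically) zero; a zero-variance feature is left at
zero, and an error is raised only when both features are degenerate.
Classification is per participant by default; `classify_states_cohort`
pools the windows of a whole cohort into one clustering with shared
centroids — the pooled variant remains well-posed for a participant who
spends an entire scan in a single state, for whom per-subject two-state
clustering necessarily splits noise.

An optional **majority (mode) filter** on the label sequence
(`smooth_window`, off by default) suppresses state transitions shorter
than the coupling estimator's temporal resolution; setting it to the MTD
window length is the natural choice when dwell times and transition counts
are of interest, since a 15-TR smoothing window cannot resolve shorter
excursions and isolated one-window label errors otherwise dominate the
mean-dwell statistic (each spurious run shortens the harmonic structure of
run lengths far more than it lowers agreement).

State summaries: mean dwell per state (mean maximal run length, window
units and seconds via the TR), transition count, and time fractions; a
state absent from a sequence has undefined dwell and is flagged.

## Receptor-density mapping

A regional statistic map (one value per cortical region) is compared with
receptor/transporter density maps (A4B2, M1, VAChT, D1, D2, DAT, NET) by
Spearman rank correlation (average-rank ties, two-sided t-approximation p,
BH-FDR across the map family). No spatial-autocorrelation-preserving null
is applied by default — plain Spearman p values are the primary output and
their limitation (spatially smooth maps inflate significance) is noted
here; a region-permutation null can be added by the caller.

**Dominance analysis** decomposes the full-model OLS R² across predictors:
the general dominance weight of predictor j is the average over subset
sizes of its mean incremental R² when added to subsets of the remaining
predictors. Weights are non-negative (incremental R² is non-negative) and
sum to the full-model R² exactly. All 2^p subsets are fitted; p ≤ 12 is
enforced. Fits are on raw values by default, with a rank-based variant
(`on_ranks=True`) reported under its own label.

## Inference layer

- **Cross-sectional GLM** — OLS of a per-subject metric on a case/control
  indicator plus age, sex (binary indicator), education; reports the group
  term with t statistic, two-sided p, and 95% CI. Rank-deficient designs
  and groups with < 2 members error. An optional within-cohort label
  permutation p is available.
- **Longitudinal mixed model** — fixed effects months + age + sex +
  education, random intercept per subject; REML with a maximum-likelihood
  refit on non-convergence and a surfaced convergence flag; a cohort in
  which no subject has a second visit errors as unidentifiable.
- **Cox phenoconversion models** — partial-likelihood fit (Breslow ties)
  of conversion risk on the z-scored baseline metric, so hazard ratios are
  per SD. Endpoints: conversion to any synucleinopathy (PD or DLB), and
  conversion to DLB only with PD conversions censored at their conversion
  time. Zero-event endpoints error.
- **FDR** — Benjamini–Hochberg step-up within declared families. The
  default family granularity mirrors the analysis structure: 8
  network-to-cortex tests, 36 internetwork cells, 24 seed-to-network
  cells, 7 receptor maps.

## Synthetic cohort generator

The generator produces second-order structure only — the analysis operates
on correlations, so Gaussian BOLD with block covariance is sufficient and
maximally testable. Region i in network n at timepoint t is

    x_i(t) = √a_t · g(t) + √b_t · f_n(t) + √(1 − a_t − b_t) · ε_i(t)

with one global factor g, one factor per network f_n, and i.i.d. noise, so
the between-network correlation is a_t and the within-network correlation
a_t + b_t. A two-state Markov chain (geometric dwell, default mean 100
timepoints) switches the regime: **segregated** (within r 0.65, between r
0.02) vs **integrated** (within r 0.40, between r 0.30) — elevated
within-network coupling in the segregated regime, elevated between-network
coupling with weakened module structure in the integrated one. The factor
construction keeps the implied covariance positive semi-definite by
construction; regimes whose base within coupling falls below the between
coupling are rejected before sampling.

Planted effects:

- **case deficit** — the within-coupling of the affected network (visual by
  default) is reduced by `group_effect` (default 0.10) in cases;
- **longitudinal decline** — within-coupling changes by
  `longitudinal_slope` (default −0.002/month) in cases across visits;
- **subject heterogeneity** — a per-subject Gaussian intercept on within
  couplings (SD 0.02). Subject/case/time shifts bottom out at the
  between-coupling floor (b ≥ 0) rather than erroring;
- **seeds** — NBM/LC/BG rows load on one network latent each (LC on
  visual) with loading r 0.3 plus independent noise;
- **conversion outcomes** — exponential proportional hazards on the
  z-scored planted baseline coupling, default hazard ratio 1.66 per SD
  (decreasing coupling increases risk), baseline hazard log 2 / 60 months,
  independent exponential censoring calibrated to ≈60% censored, PD:DLB
  event split 10:7;
- **receptor maps** — a Gaussian rank copula plants a chosen population
  Spearman correlation between each density map and a regional effect map
  (default planted ρ per map mirrors the cholinergic/noradrenergic-heavy,
  dopaminergic-null pattern: VAChT and NET 0.17, A4B2 0.10, DAT 0.07, D1
  −0.03, D2 −0.05, M1 0). |ρ| = 1 reproduces ranks exactly.

Cohort composition defaults: 41 cases, 38 controls, 400 cortical regions
in eight equal networks, TR 2 s, T = 300; cases male-skewed (34:41) with
age ≈ N(66, 7) and education ≈ N(13, 3), controls balanced, matching the
modelled cohort's demographics. Repeat visits follow `visit_months` for
cases only; controls are scanned at baseline.

What the generator does **not** emulate: haemodynamic response shape and
temporal autocorrelation (timepoints are serially independent given the
regime), motion and physiological artefacts, scanner noise spectra,
spatial autocorrelation within networks, and any nonlinearity. Passing
tests therefore certify the statistical machinery — estimator contracts,
planted-parameter recovery, calibration — not robustness to realistic
noise structure.

## Verification experiment sizes and choices

The planted-truth experiments (in `restdyn.evaluation`, driven by
`scripts/acceptance.py` and the acceptance test suite) use these problem
sizes, chosen as the smallest scales at which the targeted property is
cleanly measurable:

- graph oracles: exhaustive set-partition search on 6-node graphs, 10
  random signed toy graphs for brute-force cartography checks;
- state recovery: 20 subjects × 80 regions (8 networks of 10) × 500
  timepoints, MTD window 15, Louvain restarts 10. Two deliberate analysis
  choices apply here: Louvain resolution γ = 1.5, matching the planted
  module scale (at γ = 1 the 15-TR windowed estimates merge the n/10-node
  modules — the classic resolution limit under estimator noise — which
  corrupts participation), and pooled cohort clustering with the label
  mode-filter at the window width, for the reasons given above. The
  package-level defaults (γ = 1, per-subject clustering, no smoothing)
  are unchanged;
- mixed-model recovery: 100 replicates of 40 subjects × 3 visits (0, 24,
  48 months), planted slope −0.002/month, intercept SD 0.1, residual SD
  0.05;
- Cox coverage: 100 replicates of n = 500 with planted HR 1.66/SD and 60%
  censoring; GLM calibration: 1000 null replicates of n = 200;
- receptor mapping: 400 regions, planted ρ = 0.5;
- end-to-end contrast: 20 seeds of 20 cases vs 20 controls, 80 regions,
  T = 300, planted within-visual deficit 0.10, scanning all 36
  internetwork cells with covariate-adjusted GLMs.

## Numerical choices

- Region ordering: the metadata file's row order is canonical; every
  matrix uses it. Written numerics use 10 significant digits.
- Zero-variance detection (regions, derivatives, features, modules) uses
  relative tolerances of ~1e-12 rather than exact zero.
- Louvain move acceptance requires a gain > 1e-10; k-means uses 50
  restarts; Spearman ties use average ranks.
- Dominance subsets are fitted by least squares on centred data; the
  weight-sum identity is verified to 1e-10.
- Seeds: every stochastic routine takes an explicit seed; the generator is
  bit-reproducible for a fixed spec and seed.

## Known limitations

- Serially independent synthetic BOLD overstates the effective sample size
  per MTD window relative to autocorrelated real data; real-data dwell and
  agreement figures would be less favourable at the same scan length.
- The node-mean W state feature is structurally uninformative (zero-sum
  z-scores); the two-state split is effectively driven by participation.
- Plain Spearman p values ignore spatial autocorrelation of cortical maps.
- The Cox layer models baseline metrics only (no time-varying covariates),
  and the mixed model fits random intercepts, not random slopes.
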