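# restdyn

Static and time-resolved resting-state functional connectivity for
parcellated BOLD cohorts, built for longitudinal case–control studies of
prodromal neurodegeneration (e.g. iRBD cohorts followed to
phenoconversion). The package takes already-parcellated region × time
tables — no image-space processing — and carries them through:

- **static FC** — Pearson connectivity matrices aggregated to whole-cortex,
  network-to-cortex, internetwork, and subcortical-seed-to-network level
  (eight resting-state networks; NBM, LC, BG seeds);
- **temporal dynamics** — spatial-configuration similarity (S_L, S_G) and
  the multiplication-of-temporal-derivatives (MTD) coupling tensor with a
  15-TR sliding window;
- **graph dynamics** — per-window signed-Louvain modularity Q,
  participation coefficient B and module degree z-score W, and k-means
  (k = 2) classification of windows into integrated (high B) vs segregated
  states with dwell-time and transition summaries;
- **receptor mapping** — Spearman correlation of regional statistic maps
  with receptor/transporter density maps (A4B2, M1, VAChT, D1, D2, DAT,
  NET) plus all-subsets dominance analysis of the explained variance;
- **inference** — covariate-adjusted GLM group contrasts, random-intercept
  mixed models for change over months, Cox proportional-hazards models of
  phenoconversion (per-SD hazard ratios; any-synucleinopathy and DLB-only
  endpoints), and Benjamini–Hochberg FDR within declared families;
- **synthetic cohorts** — a generator that plants every effect the pipeline
  measures (block-covariance BOLD with Markov-switching
  integrated/segregated regimes, case and longitudinal coupling effects,
  rank-copula receptor maps, proportional-hazards conversion times), so
  each stage can be tested against known ground truth.

The scientific core, in the field's notation: time-resolved coupling
`MTD_ij(t) = ⟨Δz_i·Δz_j / (σ_{Δi}σ_{Δj})⟩_w`; signed modularity
`Q* = Q⁺ − (w⁻/(w⁺+w⁻))Q⁻` optimised by Louvain per window; participation
`B_i = 1 − Σ_s (κ_is/k_i)²`; module degree z-score
`W_i = (κ_i,own − μ_module)/σ_module`; hazard `λ(t|z) = λ₀(t)·e^{βz}` for a
z-scored baseline connectivity measure. See `docs/methods.md` for the full
model account, defaults, and limitations.

## Worked example

Generate a small synthetic cohort and push one subject through the dynamic
pipeline:

```python
from restdyn import (SimulationSpec, simulate_bold_cohort, mtd_coupling,
                     time_resolved_partition, node_cartography,
                     classify_states, state_statistics)

spec = SimulationSpec(n_cases=2, n_controls=0, n_regions=80,
                      n_timepoints=500, include_seeds=False, seed=11)
cohort = simulate_bold_cohort(spec)

series = cohort.series[0]
tensor = mtd_coupling(series, window_length=15)
traj = time_resolved_partition(tensor, gamma=1.5, seed=0)
cart = node_cartography(tensor, traj)
states = classify_states(cart, seed=0, smooth_window=15)
summary = state_statistics(states, tr_seconds=series.tr_seconds)

print(f"mean Q = {traj.q_trace.mean():.3f}")
print(f"mean B = {cart.B.mean():.3f}")
print(f"integrated fraction = {summary.fraction_time['integrated']:.2f}")
print(f"transitions = {summary.n_transitions}")
```

Output:

```
mean Q = 0.256
mean B = 0.629
integrated fraction = 0.29
transitions = 3
```

The subject spends ~29% of windows in the integrated state (elevated
between-network coupling; the generator planted switching regimes with
mean dwell 100 TRs, so a handful of transitions in 486 windows is the
expected order), mean modularity 0.26 reflects the eight planted modules
seen through 15-TR windowed estimates, and mean participation 0.63 sits
between the segregated and integrated planted levels.

The same stages are scriptable from a shell via the thin CLI:

```bash
restdyn simulate --out cohort/ --seed 7 --n-cases 4 --n-controls 4 \
    --n-regions 40 --n-timepoints 200
restdyn static  --series-dir cohort/series --metadata cohort/metadata.tsv \
    --out static_metrics.tsv
restdyn dynamic --series-dir cohort/series --metadata cohort/metadata.tsv \
    --out dynamic_metrics.tsv
```

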