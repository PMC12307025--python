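# Methods

This note documents the models, estimators and numerical choices behind
`eegconn`, and what the synthetic validation data can and cannot show.

## Spectral stage

**Low-pass filter.** Zero-phase (forward–backward) Butterworth, default
cutoff 30 Hz. The order is 5: after the two passes this attenuates power
at 1.25× the cutoff by ≈20 dB, which we treat as the filter's contract; a
4th-order filter misses that mark (≈17 dB). The pass band is flat to
within 1 % and phase is identically zero, so epoch timing is untouched.

**Epoching.** Fixed 12 s epochs, 50 % overlap; the epoch count is
`floor((T − 12)/6) + 1` and trailing samples are discarded. Twelve-second
epochs give the 1/12 Hz resolution needed to resolve IAPF-relative band
edges; the overlap doubles the epoch count at the cost of correlation
between neighbouring epochs, which the dwPLI estimator tolerates (its
bias correction concerns within-epoch noise, not epoch dependence).

**Cross-spectral densities.** One Hann taper per epoch, rFFT, density
scaling such that the auto-spectrum integrates to the windowed variance.
The CSD is stored in factored form — per-epoch tapered Fourier
coefficients of shape (epochs × channels × freqs) — rather than the full
4-D array: cross-spectra are formed on demand as `X_i · conj(X_j)`, which
is Hermitian by construction and keeps memory linear in channel count
(the full array for 61 channels × 79 epochs × 367 bins would be ≈1 GB).

**IAPF.** Channel spectra are smoothed with a Savitzky–Golay filter
(window 11 bins, polyorder 5, the convention of resting-alpha tooling)
and searched in [7, 13] Hz. A channel peak must be a local maximum with
negative second difference *and* exceed a power-law background —
a log–log linear fit across the window — by at least 100 % (i.e. reach
2× background). The background criterion is what rejects peakless 1/f
spectra: on pure noise the largest spurious rise we observe is ≈0.6×,
while genuine alpha bumps rise 7–11×. The subject IAPF is the
prominence-weighted mean of channel peaks; no qualifying channel
anywhere yields an explicit `no_peak` flag rather than a number.

**Bands.** delta [IAPF−8, IAPF−6), theta [IAPF−6, IAPF−4), alpha
[IAPF−4, IAPF+2), beta [IAPF+2, 30]. Intervals are half-open except
beta's closed upper edge; a frequency bin belongs to a band iff its
centre lies in the interval. The four bands tile [IAPF−8, 30] exactly,
for any IAPF — a property test covers this. At low IAPF the delta band
may extend below the lowest resolvable bin; only bins with positive
centre frequencies contribute.

## dwPLI

Per frequency bin and channel pair, with `I_k` the imaginary part of the
epoch-`k` cross-spectrum:

```
dwPLI = [ (Σ I_k)² − Σ I_k² ] / [ (Σ |I_k|)² − Σ I_k² ]
```

The subtraction of `Σ I_k²` in both numerator and denominator is the
debiasing: under independence the estimator is centred on zero (signed
values can be negative), unlike naive |imaginary coherence| which is
positively biased at finite epoch counts. A denominator of exactly zero
(all `I_k = 0`) means no measurable lagged coupling; the estimate is
defined as 0 with a degeneracy flag, not NaN, because downstream graph
code treats 0 as "no edge".

Band values average the *signed* per-bin estimates over the band's bins,
then take the absolute value. The alternative (absolute value per bin,
then average) is available behind a flag but inflates the null — noise
bins no longer cancel — and is not used by the pipeline.

## OMST thresholding

Kruskal's algorithm on edge distances 1/w extracts successive
edge-disjoint spanning trees; equal-weight edges order lexicographically
by label pair for cross-platform determinism. After each cumulative
union the objective J = GE − Cost is evaluated **on weights rescaled to
[0, 1] by their maximum** (the published algorithm's normalisation; MST
rounds and the cost ratio are scale invariant but GE is not — without
rescaling J degenerates to a monotone decreasing curve and m* is always
1). GE is the mean over ordered node pairs of 1/d on the selected
subgraph with 1/∞ = 0; Cost is selected weight over total weight.

Round extraction stops when the residual graph no longer spans all
nodes; the scan is capped at ⌊(n−1)/2⌋ rounds and stops early after 3
consecutive decreases of J (the curve is near-concave in practice; an
`exhaustive` switch disables the heuristic, and the acceptance tests use
it when comparing against brute force). Ties in J resolve to the smaller
round count. The thresholded graph keeps original weights on selected
edges and is connected by construction, so characteristic path length is
always defined on OMST outputs; clustering and the small-world index may
still be missing when m* = 1 leaves a tree.

A pass-through `full` mode applies no thresholding, for analyses of the
dense matrices; no proportional or absolute thresholds are offered.

## Graph metrics

All metrics operate on weights rescaled to [0, 1] by the maximum, which
makes every index invariant to overall weight scaling.

* **Clustering (Onnela).**
  `C_i = (1/(k_i(k_i−1))) Σ_{j,h} (w_ij w_ih w_jh)^{1/3}`. Nodes with
  fewer than two neighbours have no defined value and are excluded from
  the mean; the mean is missing only when *no* node has degree ≥ 2.
  A triangle-free hub graph therefore scores 0, not missing.
* **Modularity.** Weighted Newman Q. Graphs with ≤ 8 nodes are solved
  exactly by set-partition enumeration (restricted growth strings,
  Bell(8) = 4140 partitions); larger graphs use Louvain with 20 seeded
  restarts, keeping the best Q, with the one-community partition (Q = 0)
  always a candidate. The exact small-graph path exists because greedy
  Louvain can stall in a local optimum even at 6 nodes (observed ~0.1 %
  of random instances), and small-graph exactness is a correctness
  guarantee the test suite relies on.
* **Characteristic path length.** Mean weighted shortest-path distance
  (Dijkstra on 1/w) over ordered pairs; missing on disconnected graphs
  rather than substituting a harmonic-mean efficiency, which would
  silently change the estimand.
* **Small-world index.** σ = (C/C̄_null)/(L/L̄_null) with 50 surrogates by
  default. Surrogates use *connected* double-edge swaps (degree
  sequence preserved, connectivity preserved) with the weight multiset
  shuffled uniformly over the rewired edges. Plain degree-preserving
  rewiring can disconnect sparse graphs and leave L_null undefined; the
  connected variant keeps the null defined whenever the observed graph
  is. σ is missing when C is missing or 0, L is missing, or a null mean
  degenerates — which is exactly what happens on trees.

## Synthetic cohorts

The generator emulates 61-channel (10-10 montage) eyes-closed resting
recordings at 250 Hz, default 480 s (the study design's total eyes-closed
time), so a default subject yields 79 epochs.

Each channel sums four band-limited oscillators (white noise shaped by a
spectral envelope spanning the subject's IAPF-relative band; the alpha
envelope carries a Gaussian bump, SD 0.75 Hz, centred on the true peak)
plus 1/f noise. Band amplitudes are delta 1.0, theta 0.8, alpha 1.6,
beta 0.7 with 1/f amplitude 0.7 — alpha-dominant, as at rest, and strong
enough that the IAPF stage recovers planted peaks to within ±0.25 Hz.

**Coupling.** A `CouplingSpec` replaces part of the target's band
oscillator with a copy of the source's whose positive-frequency
components are rotated by `phase_lag` radians — a uniform phase lag
across the band, which shows up directly and exclusively in the
imaginary cross-spectrum. The default lag is π/2 (maximal imaginary
part). Mixing weights are `sqrt(1 − Σs²)` own + `Σ s_i` lagged sources,
so strengths act like correlation coefficients; the long-simulation
plateau of band dwPLI at strength 0.9 is ≈0.96.

**Default cohort structure.** Two travelling-wave driver fields per band
(the first and last channel's oscillators received by every other
channel at channel-specific phases with incommensurate gradients) give
*every* pair a consistent relative lag, producing the broad, smoothly
varying weight distribution real sensor-space matrices show; an
additional alpha-band module-hub layer (4 contiguous modules) raises
within-module coherence above between-module. Coupling strength defaults
to 0.55. Under these defaults full-matrix median dwPLI is ≈0.2, OMST
typically selects 2 trees, and the OMST-graph metrics land in the
empirically reported regime (clustering 0.03–0.07, Q ≈ 0.5, L 4–7,
σ 0.6–1.0), while a fraction of subject × band graphs still come out as
trees with missing clustering/small-world values — the missingness
pattern the statistics stage must tolerate.

**Zero-lag mixing.** `zero_lag_mix` adds one shared 1/f source
instantaneously to all channels. It raises real-part coherence but
leaves the imaginary cross-spectrum untouched, so dwPLI is unaffected —
the volume-conduction control used throughout the tests.

**Behavioural scores.** One chosen metric column is z-scaled across
subjects and scores follow
`b0 + b_m·z + b_a·older + b_s·male + b_i·z·older + N(0, σ)` with
treatment coding, rounded and clipped at zero to mimic word counts
(a `round_scores=False` switch exposes the exact linear predictor for
noiseless tests). Defaults put the intercept at 25 (the younger-group
semantic mean), age effect −2.46, interaction −3.85 and residual SD 5 —
word-count-scale values. Subjects with missing metrics get missing
scores, never imputed. Older subjects draw their true alpha peak from
N(9.4, 0.9) Hz and younger from N(10.1, 0.9), truncated to [7, 13].

**What the synthetic data do not show.** No ocular/muscle artifacts, no
line noise, no non-stationarity, no genuine volume-conduction forward
model (the zero-lag source is a one-dimensional surrogate), no
electrode-position geometry (modules are contiguous label blocks, not
spatial neighbourhoods). Passing tests therefore demonstrate estimator
and pipeline correctness under the stated signal model, not robustness
to real-world recording pathologies, which are assumed to be removed by
upstream cleaning.

## Statistics

* **Wilcoxon rank-sum:** midranks, normal approximation with tie
  correction and continuity correction; `W` is the Mann–Whitney
  statistic of the first sample; effect size r = |Z|/√(n₁+n₂). Exact
  two-sided p by enumeration of rank assignments is used automatically
  for groups ≤ 10 without ties.
* **Outliers:** scores beyond ±3 sample SDs are flagged (and, in the
  pipeline, reported — not silently dropped). Note the rule cannot flag
  a single extreme value in very small samples: with n observations the
  largest attainable |z| is (n−1)/√n.
* **Models:** OLS (statsmodels) on explicit design matrices — intercept,
  z-scaled metrics (SD with n−1), treatment-coded age and sex dummies,
  and metric × age products. Rank deficiency raises an error naming the
  collinear columns. Predictors are scaled *before* leverage filtering
  and not re-scaled afterwards, so reported coefficients stay on the
  full-sample SD scale.
* **Leverage filtering:** one pass; rows with hat diagonal above
  2(p+1)/n (p = non-intercept predictors) are removed and the model
  refit; only the refit is reported, with the removal count. On balanced
  factorial designs all hat values are equal and nothing is removed.
* **Families:** overall connectedness (dwPLI), segregation (clustering +
  modularity, both with age interactions), small-world, and integration
  (path length), each with the sex covariate, per band and per outcome —
  32 models on a complete table. Models whose listwise-complete sample
  is smaller than parameters + 2 are skipped with a warning rather than
  aborting the run. No multiple-comparison correction is applied.

## Problem sizes used in validation

The test suite and the acceptance script validate at deliberately modest
scales chosen to exercise every code path: 200-epoch two-channel
simulations for estimator calibration; 8-node graphs (50–100 instances)
for OMST optimality against exhaustive search; ≤6-node graphs
(1000 instances) for metric-oracle equivalence; 60-node
lattice-with-shortcuts graphs (20 seeds, 20 surrogates) for small-world
calibration; n = 400 regressions over 100 seeds and 1000 null
simulations at n = 106 for the statistical stage; and 8-subject
61-channel cohorts for end-to-end determinism.

## Known limitations

* Sensor-space only; no source localisation, no directed measures.
* The dwPLI band aggregation convention (signed mean, then absolute
  value) is one of two defensible readings of the band-level absolute
  value; the alternative is implemented but documented as inflating the
  null.
* The small-world null ensemble (connected rewiring + weight shuffle) is
  one of several in the literature; σ values are comparable only within
  a fixed null choice.
* The OMST early-stop heuristic (3 consecutive J decreases) is an
  optimisation; exhaustive evaluation is available and used wherever
  results are compared against brute force.
* Epoch-quality screening (the manual inspection step of typical
  recordings) is out of scope; an epoch-keep list can be emulated by
  slicing the continuous data before segmentation.
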