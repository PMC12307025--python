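# eegconn

Resting-state EEG functional connectome analysis: from cleaned continuous
multichannel recordings to regression models linking brain-network
organisation to verbal-fluency performance.

Ageing research increasingly asks whether the organisation of spontaneous
brain activity — how *segregated* (locally clustered) and *integrated*
(globally reachable) the functional network is — relates to cognitive
abilities such as word finding. `eegconn` implements that analysis for
sensor-space EEG and ships a synthetic-cohort generator so every stage can
be validated against known ground truth.

## The pipeline

1. **Spectral stage.** Continuous EEG is low-passed at 30 Hz (zero-phase
   Butterworth), segmented into 12 s epochs with 50 % overlap, and turned
   into per-epoch Hann-tapered cross-spectral densities (resolution
   1/12 Hz). The individual alpha peak frequency (IAPF) is estimated from
   smoothed channel spectra, and band edges are anchored to it:
   delta [IAPF−8, IAPF−6), theta [IAPF−6, IAPF−4), alpha [IAPF−4, IAPF+2),
   beta [IAPF+2, 30] Hz. Individualised bands avoid biasing band
   membership against participants whose rhythms have slowed with age.

2. **Connectivity.** The debiased weighted phase lag index (dwPLI)
   between every channel pair: with `I_k` the imaginary cross-spectrum at
   epoch `k`,

   ```
   dwPLI = [ (Σ_k I_k)² − Σ_k I_k² ] / [ (Σ_k |I_k|)² − Σ_k I_k² ]
   ```

   Signed per-bin estimates are averaged across a band's bins and the
   absolute value taken, giving a symmetric weight matrix in [0, 1].
   Because instantaneous mixing (volume conduction) has no imaginary
   cross-spectrum, the estimator ignores it.

3. **OMST thresholding.** Orthogonalized minimum spanning trees: extract
   successive edge-disjoint maximum-weight spanning trees and keep the
   union of the first m* trees, where m* maximises global cost efficiency
   J = GE − Cost (GE: mean inverse shortest-path distance on 1/w edge
   lengths; Cost: selected fraction of total weight). Data driven — no
   arbitrary density choice — and the result is always connected.

4. **Graph metrics.** On max-rescaled weights: Onnela weighted clustering
   coefficient, Newman modularity Q (exact for ≤8 nodes, best-of-restarts
   Louvain above), weighted characteristic path length L, and the
   small-world index σ = (C/C_null)/(L/L_null) against degree-preserving
   rewired surrogates. Metrics undefined on sparse graphs are reported as
   missing, never imputed.

5. **Statistics.** Wilcoxon rank-sum group comparisons with effect size
   r = |Z|/√n; then OLS per band and outcome with z-scaled metric
   predictors, treatment-coded age (younger = reference) and sex
   (female = reference), metric × age interactions, and a single
   leverage-filtering pass (hat diagonal > 2(p+1)/n) before the reported
   refit. Four model families (overall connectedness, segregation,
   small-world, integration) × four bands × two fluency outcomes.

## Worked example

```python
import numpy as np
from eegconn.synthetic import SyntheticSubject, CouplingSpec, \
    generate_subject_signals
from eegconn.spectral import lowpass_filter, segment_epochs, compute_csd, \
    estimate_iapf, derive_bands
from eegconn.connectivity import band_dwpli, summarize_dwpli

subject = SyntheticSubject(
    subject_id="demo", age_group="older", sex="female", iapf_true=9.4,
    couplings=[CouplingSpec("O1", "O2", "alpha", np.pi / 2, 0.8)],
    channel_labels=["O1", "O2", "Pz", "Cz"], duration=300.0)
eeg = generate_subject_signals(subject, seed=7)
csd = compute_csd(segment_epochs(lowpass_filter(eeg)), fmax=30.5)
iapf = estimate_iapf(csd)
print(f"IAPF: {iapf.iapf:.2f} Hz from {iapf.n_channels_contributing} channels")
for band in derive_bands(iapf):
    conn = band_dwpli(csd, band)
    print(f"{band.name:5s} [{band.f_lo:5.2f}, {band.f_hi:5.2f}) Hz  "
          f"mean dwPLI {summarize_dwpli(conn):.3f}  "
          f"O1-O2 {conn.weights[0, 1]:.3f}")
```

prints

```
IAPF: 9.25 Hz from 4 channels
delta [ 1.25,  3.25) Hz  mean dwPLI 0.016  O1-O2 0.020
theta [ 3.25,  5.25) Hz  mean dwPLI 0.012  O1-O2 0.000
alpha [ 5.25, 11.25) Hz  mean dwPLI 0.152  O1-O2 0.890
beta  [11.25, 30.00) Hz  mean dwPLI 0.004  O1-O2 0.009
```

The subject's true alpha peak (9.4 Hz) is recovered to within the spectral
resolution, the band edges shift with it, and the planted π/2-lag alpha
coupling between O1 and O2 (strength 0.8) appears as a strong alpha dwPLI
weight (0.89) while the uncoupled pairs and bands stay near the noise
floor.

## Command line

```sh
eegconn simulate --config cohort.yaml --out sim/ --seed 1
eegconn bands --input sim/sub-y001.csv --out bands.tsv
eegconn connectivity --input sim/sub-y001.csv --out conn/
eegconn threshold --input conn/sub-y001_alpha.csv --out thr/
eegconn metrics --input thr/sub-y001_alpha_thresholded.csv \
    --subject sub-y001 --out metrics.tsv
eegconn stats --metrics metrics.tsv --behaviour sim/behaviour.tsv --out out/
eegconn pipeline --config run.yaml --out run/ --seed 1
```

`pipeline` executes the whole chain on either simulated cohorts or
user-supplied recordings (BrainVision `.vhdr`, EDF, or CSV matrix with a
JSON sidecar) and writes metrics, model summaries, and a manifest that
records every seed, so reruns are byte-identical.

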