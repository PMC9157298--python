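# neonet

Frequency-specific cortical phase-coupling networks in neonatal sleep
EEG: a reusable pipeline for studying how an exposure (here, in-utero
antiepileptic drug treatment) reorganises functional brain networks
between active sleep (AS) and quiet sleep (QS), and how that
reorganisation relates to clinical outcome and cortical
cytoarchitecture.

The package is written for researchers analysing multichannel EEG at
the cortical-network level. It covers the full chain:

1. **Preprocessing** — 0.4–45 Hz prefilter, decimation to 100 Hz,
   average montage, zero-phase Butterworth filtering into four bands
   (low delta 0.4–1.5 Hz, high delta 1.5–4 Hz, theta 4–8 Hz, alpha
   8–13 Hz), and six equidistant 30-s windows per sleep state.
2. **Source modelling** — minimum-norm inverse with dSPM noise
   normalization on a supplied lead field, collapse of sources into
   cortical parcels by fidelity-weighted averaging.
3. **Connectivity** — debiased weighted phase lag index (wPLI) per
   subject/state/band, with a simulation-based edge-fidelity mask that
   removes parcel pairs the sensor array cannot resolve.
4. **Network statistics** — network-based statistics (NBS): edge-wise
   t-maps for sleep, group, and sleep-by-group contrasts, suprathreshold
   component extent, max-component permutation FWE, Cohen's *d*.
5. **Outcomes** — per-subject network dynamics Δ = AS − QS correlated
   (two-tailed Spearman) with composite neurological scores (PCA-derived
   C1/C2) and neurocognitive scores, BH-FDR corrected per family.
6. **Cytoarchitecture** — layer-resolved neuronal-density profiles of
   detected networks tested against the whole cortex (two-sample KS *D*
   with a surrogate-network null).
7. **Synthetic cohorts** — a generator that plants known coupling
   structure (state- and group-dependent, edge-exact), outcome
   correlations, and atlas contrasts, so every stage is testable
   end-to-end without clinical data.

## The statistics at the core

For two band-limited signals with analytic representations
$z_x(t), z_y(t)$, the imaginary cross-spectral terms are
$I_t = \mathrm{Im}\,[z_x(t)\,\bar z_y(t)]$, and the debiased squared
wPLI is

$$\widehat{\mathrm{wPLI}}^2 = \frac{(\sum_t I_t)^2 - \sum_t I_t^2}{(\sum_t |I_t|)^2 - \sum_t I_t^2},$$

which has expectation 0 for independent signals, ignores zero-lag
(volume-conducted) coupling, and reaches 1 for a constant non-trivial
phase lag. NBS thresholds the edge-wise t-map at $t = 2.5$, forms
connected components per sign, and compares each component's extent to
the permutation null of the maximum extent over both signs (5000
permutations by default), giving family-wise-error-controlled network
p-values; effect size is $d = \overline{|t|}/\sqrt{\mathrm{df}}$.

## Worked example

The numbered drivers under `analysis/` run a complete desk-scale study
(46 exposed vs 61 control subjects, 12 parcels, coupling planted in the
high-delta band on a 10-edge interaction network and a disjoint 10-edge
sleep network):

```bash
python analysis/01_simulate_cohort.py   # cohort -> scratch/study
python analysis/02_connectivity.py      # wPLI matrices + fidelity mask
python analysis/03_network_stats.py     # NBS per contrast x band
python analysis/04_outcomes.py          # Delta vs clinical scores
python analysis/05_cytoarchitecture.py  # layer profiles of the networks
python analysis/06_calibration.py       # FWE + recovery summary
```

Driver 03 prints the component table (abridged):

```
   contrast       band direction  extent    p_fwe  cohens_d
 sleep_main high_delta  positive       6 0.000999    0.3072
interaction high_delta  positive       9 0.000999    0.3315
interaction      theta  negative       2 0.070929    0.2688
 group_main  low_delta  negative       1 0.580420    0.2547
```

The planted high-delta interaction network is recovered (9 of its 10
edges, FWE p ≈ 0.001) and the planted sleep network appears as the
high-delta sleep main effect; everything else stays at chance. Driver
04 then finds the planted outcome association — Δ in the detected
network correlates with the fine-motor score (Spearman ρ = 0.25,
p_FDR = 0.034 at n = 107) while the five uncorrelated scores stay
null — and driver 05 shows the planted layer-III density contrast
carrying the smallest surrogate p of the six layers. Driver 06 reports
the empirical family-wise error of the network test on null cohorts
(0.02 at nominal 0.05) and edge-level recovery of the planted network
(mean F1 ≈ 0.65 at a realized Cohen's d ≈ 0.6).

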