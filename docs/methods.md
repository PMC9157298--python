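# Methods

This note documents the models, estimators, and numerical choices
behind the package, what the synthetic cohorts do and do not emulate,
and the problem sizes used in the automated checks.

## Study design being modelled

Two groups of neonates (exposed, n = 46; control, n = 61) recorded
during sleep; each subject contributes one active-sleep (AS) and one
quiet-sleep (QS) segment. Connectivity is analysed in four bands —
low delta 0.4–1.5 Hz, high delta 1.5–4 Hz, theta 4–8 Hz, alpha
8–13 Hz — over a cortical parcellation (58 parcels at full scale,
configurable). Contrasts of interest are the sleep main effect, the
group main effect, and the sleep-by-group interaction; the interaction
networks are carried forward to outcome correlation and
cytoarchitectonic profiling.

## Preprocessing

Recordings are prefiltered 0.4–45 Hz, decimated to 100 Hz with
polyphase anti-aliasing, and re-referenced to the average montage. Band
filtering uses minimum-order Butterworth high-/low-pass pairs designed
for 20 dB stop-band attenuation (1 dB pass-band ripple), applied
forward–backward, so the effective attenuation is ≥ 40 dB and the net
phase response is zero. The transition band is 12.5 % of each cut-off:
wide enough to keep the orders moderate (~22–26), narrow enough that
the four band outputs of a common broadband input are essentially
incoherent (worst-case mean magnitude-squared coherence 0.098) — a
wider 25 % transition leaves adjacent bands sharing their transition
region (coherence up to 0.17), which would leak effects across bands.

Per sleep state, 6 equidistant 30-s windows (3 min total) are selected
across the annotated span of that state; when a state is interrupted,
onsets are spaced on the concatenated within-state timeline and each
window is kept inside one contiguous segment. A subject lacking
6 × 30 s of a state raises an exclusion signal rather than returning
partial data. Artifact handling is by annotation only; no automatic
detector is included.

## Source model

The forward model is an explicit sensors × sources gain matrix with
fixed (surface-normal) orientations; conductor-model construction is
out of scope and the package ships a toy spherical model (sensors just
outside a unit sphere of sources, smooth inverse-square distance
gains). The inverse is the Tikhonov minimum-norm kernel
K = Gᵀ(GGᵀ + λ·s·C)⁻¹ with noise covariance C (identity by default —
no empty-room data exists for synthetic cohorts), s a scale matching
the gain power, and λ = 1/9 by default (the SNR = 3 convention; the
regularization level is otherwise unidentified here). Source estimates
are dSPM-normalized: each row of K is divided by
sqrt((KCKᵀ)ᵢᵢ), the standard deviation of that source under pure
noise, so noise-only input yields unit-variance estimates.

Parcel signals are fidelity-weighted means of member sources. The
weights are defined by simulation: in each of 100 iterations every
parcel is driven by an independent white signal, projected to the
sensors (with 20 dB sensor noise — without noise the round-trip
correlation is scale-invariant and even a vanishing gain column would
score 1), reconstructed, and each source's planted-vs-reconstructed
correlation is averaged and clipped to [0, 1]. This correlation-based
definition is a declared stand-in for the parcellation literature's
weighting, which is not fully specified in the modelled study.

## Debiased wPLI

Cross-spectral terms are formed per sample from the analytic (Hilbert)
signals of the band-filtered data, pooled over the six windows after
trimming 1 s from each window edge against filter/Hilbert transients.
The debiased squared-wPLI estimator
((ΣI)² − ΣI²) / ((Σ|I|)² − ΣI²) is used; negative estimates are kept
(clipping would re-bias the null). When the cross-spectrum is real
everywhere — identical or purely zero-lag signals — the estimate is 0
by convention (numerically: when the summed |imaginary| mass is below
1e−9 of the summed cross-spectral modulus).

Finite-sample behaviour: per-sample Hilbert terms are autocorrelated
over roughly the band's inverse bandwidth, so the null estimate carries
a small positive O(1/T) residual (≈ 0.05 at 15 s, ≈ 0.025 at 30 s,
≈ 0.01 at 60 s in the high-delta band). At the 3-minute epochs the
pipeline pools per subject this is negligible, and it cancels exactly
in all within-design contrasts.

## Edge-fidelity mask

For every parcel pair, 500 iterations (default) plant a perfectly
synchronous quarter-cycle-lagged pair (true wPLI = 1) in the two
parcels and independent band-limited noise of the same variance
elsewhere, project through the forward model, reconstruct, and collapse
back to parcels — implemented via the precomputed parcel-level
resolution matrix, since every step is linear. The pair's fidelity is
its mean recovered wPLI; recovered values of all non-driven pairs are
pooled (one global pool, not per-edge) and edges whose fidelity exceeds
the pool's 99th percentile are retained. Masked edges become absent
(NaN), not zero, downstream. The simulation length is band-adaptive,
max(8 s, 16/bandwidth): with short signals the slow band (0.4–1.5 Hz)
has so few independent cycles that even unsynchronised parcels appear
phase-locked and the mask degenerates to excluding everything. Masks
are computed per band; they differ across bands only through the
band-limited simulation signals.

## Network-based statistics

Edge-wise statistics: paired t on AS − QS for the sleep main effect
(pooling both groups), unpaired pooled-variance t on state-averaged
values for the group main effect, and unpaired t on Δ = AS − QS for
the interaction (algebraically the 2 × 2 mixed-design interaction).
Degenerate-variance edges get t = 0 with a warning. Edges with
|t| > 2.5 form connected components per sign; component extent (edge
count; an intensity variant is available) is tested against the
permutation null of the **maximum component statistic over both
signs**, so one run controls the family-wise error jointly across the
positive and negative networks it reports — with separate per-sign
nulls the realized error rate doubles. Permutations follow the design:
group-label permutations for between-group contrasts, within-subject
sign flips for the sleep contrast; the space is enumerated exhaustively
when smaller than the requested 5000. P-values use the +1 convention,
so p ≥ 1/(n_perm + 1). Effect size per component is Cohen's
d = mean|t|/sqrt(df).

## Outcomes

Composite neurological scores C1/C2 are the first two principal
components of the standardized item table (constant items dropped;
component sign fixed so the largest-magnitude loading is positive).
Network dynamics per subject is Δ = AS − QS averaged over the
network's (unmasked) edges. Spearman correlations are two-tailed with
exact enumeration p-values for n ≤ 10 and the t-approximation above;
ties get average ranks; missing scores are deleted pairwise.
Benjamini–Hochberg FDR is applied within each declared assessment
family (2 neurological × networks; 4 neurocognitive × networks).

## Cytoarchitecture

The atlas is a (region, layer 1–6, neurons/mm³) table keyed by parcel;
each source inherits its parcel's six densities (unweighted by parcel
area — a declared choice). A network's profile per layer is the
density sample of all sources in parcels incident to ≥ 1 network edge.
The observed two-sample KS D against the whole cortex is compared with
1000 surrogate networks drawn as uniformly random parcel sets of the
same size (node-level matching: profiles depend only on incident
parcels), p with the +1 convention, BH-FDR over the network × layer
family. When the network covers nearly the whole cortex the null is
degenerate and a warning is raised.

## Synthetic cohorts

The generator's defaults are the study conditions. Parcel signals are
sums of band-limited Gaussian components (amplitudes 1.0/0.7/0.45/0.3
across the four bands, a coarse 1/f-like decay). Coupling is planted in
one band (high delta by default) on two disjoint compact networks of 10
edges each (cliques over 5 parcels — focal clusters that stay connected
when partially recovered): an interaction network whose coupling is
k(1 ± e) with the sign pattern AS-dominant in the exposed group and
QS-dominant in controls, and a sleep network AS-dominant in both
groups. **Edge-exactness:** each planted edge owns its own band-limited
driver, shared by its two endpoints with a constant quarter-cycle lag
and variance split by node degree, so coupling exists on exactly the
planted edges rather than on every pair inside a component. Coupling
jitter is drawn per subject *and state* (a purely per-subject jitter
cancels in Δ and leaves no biological between-subject variance in the
quantity the interaction tests). Source signals are the parcel signals
copied to member sources, projected through the lead field, plus white
sensor noise at 10 dB SNR.

Calibrated operating point (fixed once): baseline coupling 0.6,
interaction modulation e = 0.3, state-level jitter SD 0.18. At the full
cohort size this realizes an edge-level Cohen's d on Δ of ≈ 0.6 ± 0.15
and edge-recovery F1 ≈ 0.65–0.7 — the "moderate effect" regime the
recovery checks target.

Outcome scores: the per-subject planted Δ is rank-transformed to
normal scores and mixed with independent noise at the Pearson level
2·sin(πρ/6) that yields the requested Spearman ρ (Gaussian copula);
fine-motor (+ρ) and C2 (−ρ) carry the effect, the other four scores
are independent. C1/C2 also drive a synthetic 8-item neurological
table through a two-factor model with unequal blocks (5 vs 3 items) so
PCA can re-derive the composites. The atlas draws region densities
log-normally (CV 0.12) around layer-typical means (2·10⁴–1.1·10⁵
neurons/mm³) and optionally shifts one layer (III by default) by +3
region-level SDs in the interaction-network parcels.

What the generator does **not** emulate: amplitude dynamics
distinguishing AS from QS (trace-alternant discontinuity etc. — only
coupling is state-modulated), EEG artifacts, realistic conductor
geometry, electrode-placement error, volume-conduction asymmetries of
real head anatomy, and missing clinical scores. Passing tests therefore
demonstrate correctness of the estimators and inference machinery
under controlled coupling structure, not robustness to real-data
nuisances.

## Problem sizes in the automated checks

The test-suite and driver runs scale the study down so the whole chain
stays in the minutes range: 12-parcel head models with 16 sensors and
2 × 10 s windows per state for full-cohort recovery runs (500
permutations, 20 seeds); 200 null cohorts at 20 parcels / 15 vs 15 /
500 permutations for the family-wise-error check; 300–1000 surrogates
for cytoarchitectonic tests; fidelity masks at 10–50 iterations on
6–12 parcel models with the oracle cases (identity model, duplicated
gain columns) checked exactly. Production defaults remain the study
values (58 parcels, 6 × 30 s, 5000 permutations, 500 fidelity
iterations, 1000 surrogates).

## Known limitations

* The fidelity-mask procedure is O(edges × iterations) full
  reconstructions; at 58 parcels × 500 iterations it is an overnight
  computation rather than an interactive one.
* The debiased wPLI null has a small positive finite-sample residual at
  short epoch lengths (quantified above).
* The correlation-based fidelity weights and the spherical toy geometry
  are stand-ins; with a real lead field and parcellation both slots
  accept external inputs unchanged.
* Exact Spearman p-values enumerate n! orderings and are enabled only
  for n ≤ 10.
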