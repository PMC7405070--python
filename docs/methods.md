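# Methods

This note records the models, conventions and numerical choices behind
`claustrum_ephys`, in the order data flows through the package.

## Recordings and quality control

A cell's data is a family of 1-s current steps (`SweepSet`): voltage in mV,
current amplitudes in pA, sampling at 50 kHz (other rates are accepted),
with a configurable stimulus window (default onset 0.1 s, duration 1 s).
Voltages are used as recorded; the liquid-junction potential (−11.7 mV for
the K-gluconate internal this workflow targets) is *not* subtracted, to
stay commensurable with the published property tables — a correction can be
applied upstream if desired.

QC follows standard whole-cell criteria: access resistance Ra ≤ 30 MΩ,
Ra/Rm ≤ 20%, resting potential at least as negative as −50 mV, and
accepted APs must overshoot 0 mV. Two rules need conventions the source
tables do not pin down:

* "unstable RMP" is operationalized as baseline drift > 5 mV between the
  first and last sweep (conservative, configurable);
* max-activity features are only computed when the firing-frequency/current
  curve has saturated, operationalized as the AP count being non-increasing
  across the top two amplitudes; otherwise the cell is flagged
  (`no_saturation`) and those features are missing.

## Feature extraction

* **AP detection.** Threshold = first sample of a suprathreshold excursion
  where dV/dt > 10 mV/ms (central differences on the raw trace, no
  pre-smoothing), with a 1-ms debounce so noise cannot retrigger within an
  upstroke. Events whose peak does not overshoot 0 mV are discarded.
* **Waveform.** Amplitude is peak − threshold; half-width is the time
  between the two half-amplitude crossings (linear interpolation between
  samples); max rise is the dV/dt maximum between threshold and peak; max
  decay is the dV/dt minimum between threshold and the AHP trough, capped
  at +10 ms. If the falling half-amplitude crossing is not found before the
  next AP, the half-width is missing.
* **AHP.** Trough search runs from the AP peak to the next AP's threshold
  (or window end); amplitude is trough − threshold (negative), latency is
  measured from the AP *peak* (the reference point is a convention; it is
  recorded here so sensitivity analyses can revisit it). A non-negative
  "AHP" is still reported and flagged as no-AHP by its sign.
* **ADP.** At the *ct* level, after the first AP's AHP: the trace segment
  from the trough onward is low-pass filtered (digital 8th-order Bessel,
  50 Hz cutoff, causal). The post-ADP local minimum is placed where the
  filtered slope first returns to ≥ 0 after a genuine downslope
  (< −10⁻³ mV/ms); an ADP is present when the raw trace has a local maximum
  exceeding both endpoints by a 0.3 mV noise margin. Its integrated
  amplitude is the mean of the positive part of the trace after subtracting
  the straight line joining the trough to the local minimum. Two details
  matter numerically: the filter is applied only to the post-AHP segment
  (state initialized at the trough), because a causal 50-Hz filter's lagged
  response to the spike itself otherwise fabricates a bump; and the
  "downslope" tolerance prevents floating-point wiggle on flat segments
  from counting as repolarization.
* **Trains.** ISIs run between consecutive AP peaks; instantaneous
  frequency is 1000/ISI (Hz). Adaptation = first inter-AP frequency minus
  the mean of the last three inter-AP frequencies ("three APs bound two
  ISIs": the mean is over the frequencies of the last three ISIs, which
  requires ≥ 5 APs; shorter trains leave the statistic missing). The ISI
  ratio is the final/initial frequency ratio. Cv2 statistics average
  2|ISIᵢ₊₁ − ISIᵢ|/(ISIᵢ₊₁ + ISIᵢ) over consecutive ISI pairs; the -1st-AP
  and -1st/2nd-AP variants drop the first one or two ISIs. The SD of the
  first two ISIs is the sample SD (|ISI₂ − ISI₁|/√2). Amplitude ratios use
  absolute AP amplitudes; the 1st/last ratio divides by the mean of the
  last three amplitudes.
* **Initial-adaptation change.** Over consecutive suprathreshold sweeps
  whose first-AP-pair frequency is defined, the change in that frequency
  divided by the current difference; the maximum over pairs is reported
  together with the current level (relative to *ct*) where it occurred. The
  second variant excludes pairs starting at the *ct* sweep and pairs that
  bridge a single-AP trace.
* **Missingness.** A statistic whose train is too short is NaN, never 0.
  Downstream, clustering imputes missing values with the column mean
  (Z-score 0) and the classifier imputes with stage training means, each
  with a warning.

The canonical registry (`data/registry.csv`, version 1.0) fixes every
property's stable key, printed label in the 38- and 63-property sets, unit
and stimulus level. The 38-property set is *not* a subset of the
63-property set: the six ADP/initial-adaptation properties appear only in
the 38-set, while the per-level waveform-ratio and max-activity properties
appear only in the 63-set; 32 properties are shared. Feature CSVs use the
printed labels (historic spelling variants resolve through an alias table);
everything in memory is keyed by the stable keys.

## Clustering

Features are Z-scored per column (sample SD; constant columns become zeros
with a warning). The population stage clusters cells by Pearson correlation
distance (1 − r, not 1 − |r|) between their Z-scored profiles with average
linkage; subcluster stages use Euclidean distance with Ward linkage.
Silhouette widths are computed on the same distance matrix used for the
clustering; singleton clusters get width 0, ties in the arg-max over
k = 2…9 go to the smallest k, and a maximum average width below 0.25 sets a
random-structure flag. t-SNE uses learning rate 200, PCA initialization,
at most 1000 iterations and profile-specific settings (all neurons:
perplexity 25, exaggeration 1; PN: 8/7; IN: 7/7; exaggeration applies
during the standard 250-iteration early phase); LLE is the modified variant
with 14 (PN) or 13 (IN) neighbors and 100 iterations.

## Classification

Each stage is standardize → PCA keeping ≥ 99% of training variance (the
component count is data-driven, not hard-coded) → single-hidden-layer
feedforward network with logistic hidden activation, softmax output and
full-batch L-BFGS (≤ 500 iterations), L2 weight decay 0.001 and 10 hidden
units by default; a grid search (hidden ∈ {2, 5, 10, 20},
decay ∈ {10⁻⁴, 10⁻³, 10⁻²}) by stratified 10-fold CV accuracy is available.
Stage 1 (IN vs PN) and the PN-subtype stage use the 38-property set; the
IN-subtype stage uses the 63-property set and can be trained on a dedicated
interneuron table (mirroring a marker-confirmed IN database). Stages train
on the intersection of their canonical key set with available columns,
warning when short. Accuracy is the pooled fraction correct over stratified
10-fold CV with seed-controlled fold assignment; every class needs ≥ 3
members. Final eight-way probabilities are branch products
(e.g. P(PV) = P(IN)·P(PV | IN)) renormalized to sum to 1; the final label
follows the argmax chain (branch first, then subtype). Models serialize to
a versioned JSON archive (weights, PCA basis, scaler moments, stage feature
keys); loading rejects a registry-version mismatch and reproduces
predictions bit for bit.

## Temperature correction

Q10 = (P₂/P₁)^(10/(T₂−T₁)). For negative-valued properties (AHP
amplitudes, decay rates, thresholds, frequency changes) the ratio is taken
on magnitudes and the sign restored — the power law is undefined across
sign changes and the published coefficients for such properties are
positive. Per-cell coefficients aggregate per property after discarding
values outside [Q1 − 3·IQR, Q3 + 3·IQR]; the *mean* of survivors is used
(median aggregation would be the natural alternative; means follow the
published procedure). Correction divides each value's magnitude by
Q10^((T − 24)/10). Ratiometric properties with extreme coefficients are
corrected like any other by default; a caller can supply a table that
exempts them. The shipped table (`data/q10.csv`) covers all 69 registry
properties at reference 24 °C.

## Synthetic data

The feature sampler draws each property independently per cell:

* PN subtypes (PN1–PN5): center = published median, scale = 1.4826 × MAD;
* IN subtypes (PV, SST, VIP): center = published mean,
  scale = SEM × √n with n = 19, 28, 30;
* the six ADP/initial-adaptation properties have no per-IN-subtype
  statistics and are drawn from the IN population distribution
  (SEM × √152), shared across the three IN subtypes;
* the single outlier VIP interneuron ships as its exact printed
  38-property vector (scale 0).

Strictly positive heavy-tailed properties (Rm, ct, latencies, ISI means and
SDs, Cv2) use a moment-matched log-normal so draws cannot go negative;
everything else is normal, with physical clipping (probabilities to [0, 1],
AP counts ≥ 1, widths > 0). Default cohort sizes are the study conditions:
152 INs in 19 : 28 : 30 proportion plus 174 PNs; PN subtype proportions are
not published, so the default splits the 174 nearly equally
(35/35/35/35/34, configurable). Draws are reproducible bit for bit by seed.

**What independence implies.** No within-subtype covariances are published,
so none are modeled. For the supervised stages this makes separability
somewhat optimistic (acceptance checks are therefore one-sided ≥
comparisons). For the *correlation-distance population clustering* it is
pessimistic in a specific way: real cells share a within-class covariance
signature (a PN is broad-spiked *and* shallow-AHPed *and* adapting at
once), which is exactly what profile correlation measures. Computed from
the printed tables, the PN1 mean Z-profile is nearly orthogonal to every
other subtype profile (max r ≈ 0.2), so under independent sampling the PN1
block attaches to either side of the population dendrogram depending on the
seed, and the k = 2 cut recovers the IN/PN labels in only a minority of
seeds (mean agreement ≈ 0.86 over 20 seeds). The acceptance suite keeps the
strict assertion (and fails it), alongside a companion test showing the
identical pipeline separates a cohort generated from the two *population*
distributions at ≈ 100% — isolating the shortfall to the independence
assumption, not the clustering code. Passing classifier results on these
cohorts demonstrate that the pipeline recovers the published structure
under the published summary statistics; they do not certify accuracy on raw
recordings, which carry correlations, artifacts and QC failures the
generator does not emulate.

The trace simulator is an adaptive leaky integrate-and-fire model: leak
(rest, Rm, τm), spike-triggered adaptation current (increment b, decay τw),
an optional depolarizing after-current producing ADPs and doublets, a
slowly inactivating onset current for delayed firing, and per-spike
threshold jitter for irregular firing. Spikes are rendered as sine-segment
templates parameterized by amplitude (with along-train decrement), upstroke
and downstroke slope scales and AHP depth; integration is forward Euler at
the sampling rate (optional substepping; spike times converge as the step
shrinks). Baseline noise is an Ornstein–Uhlenbeck process (0.15 mV,
τ = 0.5 ms) emulating an acquisition-filtered baseline — white noise at
50 kHz would inject unphysical sample-to-sample dV/dt. Preset parameters
per subtype were chosen once so that extracted anchors (RMP, Rm, ct, AP
counts, ADP presence, latency) land near the published centers; the model
is phenomenological and makes no biophysical claims (no conductances, no
sag/rebound).

## Problem sizes

Tests and the acceptance script run on the study-condition cohorts (326,
174 and ~308 cells for the three classifier stages; 5 seeds averaged in the
script), and simulator-based tests use a handful of cells per preset; the
full test suite and the acceptance script each complete in well under five
minutes on a single CPU.

## Known limitations

* ABF ingestion needs the optional `pyabf` dependency; the CSV sweep
  dialect is the first-class format.
* The sampler's independence assumption is declared, not believed; see
  above for its one measured consequence.
* AHP latency reference (peak vs threshold), the per-level AHP averaging
  convention (first AP only) and the sample-SD reading of "SD of first two
  ISIs" are conventions chosen here and documented so they can be varied.
* Max-activity features require f–I saturation; cells driven with ladders
  that never saturate get missing max-activity features rather than
  unreliable ones.
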