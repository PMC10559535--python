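# Methods

## Sensor model and calibration

A MOS sensing element exposed to a gas at concentration *C* (ppm) settles
at resistivity *Rₛ = A·Cᵅ*. The shipped constants (four Figaro models ×
seven gases) are stored in `src/enose/data/figaro_calibrations.json` as a
versioned resource; entries the manufacturer does not characterize
(propane on TGS-2611E00/TGS-2611C00/TGS-2620, CO on
TGS-2611E00/TGS-2611C00/TGS-2610C00) are modelled as `available=false`
rather than zeros, so accidental use raises a typed error instead of
silently propagating. Fitting is ordinary least squares on (ln C, ln Rₛ)
— the spreadsheet-trendline regression that produced the constants in the
first place — which recovers noiseless power-law data exactly; nonlinear
least squares would weight the data differently without any matching
provenance.

Gases with *α = 0* (air and ethanol on some models) make the law
non-invertible; the inversion raises `NonInvertibleError` and the
featurizer maps it to a 0.0 sentinel.

### Voltage to resistance

How a measured output voltage becomes *Rₛ* is not part of the published
constants, so the package adopts the standard Figaro test circuit: a load
resistor R_L in series with the element across a supply V_cc, read over
R_L, giving R = R_L·(V_cc − v)/v. Defaults V_cc = 5 V, R_L = 10 kΩ are the
conventional test-circuit values. Because the calibration tables are on a
dimensionless (normalized) resistivity scale rather than in ohms, the
ohmic value is divided by a configurable `reference_resistance` (default
1 kΩ) before inversion. All three constants live in `DividerCircuit` and
are serialized with any run metadata, since the ppm features depend on
them.

## Curve preprocessing and featurization

Curves are 15000 samples over a 120 s window. The sampling rate is fixed
at 125 Hz = 15000/120; time *t* maps to index min(round(t·125), N−1), so
t = 120 s addresses the final sample. Smoothing is a 5-sample median
filter (kills single-sample spikes) followed by a 25-sample centered
moving average, both with edge reflection; the baseline offset is the mean
of the first second of the smoothed trace (the pre-injection clean-air
level) and is subtracted throughout. These are deliberately minimal,
standard choices and fully configurable via `FilterConfig`.

All downstream quantities — characteristic points, slopes, differences,
ppm estimates, statistics — are computed on the corrected trace. V_B is
its global maximum with ties broken toward the earliest sample.

Numerical policies:

- a slope whose time base is below 1 ns yields 0 with a warning, never an
  infinity;
- quantiles use the linear-interpolation rule; skewness is the adjusted
  Fisher–Pearson coefficient and is defined as 0 for a (near-)constant
  trace; CV = std/mean is 0 when |mean| < 1e-12;
- the mode of a continuous voltage trace is the center of the most
  populated 0.01 V histogram bin (lowest bin on ties);
- ppm inversions are evaluated in log space and clipped to [0, 10⁶] ppm:
  a million ppm is pure gas, and the clip also keeps near-zero exponents
  (|α| ~ 10⁻³, whose inverse power explodes numerically) finite;
- if V_B falls outside the divider's valid (0, V_cc) range — e.g. a flat
  trace collapses to 0 after offset removal — all seven ppm features take
  the 0.0 sentinel.

The 32-entry feature order is frozen in `FEATURE_NAMES` (5 points, 7
slopes, 4 differences, 7 ppm values in gas-tuple order, 8 statistics,
identifier) so trained models are portable. The identifier is
model_ordinal·100 + socket, injective over the 4×32 grid, and enters the
network through the same normalization as every other feature.

## Dataset construction

`enumerate_cohort` lays out the redundancy design
(patients × containers × acquisitions files, 32 curves each);
`build_instances` featurizes every curve into one labeled instance
(0 = HBP, 1 = CaP). The patient-level split is seeded uniform sampling
stratified by class — how the original cohort was divided is not
documented, and random stratified assignment is the neutral choice; the
seed is carried in `DatasetSplit`. Disjointness of the two patient sets is
enforced by the type's invariant, not just tested.

## Network

Architecture 32 → z-score normalization → dense 64 → 32 → 16 (ReLU) → 2
(softmax). The middle hidden width is not fully pinned down by the design
description ("from 64 to 16"); geometric halving 64→32→16 is used and is
configurable. Normalization statistics are per-feature mean and standard
deviation of the *training* matrix only (features with deviation < 1e-8
get scale 1 to avoid division by zero); they are never updated at
inference.

The optimizer is mini-batch SGD with momentum 0.9 and per-update
inverse-time decay lr_t = lr₀/(1 + decay·t) with lr₀ = 0.001 and
decay = 1e-7 — the legacy convention in the framework family the
hyperparameters come from. Loss is categorical cross-entropy with
per-sample weights class_weights[label]; the gradient of the weighted loss
at the softmax is w·(p − y), averaged over the batch. Epoch-level
shuffling is seeded (init and shuffling use decoupled streams derived from
the one seed); the batch remainder is kept as a short final batch. A
non-finite loss aborts with a diagnostic. With a fixed seed, two runs are
bitwise identical on the same platform.

The trainer is a self-contained numpy implementation: the model is small
(≈4.6k dense parameters) and a transparent, fully deterministic trainer is
worth more here than a framework dependency. Serialization is a single
JSON document (config, weights, normalization statistics, history).

## Evaluation

Confusion counts use the frozen orientation rows = true (0 top), columns =
predicted (0 left); the orientation string is embedded in every report so
the false-negative cell (row 1, column 0) is unambiguous. Zero-denominator
precision/recall report 0 with a warning. Accuracy equals the
support-weighted mean of the recalls to machine precision, which the tests
assert. `patient_vote` (majority vote per patient, ties to the cancer
class to favor sensitivity) is an optional aggregation the instance-level
method does not require.

Both classes' recalls are always reported: the class weighting boosts
recall of the weighted (cancer) class at the expense of the other, and
printing both avoids any ambiguity about which one a headline number
refers to.

## Synthetic cohort

The generator emulates the acquisition design, not sensor physics. Each
curve is a baseline plus a double-exponential pulse
a·(e^(−(t−t₀)/τ_d) − e^(−(t−t₀)/τ_r)), normalized to peak at amplitude
*a* — the simplest shape with the observed rise-peak-decay structure —
plus white Gaussian sample noise. Class membership shifts the amplitude
mean; each patient carries an additive amplitude offset shared across all
of that patient's files, which is exactly what makes the patient-disjoint
split a meaningful leakage test. Defaults: baseline 0.5 V, class
amplitudes 1.0/2.0 V, amplitude jitter 0.05 V, patient effect 0.1 V, noise
0.02 V, peak at 80 ± 5 s, τ_r = 12 s, τ_d = 45 s, 120 s at 125 Hz. The
class contrast is deliberately large (~10σ): the generator's job is to
verify the pipeline end to end, so the expected outcome on it is
near-perfect separation.

What the generator does **not** emulate — cross-sensor correlation
structure, session-to-session drift, humidity/temperature confounds, and
the true biological effect size — bounds what passing tests mean: they
demonstrate the pipeline's correctness and its leakage hygiene, not
clinical performance. Acquisitions are drawn independently given the
patient effect; real replicate drift is unknown and left out.

## Test problem sizes

The suite runs a desk-scale cohort (4 patients per class, 2 containers, 2
acquisitions → 32 files, 1024 instances) and trains for 200 epochs; the
class-weighting comparison uses an overlapping-class variant (amplitude
means 1.0 vs 1.12 V against 0.15 V patient spread) where the unweighted
network is genuinely imperfect, so the weighted-vs-unweighted recall
ordering is informative. These sizes keep the whole suite fast while
exercising every stage at full curve resolution.

## Known limitations

- The ppm features inherit the arbitrary divider constants; they are
  consistent within a dataset but not absolutely calibrated
  concentrations.
- Which measured quantity (peak vs steady state) the original ppm
  estimates used is undocumented; V_B is chosen as the most informative
  point.
- Whether the published statistics were computed before or after
  filtering is undocumented; this package computes them after, matching
  the corrected-curve illustration of the featurization.
- Single hold-out splitting only; cross-validation is an easy extension
  but not provided.
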