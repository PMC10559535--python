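# enose

A tested re-implementation of a metal-oxide-semiconductor (MOS)
electronic-nose screening pipeline for distinguishing prostate cancer (CaP)
from benign prostatic hyperplasia (HBP) from the volatile profile of urine
headspace. It is aimed at researchers working with multi-sensor MOS arrays
(such as the 32-socket MOOSY-32 board) who need a reproducible path from
raw voltage curves to a class-weighted neural classifier — and at anyone
who wants to study the method itself, since a synthetic cohort generator
stands in for the clinical samples.

## The method

**Sensor calibration.** Each Figaro sensor's resistivity responds to a gas
concentration *C* (ppm) by a power law

&nbsp;&nbsp;&nbsp;&nbsp;*Rₛ = A · Cᵅ*

with per-(sensor model, gas) constants *A*, *α* obtained by log-log
regression of the manufacturer's sensitivity curves. The package ships
those constants for the four sensor models TGS-2611E00, TGS-2611C00,
TGS-2610C00 and TGS-2620 across seven gases (methane, isobutane, hydrogen,
propane, ethanol, air, CO), and implements the forward model, its inversion
to ppm, and refitting.

**Featurization.** Each acquisition holds 32 voltage curves of 15000
samples (120 s at 125 Hz). After median/moving-average smoothing and
baseline subtraction, five characteristic points are read — V_A (t = 40 s),
V_D (60 s), V_B = V_max, V_E (100 s), V_C (120 s) — and expanded into a
32-parameter instance: the 5 point voltages, 7 pairwise slopes (e.g.
slope_AB = (V_B − V_A)/(t_B − t_A)), 4 differences from the peak (e.g.
dif_BA = V_B − V_A), 7 per-gas ppm estimates from inverting the power law
at V_B, 8 distribution statistics (75th percentile, standard deviation,
mode, mean, median, IQR, coefficient of variation, skewness), and a
sensor/socket identifier code.

**Redundancy design.** 4 urine containers per patient × 5 acquisitions per
container × 32 sensors = 640 instances per patient; 40 patients give 800
acquisition files and 25,600 instances. Train/test splitting is
patient-disjoint (10 CaP + 10 HBP patients per side → 12,800 training
instances), so no patient's replicates leak across the boundary.

**Classifier.** A feed-forward network 32 → normalization → 64 → 32 → 16 →
2 (softmax), ReLU hidden activations, Glorot-uniform weights, zero biases;
SGD with learning rate 0.001, momentum 0.9, per-update decay 1e-7,
categorical cross-entropy, batch size 32, 1280 epochs. Class weights
{0: 1.0, 1: 32.0} multiply the loss of cancer-class samples, trading
precision for recall on the class where a miss is costliest. The trainer
is a compact, fully seeded numpy implementation.

**Evaluation.** A 2×2 confusion matrix with frozen orientation (rows =
true label 0/1 top-down, columns = predicted 0/1 left-right), accuracy and
per-class precision/recall/F1, plus an optional per-patient majority vote.

## Worked example

`python examples/train_and_evaluate.py` simulates a separable desk-scale
cohort (8 patients, 2 containers, 2 acquisitions), trains the
class-weighted network and evaluates on held-out patients:

```
1024 instances from 8 patients
train (512, 32), test (512, 32), patient-disjoint
final training loss 0.0004, accuracy 1.000
confusion matrix (rows true 0/1, cols predicted 0/1): ((256, 0), (0, 256))
accuracy 1.000; recall per class (1.0, 1.0)
```

All 512 held-out instances land on the diagonal: every benign and every
cancer instance of the unseen patients is classified correctly — expected
here, because the synthetic classes are built ~10σ apart. The other
examples (`calibrate_sensors.py`, `featurize_curve.py`,
`simulate_cohort.py`) each demonstrate one stage in isolation.

A thin CLI mirrors the library: `enose simulate`, `enose build-dataset`,
`enose train`, `enose evaluate`.

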