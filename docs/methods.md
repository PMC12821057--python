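# Methods

This note documents the models and procedures implemented in `elvmass`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## The estimation problem

Left-ventricular mass (LVM, grams) is a prognostic marker normally measured
by imaging (CT, MR, echo). The package implements an estimator that predicts
LVM from a routine 12-lead ECG plus readily available scalars: demographics
(age, sex, height, weight) and automatically reported ECG parameters (QRS
duration; P, R and T axes). Left-ventricular hypertrophy (LVH) is then a
threshold decision on the predicted mass indexed to body surface area.

## Synthetic cohort generator

Clinical ECG–CT pairs are not distributable, so the package ships a seeded
generator that produces cohorts with a *known* ground truth, making every
downstream stage testable against closed forms.

**Covariates.** Sex ~ Bernoulli(0.5); height is sex-conditional normal
(male 172 ± 7 cm, female 159 ± 7 cm); weight = −50 + 0.7·height + N(0, 8) kg
(floored at 35 kg); age ~ N(60, 12) clipped to [20, 90] years. True mass is
linear in the covariates:

    LVM = γ0 + γh·height + γw·weight + γsex·[male] + ε,   ε ~ N(0, σ_LVM)

with defaults γ0 = −135 g, γh = 1.2 g/cm, γw = 0.8 g/kg, γsex = 25 g,
σ_LVM = 15 g. These produce cohort-level correlations corr(LVM, height) ≈
0.8, corr(LVM, weight) ≈ 0.65 at n = 1000 — the moderate-to-strong positive
associations a real adult cohort shows — and mean LVM ≈ 150 g (male) /
105 g (female).

**Waveforms.** Each beat is a sum of five Gaussians (P, Q, R, S, T), in the
spirit of the classic ECGSYN generator, projected on the 12 leads by a fixed
amplitude matrix with physiologic polarity (aVR inverted, V1 rS, V4–V6 tall
R). Records are 10 s at 500 Hz; the beat template is tiled at a heart rate
drawn uniformly from [55, 95] bpm (≥ 9 beats per record), plus optional
baseline drift (0.05 mV at 0.25 Hz) and white noise (0.01 mV RMS).
Fiducial landmarks are defined as the ±3σ boundaries of the component waves
and exported per beat, so delineation and segment masks can be scored
against truth.

**LVM coupling.** With fractional excess e = (LVM − LVMref)/LVMref
(LVMref = 130 g): R amplitudes scale by (1 + 0.4·e), the Q/R/S Gaussian
widths by (1 + 0.2·e) (so QRS duration lengthens with mass), and the T-wave
amplitude shifts by −0.05·e mV (the ST-T strain-like effect). The reported
QRS duration is computed from the morphology the row's LVM induces, plus
4 ms measurement noise; the R axis carries a weak negative association
(−25°·e + N(0, 20°)).

**Voltage variability.** On top of the coupling, the whole amplitude matrix
of each patient is scaled by exp(N(0, 0.15)). This models inter-individual
attenuation (chest geometry, electrode placement) that is unrelated to mass
and is the reason ECG voltage is a noisy LVM readout in practice. It is the
condition under which adding demographics to the waveform materially
improves prediction, as observed clinically; with the term set to zero the
waveform encodes the realized LVM almost noiselessly and a waveform-only
model suffices. Tests that need a deterministic amplitude→LVM map set it
to 0 explicitly.

**Reproducibility contract.** A single cohort seed spawns one child RNG
stream per row (`numpy` SeedSequence), so row i is bit-identical for any
cohort size — cohorts are extensible without perturbing earlier rows.

**What the generator does not emulate.** Pathological morphologies (bundle
branch block, atrial fibrillation, pacing — these are exclusion categories,
not modelling targets), beat-to-beat variability, respiratory modulation,
electrode artefacts, and any nonlinear LVM–morphology relationship. Passing
the recovery tests therefore shows the pipeline can extract a planted
signal under realistic noise, not that the architecture attains any
particular clinical accuracy.

## Ingestion rules

Records pair with a CT-derived mass only if the ECG falls within a
configurable window of the CT (default 183 days ≈ 6 calendar months). When
several ECGs match one mass measurement, the closest in time is kept (tie →
earlier ECG); the rest are logged as redundant. Rows with bundle branch
block, paced rhythm, atrial fibrillation, or unknown sex are excluded.
Missing numeric scalars are imputed with column medians computed on the
training partition only, and the frozen medians are reused for held-out
rows — a leakage-free reading of median imputation, verified by a poisoning
test. CT mass is volume × 1.05 g/mL.

## Preprocessing

* **Filter:** 3rd-order Butterworth band-pass 0.5–40 Hz, applied zero-phase
  (forward-backward), per lead. The band preserves ST-T morphology while
  removing baseline wander and high-frequency noise.
* **R peaks:** Pan–Tompkins-style energy detector on lead II (V5 fallback if
  II is flat): 5–15 Hz band-pass, derivative, squaring, 150 ms integration,
  peak picking with a 200 ms refractory period, refinement to the local
  extremum. On noiseless synthetic records detections land within 10 ms of
  truth.
* **Single beat:** the *middle* eligible peak (index ⌊n/2⌋, 0-based, among
  peaks whose full window fits) with a −250 ms … +450 ms window around R
  (350 samples at 500 Hz, R at sample 125) — wide enough to hold P, QRS and
  T at ≤ 100 bpm. The same sample range is sliced from all 12 leads;
  synchrony is asserted with index-valued dummy signals.
* **Random crop:** length uniform in [min, max] s, start uniform over the
  feasible range, one draw applied to all leads.
* **Lead groups:** `electrical` = {limb: I, II, III, aVR, aVL, aVF},
  {precordial: V1–V6}; `anatomical` = {LAD: V1–V4}, {LCx: I, aVL, V5, V6},
  {RCA: II, III, aVF}, {LM: aVR}; `none` = one 12-lead group. Groupings are
  validated as partitions.
* **Delineation:** slope-threshold rules on lead II — a boundary is where
  |dx/dt| stays below 2 % of the local wave's peak slope for ≥ 10 ms.
  Slope thresholds are insensitive to the residual baseline offset the
  band-pass leaves on a beat train (an amplitude-threshold rule is not,
  which is why the derivative criterion was chosen). On noiseless synthetic
  beats all four landmarks land within 20 ms of the generator's truth. On
  failure the segment is flagged and deterministic fixed offsets are used
  (P onset −200 ms, QRS onset −50 ms, QRS offset +50 ms, T offset +400 ms
  relative to R), so saliency partitions always exist. Simulator ground
  truth overrides detection when supplied.

All sample windows are half-open `[start, end)`, 0-based.

## Model

Each lead group is encoded by its own temporal convolutional network:
`n_blocks` residual blocks, two dilated 1-D convolutions per block
(kernel k, dilation base^i, ReLU, dropout), with a 1×1 skip when channel
counts change. The receptive field R = 1 + Σᵢ 2(k−1)·baseᶦ must cover the
input length; this is enforced at construction (defaults: 5 blocks, k = 7,
base 2 → R = 373 ≥ 350). Convolutions pad symmetrically (acausal): the beat
is a complete window, not a stream; a `causal` switch exists. Block output
is global-average-pooled and linearly embedded; group embeddings are
concatenated and projected; scalar branches (demographics, ECG parameters)
are z-scored with training-fold statistics and passed through small MLPs;
the fused vector feeds an MLP regressor with one linear output (grams).
Training minimizes MAE with Adam.

Input sets: `ecg_only`, `ecg_demo`, `ecg_demo_params` (the full model),
`ecg_params`. Sex-specific variants filter rows to one sex and drop the
then-constant sex indicator.

The layers, backpropagation and Adam are implemented in numpy inside the
package (`elvmass._nn`); gradients — including the input gradients that
saliency consumes — are verified against central finite differences to
< 10⁻³ relative error (observed ≈ 10⁻⁷).

Two width presets ship: the default (32 channels, embedding 64, projection
128, regressor 128-64-1) and `small_model_spec()` (16 channels, embedding
32, projection 64, regressor 64-32-1 — same depth, same receptive field).
The shipped experiments and the acceptance script use the small preset with
30 epochs, batch 64, learning rate 10⁻³, patience 8 — the problem size at
which the recovery experiments below were designed to run on a single CPU.

## Cross-validation and metrics

Indices are sorted by LVM (stable ties) and dealt systematically: sorted
position j → fold j mod 5, giving every fold the same mass distribution
(per-fold means agree within 5 %). For each test fold the validation set is
every 10th LVM-sorted sample of the training portion. At n = 1459 this
yields test folds of 292/291, validation 116 ± 1 and training 1051 ± 1.
Model selection keeps the epoch with minimum validation MAE (early stopping
after `patience` non-improving epochs). Reported errors are MAE (g) and
MAPE (%); fold aggregation is mean ± SD over test folds.

LVH: indexed LVM = mass / BSA with Mosteller BSA √(height·weight/3600)
(Du Bois available; the two differ < 3 % over the adult range), thresholds
*strictly* above 72 g/m² (men) / 55 g/m² (women). Classification metrics
are computed from predicted-mass labels; the c-statistic is a rank-based
AUROC (midranks, ties 0.5) using predicted indexed LVM as the continuous
score — hard-label AUROC would be degenerate. It equals brute-force
concordant-pair counting (tested on random instances up to n = 200). Note
that with pooled sexes a perfect predictor does not reach c = 1: the score
is one-dimensional but the threshold is sex-specific.

An echo→CT linear recalibration hook (`slope·LVM + intercept`) exists for
echo-sourced cohorts; the coefficients must be supplied in configuration —
no silent identity default.

## Saliency

For one beat, saliency is |∂ŷ/∂x[lead, t]| from a backward pass of the
prediction; scalar-branch gradients are excluded (the table attributes
importance to the ECG alone). The window is partitioned into PR = [P onset,
QRS onset), QRS = [QRS onset, QRS offset), ST-T = [QRS offset, T offset),
TP = remainder; cells are (segment × limb/precordial). Each map's 8 cells
are normalized to 100 % first, then averaged across maps (normalize-then-
average, matching percentage-of-sample averaging); all-zero maps are
excluded with a warning. Strata are LVM tertiles by default, 5 samples per
stratum, seeded. Importance tables always sum to 100 ± 10⁻⁶ and are
invariant to positive rescaling of the model output.

As a directional check, when the generator confines the LVM effect to QRS
morphology (no ST-T shift, no voltage variability), a trained waveform-only
model concentrates its importance in the QRS cells. This holds only for a
*converged* model (the directional runs use batch 32, learning rate
2·10⁻³, 60 epochs on n = 400, reaching test MAE ≈ 1 g): gradient saliency
measures local sensitivity, and an undertrained network is roughly
uniformly sensitive across the window, so the wide ST-T region leads by
area alone. Convergence is what concentrates sensitivity on the
informative samples.

## Numerical choices and degenerate inputs

* Stable sorts and explicit tie-breaks everywhere (fold assignment: original
  index; ECG matching: earlier record).
* The finite-difference gradient check exploits that the ReLU network is
  piecewise linear: central differences are exact wherever the ±h interval
  contains no activation kink, and a kink is detected by re-estimating at
  h/2 (any disagreement beyond roundoff, 3·10⁻¹²). Coordinates that
  straddle a kink are excluded — a finite difference is not a derivative
  oracle at a non-smooth point.
* All stochastic components (generator, initialization, dropout, batch
  shuffling, cropping, stratified sampling) take explicit seeds; evaluation
  mode is bit-reproducible.
* Standardization guards zero-variance features (SD < 10⁻¹² → 1).
* MAPE requires strictly positive truth; the MAE subgradient at 0 is 0.
* Empty partitions (e.g. sex filtering), all-missing imputation columns,
  single-class c-statistics, and all-zero saliency maps are rejected or
  reported with explicit reasons rather than silently propagated.

## Known limitations

* The numpy network trains on one CPU; it is adequate for the shipped
  cohort sizes (n ≈ 10³, 350-sample beats), not for full-length 5000-sample
  inputs at scale. Full-length and random-crop representations are
  implemented and tested at the preprocessing level, but the shipped
  training experiments use the single-beat representation.
* Hyperparameters are package defaults chosen for the synthetic recovery
  task; they are not tuned values from any clinical dataset, and synthetic
  performance numbers say nothing about clinical accuracy.
* The delineator is designed for the generator's morphology family; on real
  ECGs a validated delineator should replace it (the fallback and the
  truth-override hooks make that swap contained).
* No vendor XML parsing; waveform I/O is CSV/HDF5 with a documented layout.
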