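# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `hncnet`, in enough detail to audit or re-derive
every constant in the code.

## Pre-processing

A (volume, mask) pair is turned into the CNN input by, in order: in-plane
resampling to 1×1 mm (image linear, mask nearest-neighbour; the slice axis
is left untouched and the manifest records this), masking the scan to the
GTV, selecting the slice with the largest GTV area (ties broken toward the
lowest index), cropping 180×180 pixels about the rounded (half-up) 2D
centroid of that slice's mask with the half-open convention
`[c−90, c+90)`, Hounsfield windowing, Gaussian smoothing, and a final clip
to [0, 1].

Windowing maps `[level − width/2, level + width/2]` linearly onto [0, 1]
after clipping. Three window settings are first-class: 0/1000 (wide),
50/350 (soft tissue) and 125/350 (the default; it covers the
soft-tissue-to-faint-enhancement band where tumor texture lives).
Windowing and intensity normalization are a single linear map, and
smoothing is applied *after* it: Gaussian filtering commutes with affine
maps, so the only order-sensitive step is the final clip, which is
explicit. The smoothing sigma is configurable with default 1.0 px (mild
denoising at 1 mm spacing). Voxels outside the GTV are filled with the
lower window bound so the background maps exactly to 0; internally the
pipeline fills with the HU floor (−1024), which windows to the same 0 for
every window considered. 8-bit PNG export quantizes `v → round(v·255)`
(round half up) and is exactly invertible to within 0.5/255.

## Phantom cohorts

The generator emulates the *structure* of multi-center head-and-neck
cohorts, not their anatomy. Each phantom volume (default 32×160×160 voxels
at 3×1×1 mm) is soft-tissue noise (40 ± 20 HU) with a fixed air cavity
(−1000 HU) and a bone bar (+700 HU) as landmarks, plus one ellipsoidal
tumor of mean 100 HU whose internal texture is i.i.d. Gaussian with
standard deviation equal to the patient's *texture heterogeneity* — the
latent prognostic variable.

Per cohort, heterogeneity is drawn log-normally (median 30 HU, log-sd
0.45). With `z` its standardized value, the primary (DM) event probability
is `σ(b0 + effect_size·z)`; `b0` is solved numerically (Brent) so the
*sample mean* of these probabilities equals the requested prevalence,
making prevalence a testable target. Secondary outcomes reuse `z` with
damped effects (0.7× for LRF, 0.5× for death; death probabilities are
scaled by 1.6, capped at 0.95, so mortality exceeds DM incidence). Event
times are uniform inside the time frame. Event-free patients are censored
short of the frame with the configured probability (follow-up uniform in
[0.2, 1)×frame), otherwise followed for 1–2 frames.

Tumor in-plane radius is `15 + c·z + 1.5·ε` mm (clipped to [7, 24]), with
`c = size_risk_coupling` (default 2 mm/SD; 0 confines the signal to
texture — used by the windowing test, where a window that misses the tumor
HU band must see only an uninformative silhouette). Clinical covariates
depend on the latent log-odds `η = b0 + effect·z` with documented
coefficients: age `62 + 4η ± 9`, HPV positivity `σ(0.6 − 0.5η)`, N stage
ordinal in `η` (cuts 0, 1.2, 2.2; unit noise), T stage from radius (cuts
11/15/19 mm), overall stage and treatment derived from T/N. Institutions
are sampled from five synthetic centers with weights 0.21/0.23/0.09/0.15/
0.32, mirroring realistic center imbalance. GTV area/volume are the
analytic ellipse/ellipsoid values.

What passing tests on phantoms do **not** show: robustness to scanner
effects, anatomy, delineation variability, or concept shift between
centers — the phantoms are exchangeable across institutions by
construction, so cross-center generalization is trivially easier than in
real cohorts.

## Labelling and splits

For an outcome with time frame `T` (730 d for DM/LRF, 1460 d for OS): an
event at `t ≤ T` is positive; a patient observed event-free through `T`
(including events recorded after `T`) is negative; an event-free patient
with follow-up `< T` is excluded — their status is unknown. Cohort split
assigns whole institutions to train/validation/test; stratified k-fold
(scikit-learn `StratifiedKFold`, shuffled, seeded) keeps per-fold positive
counts within one of exact proportionality and never assigns excluded
records.

Clinical encoding is fitted on training records only: one-hot blocks per
categorical variable with an explicit `unknown` level (missingness is
informative and common for HPV), T/N stages collapsed to main categories
(T4a/T4b → T4), M stage dropped (the cohorts exclude metastatic
presentation), age divided by 100, GTV volume and area binned by training
quartiles. The exact feature list for the 11-input ANN is configurable;
the default is the full encoded vector, and nothing asserts a specific
historical feature set.

## Models

The architecture lives in `src/hncnet/configs/default_cnn.yaml`, and the
builder refuses any configuration whose trunk does not map 180×180×1 to
4×4×32 (512 flat features). The shipped configuration — conv 3×3 stride 1
(valid) with 8/16/32 filters, max-pools 3/3/4, FC 512→128→96→16→1 — counts
exactly 85,505 parameters (conv 5,888 + FC 79,617). Each conv block
applies conv → max-pool → leaky ReLU; pooling and a monotone activation
commute, so the order is a convention, not a modelling choice. Dropout
(p = 0.25) follows every FC layer except the last; applying it before the
sigmoid would randomly scale the logit at train time for no benefit.

Weights use fan-in-scaled uniform initialization
`U(±√(6/fan_in))` (named `he_uniform_fan_in` in the config so checkpoints
are portable across versions); biases start at zero. Fusion concatenates
the clinical vector at the input of one FC layer without a projection, so
the parameter delta is exactly `clinical_dim × fan_out` of that layer —
a closed form the tests assert. The ANN is 11→8→4→1 with the same
activations; the logistic baseline is one affine layer + sigmoid trained
with the same optimizer.

The layer engine is NumPy with numba-jitted kernels for stride-1
convolution and max-pooling (cache-blocked row loops; an im2col + GEMM
path remains as the reference and handles strided convolutions), verified
against each other and against finite differences. The first layer skips
its input-gradient pass. Forward/backward buffers are reused across
batches to avoid large allocations; all tensors are float32.

## Training

SGD with classical momentum (`v ← μv + g + λw`, `w ← w − ηv`); L2 decay
applies to weight matrices only, never biases. Per epoch: shuffled
mini-batches of 64 with augmentation applied to training images only
(flip h/v at p = 0.5 → rot90 uniform over {0,1,2,3} → rotation uniform in
[0°, 20°], bilinear, zero fill — a signed range is a config toggle —
→ per-axis integer shifts uniform in ±3% of the width). At epoch end,
training and validation AUC are computed in a clean pass (no augmentation,
dropout off), which makes the early-stopping trigger (train AUC > 0.95)
well-defined and comparable to validation AUC. Probabilities are clamped
to [1e−7, 1−1e−7] inside the loss. All randomness (shuffling,
augmentation, dropout) derives from the training seed via three spawned
substreams; experiment-level stage seeds derive from a master seed through
named `SeedSequence` streams, so any stage can be rerun in isolation.

Checkpoints (weight lists) are retained for every epoch by default — at
85,505 float32 parameters this is ~0.33 MB/epoch — with a configurable
stride for larger models; the best-validation epoch is always retained.

## Selection and evaluation

The overfitting gap is `train AUC − val AUC` *without* absolute value:
epochs where validation exceeds training are always eligible (the
criterion exists to veto overfit epochs; underfitting is handled by
maximizing validation AUC among the eligible). The threshold starts at
0.05 and escalates by 0.01 (configurable) until an epoch qualifies; the
final threshold is reported. Comparisons use a 1e−9 tolerance so float
escalation cannot exclude an epoch whose gap equals the threshold. Ties
everywhere break toward the earliest epoch/first candidate. Alternative
modes (best validation AUC, lowest validation loss) are implemented for
criterion comparisons.

ROC AUC is the Mann–Whitney statistic (ties half-weighted), delegated to
scikit-learn and cross-checked against exhaustive pair counting. The
bootstrap CI is the percentile interval (2.5/97.5) over 1000 resamples of
(label, score) pairs — the minimal reading of "bootstrap CI", and exactly
testable; single-class resamples are redrawn up to 20 times, then skipped
with a warning. Coverage at population AUC 0.8, n = 200, measures ~0.97.
Kruskal–Wallis (tie-corrected, chi-squared p) compares per-repetition
AUC distributions in the windowing ablation; repetitions share seeds
across window arms, so arms are paired and a duplicated window reproduces
bit-identically (H = 0).

## Problem sizes and tolerances in the tests

The end-to-end recovery test uses 300 phantoms, 150 epochs, batch 64 —
large enough that a strong effect (effect size 2) clears held-out AUC 0.75
and a null cohort stays within [0.4, 0.6], small enough to run on one CPU
core in minutes. Unit and property tests use miniature cohorts (10–100
patients, 2–20 epochs) chosen so every split retains both classes.
Monte-Carlo assertions carry explicit slacks (e.g. ±0.1 on a null
point-biserial correlation at n = 400; ±3% on bootstrap coverage over 500
replicates; exact binomial 99% bounds on the calibrated prevalence at
n = 1000). Gradient checks compare analytic and central finite differences
at 1e−3 step in float32.

## Known limitations

Single-slice 2D input (the largest-GTV slice) ignores the rest of the
tumor; through-plane resampling is not performed; phantoms carry no
scanner or anatomy realism; survival modelling of censored time-to-event
data is out of scope (censoring is handled by exclusion); and the fusion
model does not learn feature interactions beyond what concatenation at one
FC layer allows.
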