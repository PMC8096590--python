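# Methods

## The model

KecNet is a small 1-D convolutional network for 5-class AAMI heartbeat
classification (N normal, S supraventricular ectopic, V ventricular
ectopic, F fusion, Q unknown) of 10-second single-lead ECG segments
(M = 3600 samples at 360 Hz). Two pieces of domain structure replace
free-form capacity:

1. **A learnable windowed-sinc bandpass filter bank as the first layer.**
   Each of the F = 32 filters is the ideal bandpass impulse response

       g[n] = 2 f̂_H sinc(2π f̂_H n) − 2 f̂_L sinc(2π f̂_L n),

   evaluated at symmetric integer tap offsets n ∈ [−(L−1)/2, (L−1)/2]
   with L = 251 and normalized frequencies f̂ = f / fs, multiplied by a
   Hamming taper 0.54 − 0.46 cos(2πn/(L−1)) to suppress spectral leakage
   (Hanning and Kaiser tapers are supported and give equivalent trained
   models). Only the two cutoff frequencies per filter are trained — 2F =
   64 values regardless of L, versus F·L = 8032 free taps for a standard
   layer of the same shape, a (1 − 2/L)·100 = 99.2032% per-layer
   reduction. The kernels are even-symmetric, so one half is computed and
   the other half is mirrored bit-for-bit (the taper is mirrored the same
   way so the symmetry is exact in floating point).

2. **An RR-interval rhythm feature fused into the classifier head.** The
   coefficient of variation CV = σ/t̄ of the segment's RR intervals
   (population standard deviation over mean) is concatenated to the
   16-dimensional global-average-pooled feature vector. CV is
   scale-invariant (heart-rate independent), near zero for regular
   rhythm, and large for ectopic or irregular rhythm; because the R-peak
   is the dominant ECG deflection, it survives noise levels that destroy
   subtler morphology.

Layer stack: SincConv(32×251, stride 1, no bias) → ReLU → MaxPool(2,2) →
Dropout 0.2 → BatchNorm → Conv(16×5) → ReLU → Conv(16×5) → ReLU →
MaxPool(2,2) → Dropout 0.2 → BatchNorm → GAP → [⊕ CV → width 17] →
Dense 16 → ReLU → Dropout 0.3 → Dense 8 → ReLU → Dense n_classes →
softmax. Convolutions use same-padding (the pooling chain then needs the
input length divisible by 4); argmax ties break toward the lower class
index. The ablation baseline replaces the first layer with a standard
convolution (32 filters of length 32, free taps, bias), everything else
identical.

## Training

Adam (β₁ 0.9, β₂ 0.999), categorical cross-entropy, batch 128. The
package defaults are the published recipe (learning rate 3e-4, 60
epochs). Weight init, batch order, and dropout masks all derive from one
seed, so identical seeds give bit-identical trained weights.

The network and its gradients are implemented directly on numpy/scipy.
The sinc layer's backward pass uses the analytic derivative
d(2f̂ sinc(2π f̂ n))/df̂ = 2 cos(2π f̂ n) (valid at n = 0), chained
through the cutoff reparameterization below; convolutions run via FFT
(long, first-layer kernels) or shift-matmul (short kernels). Gradients of
every layer are verified against central finite differences in the test
suite.

**Cutoff reparameterization.** The optimizer sees two unconstrained reals
per filter; the layer materializes f_L = |θ₁| and f_H = f_L +
max(|θ₂|, min_band) with both clipped to the Nyquist frequency and
min_band = 1 Hz. Every materialized kernel is therefore a valid bandpass
with 0 ≤ f_L < f_H ≤ fs/2 at every optimization step, with no projection
step in the optimizer. Clipped or floored coordinates receive zero
gradient (subgradient convention); a degenerate band f_L = f_H yields the
zero kernel. Initialization spreads contiguous, slightly jittered bands
over 0–60 Hz (`band_limited`, the default — the diagnostic ECG band where
P/T and QRS energy lives) or over the full 0–fs/2 (`uniform`).

**Batch-normalization inference statistics.** At desk scale an epoch is
~10 optimizer steps, so momentum-smoothed running BN statistics lag far
behind the weights and inference-mode accuracy collapses. Instead, after
each epoch the package recomputes exact population moments of every BN
input ("precise BN") over an evenly spaced, class-spanning sample of up
to 512 training segments with dropout disabled. The momentum update still
runs during training as a fallback between recalibrations.

**Desk-scale optimization.** The published recipe pairs lr 3e-4 and
batch 128 with ~10³ steps per epoch at full dataset scale. The
scaled-down experiment protocols (`kecnet.experiments.desk_train_config`)
use lr 3e-3 and batch 64 so that per-epoch optimization progress is
comparable at ~10–30 steps per epoch; `TrainConfig` defaults keep the
published values.

## QRS detection and the CV feature

Pan–Tompkins stages: zero-phase Butterworth bandpass 5–15 Hz (order 2),
five-point derivative (−x[n−2] − 2x[n−1] + 2x[n+1] + x[n+2])/8, squaring,
150 ms moving-window integration, then dual adaptive thresholds: running
signal/noise levels updated by the 0.125/0.875 rule, threshold = noise +
0.25·(signal − noise), 200 ms refractory spacing, search-back at half
threshold when a gap exceeds 1.66× the running mean RR, and a T-wave
discrimination step that rejects candidates within 360 ms of the last
QRS whose local slope is below half the previous QRS slope. Accepted
peaks are refined to the local absolute maximum of the bandpassed signal
within ±50 ms, which makes detection polarity-insensitive. All constants
live in `PanTompkinsConfig`.

The printed formula for σ in the source procedure omits the square (it
reads as a mean of signed deviations, identically zero); the package uses
the population standard deviation, the only sensible reading of
"standard deviation". A segment with fewer than 3 detected beats —
physiologically extreme or noise-destroyed — gets CV = 0 with an
`insufficient_beats` flag rather than an error, so batch preprocessing
never aborts.

## Preprocessing

Beat symbols map to the five AAMI classes by exact table lookup
(N ← NOR, NE, AE, LBBB, RBBB; S ← AP, APB, APC, NP, SP; V ← VF, VE, PVC;
F ← F; Q ← UN, FPN, P), with the standard single-character annotation
symbols aliased onto the same classes; anything else (artifacts, rhythm
labels) is excluded with a logged warning. Sliding windows (default
stride = M, non-overlapping) take the majority class of their mapped
beats; ties go to the pathological class, with precedence V > S > F > Q
over N — conservative toward flagging disease. Windows with zero mapped
beats are dropped (majority is undefined). Each window is Z-scored
(constant windows map to zero). Class balancing translates window start
points by uniform shifts of magnitude M/8–M/2, keeping a shifted window
only if its majority label is unchanged. Splits are stratified per class:
20% test, then 12.5% of the remainder as validation (net 70/10/20).
Test-time noise is zero-mean white Gaussian rescaled to its empirical
power so the realized SNR is exact to machine precision.

## The synthetic data generator

Each beat is built from simple pulses with controlled spectra. The R
wave is a Laplacian (cusped) pulse exp(−|t|/τ) whose full width at half
maximum is the class's QRS width: unlike a Gaussian of the same width,
its sharp apex carries the broadband 10–40 Hz energy real QRS
deflections have — which both the 5–15 Hz detection band and the upper
filters of the sinc bank rely on. Wide (ventricular-like and fusion)
complexes are *notched*: two merged sharp lobes spanning the nominal
width, as real PVCs are slurred/notched — a single smooth hump of that
width would be spectrally empty above ~10 Hz, which no real QRS is. P
(optional, −160 ms, σ 25 ms) and T (+280 ms, σ 60 ms) waves stay smooth
Gaussians; a biphasic variant models distorted (unknown-class)
morphology. Beat times follow mean_RR·(1 + jitter·z) with z standard
normal truncated at ±3σ; premature beats (class-dependent rate) arrive
at 55% of the drawn interval with a 145% compensatory pause; an optional
RR-alternans term alternates ±a around the mean. Baseline wander is a
0.2 Hz sinusoid at 5% of QRS amplitude with random phase, and every
record carries a broadband sensor-noise floor (white, default 35 dB SNR
— the order of a decent ambulatory recording): real recordings are never
spectrally silent, and a model trained on zero-noise bands meets
test-time noise with degenerate feature statistics. Each record carries
its ground-truth R-peak list, which is the oracle for all detection
tests.

Default class conditions: N (75 bpm, jitter 1%, 80 ms QRS, P present),
S (85 bpm, jitter 10%, 70 ms QRS, 30% premature beats), V (70 bpm,
jitter 5%, 140 ms notched QRS, no P), F (75 bpm, jitter 5%, 110 ms
notched QRS), Q (65 bpm, jitter 15%, 60 ms low-amplitude biphasic QRS,
no P/T). These are separable jointly by QRS width, P presence, amplitude
structure, and CV — verified by a nearest-centroid check on measured
features — so the deep model's desk-scale targets are attainable by
construction.

**The CV-ablation class pair** isolates rhythm: two classes with
bit-identical beat morphology (bare 80 ms QRS, no P or T), 48 bpm, where
one has 20% RR alternans (alternating short/long intervals, a
bigeminy-like pattern). Alternans leaves the average rate and per-window
beat count unchanged, and the slow rate keeps every neighboring-beat
spacing beyond the convolutional stack's ~0.8 s receptive field — so the
morphology path is blind to the difference by design and only the CV
input separates the classes. This is the situation the rhythm feature
exists for, reduced to its purest form.

**What the generator does not emulate:** inter-patient morphology
variability, electrode motion artifacts and muscle noise (only white
noise and sinusoidal wander), multi-lead structure, and within-record
class changes (each record carries one rhythm). Passing the synthetic
benchmarks therefore demonstrates that the architecture, features, and
training loop work as designed — not clinical-grade performance, which
requires the real archive (see the `prepare` CLI path).

## The noise-robustness protocol

Models are trained on unperturbed records and evaluated on test segments
with added white noise at 60/30/10 dB SNR; noisy segments are
re-Z-scored and their CV recomputed from the noisy signal (the
deployment condition). The training records for this study use a
wearable-grade 18 dB sensor floor rather than the 35 dB default. The
reason is structural, not cosmetic: the sinc first layer resolves the
input's spectrum into narrow bands, and per-window Z-scoring of a noisy
segment deflates the signal-band channels while inflating the
noise-dominated ones. If training data is nearly noiseless, heavy test
noise is a pure distribution shift in feature scale that collapses any
spectral classifier and the model comparison degenerates into comparing
failure modes. With realistically noisy training records, both models
remain functional at 10 dB and the comparison measures what it should:
the band-limited sinc bank rejects out-of-band noise and degrades less
than the broadband free-tap first layer.

## Desk-scale experiment sizes

Chosen so the full suite and the acceptance script run on one CPU in
tens of minutes: clean benchmark 500 records/class (300/class in the
acceptance script), 8 epochs; robustness sweep 150/class at the 18 dB
floor, 16 epochs; CV-fusion ablation 150/class per pair member, 12
epochs; all with the desk-scale recipe (lr 3e-3, batch 64). Records are
10 s, so each record contributes one segment. The tests average the
fusion and robustness comparisons over three training seeds.

## Parameter accounting

`count_parameters` reports honest per-layer trainable counts (sinc layer:
2F exactly; standard convolutions and dense layers include biases) plus
the analytic per-layer gain. Published headline parameter totals for this
architecture are not reconstructible under any standard counting
convention we know, so no acceptance surface depends on matching them.

## Known limitations

- Splits are segment-wise, not patient-wise; real-data accuracy under
  this protocol overstates inter-patient generalization (a known caveat
  of the evaluation design the package reproduces).
- The WFDB codec is a subset (format 16/212 signals, binary beat
  annotations); multi-segment records and other formats are out of scope.
- Desk-scale training uses few optimizer steps; reported synthetic
  accuracies are stand-ins for direction and ordering claims (sinc ≥
  standard on clean data; smaller degradation under noise; fusion helps
  on rhythm-only contrasts), not absolute benchmarks.
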