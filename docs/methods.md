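# Methods

## Signal cleaning

Each modality gets a fixed chain, applied forward–backward (zero phase) so
cleaning introduces no delay:

| modality | chain | defaults |
|---|---|---|
| ECG / HR | 59–61 Hz notch → 1.5–150 Hz FIR band-pass → min–max | notch: order-2 Butterworth band-stop; FIR: 1001 taps, Hamming |
| GSR | 4 Hz low-pass → Gaussian smoothing → scale to maximum | Butterworth order 4; σ = 0.5 s |
| EMG | 0.5–500 Hz band-pass → 60 Hz notch → min–max | Butterworth order 4 |
| RESP | 0.05 Hz high-pass → 0.70 Hz low-pass | Butterworth order 4 |

Filter orders are free parameters of the design.  Butterworth order 4 and
an order-2 notch are conventional for biosignals.  The FIR length matters
more than it looks: the band-pass must *remove baseline wander*, and a
short FIR (≈100 taps at ECG rates) has a transition band of several hertz,
so a 0.2 Hz drift tone passes nearly unattenuated.  1001 taps give a
≈1.6 Hz transition and >50 dB stop-band attenuation (doubled by the
forward–backward pass), which meets the ≥20 dB contract the test suite
enforces on stop-band tones.  All orders are configurable per
`FilterSpec`.

Two further conventions: any band edge at or above 0.45·fs is clipped to
0.45·fs with a warning (the EMG chain's nominal 500 Hz upper edge exceeds
Nyquist at the 495 Hz sampling rate it is used with), and a collapsed band
after clipping is an invalid specification.  Min–max of a constant
sequence is defined as all zeros.  A literature-standard 5–15 Hz
QRS-detection band-pass is exposed separately (`qrs_band`) rather than
chained: stacking it with the 1.5–150 Hz band-pass would make the wider
band pointless, and the ECG waveform morphology survives only the wider
band.

Applying the ECG/HR chain to a *level-coded* heart-rate channel removes
the channel's mean by construction (everything below 1.5 Hz goes).  This
is faithful to the chain's definition — on real data HR information enters
through beat timing, not a DC level — but it means synthetic HR level
offsets do not survive cleaning; the synthetic GSR tonic level is the
main cleaned-domain class carrier.

## Segmentation

Channels are linearly resampled to a common rate (default 8 Hz — windowed
classification here rides on slow level/rate structure, not waveform
detail), stacked alphabetically by channel name (so nothing depends on
channel order), and cut into windows of 10 s with 50 % overlap by default.
A window takes the label of the phase covering the majority of its span;
ties go to the earlier interval; windows outside the annotated region are
dropped.  Label schemes: three-level (rest→low, highway→medium,
city→high) and two-level (rest→relaxed, city/highway→stressed).
`SegmentSet.normalized()` applies per-channel min–max over the pooled
window set, the standard rescaling before training when windows are built
from uncleaned channels in native units.

## Network architectures and training

The classifiers are built from declarative specs.  Convolutional blocks
are Conv1D (kernel 3, causal left padding, so every layer preserves
length) → ReLU → layer normalization.  Layer normalization operates over
the channel features at each time step (switchable to per-channel
normalization over time via `ln_axis`).  Device profiles:

* `srad`, `e4l`, `e4r`, `e4lr`, `bh_e4lr`: filters 8→32→64→128 plus a bare
  trailing 8-filter convolution;
* `bh`: filters 128→64→32, no trailing convolution.

Fusion profiles use early fusion — the constituent devices' channels are
resampled to the common rate and stacked as input channels into a single
stack whose block ladder is the deeper of the constituents.  A
parallel-branch fusion variant is out of scope.

The plain CNN ends with global average pooling and a fully connected
softmax head of width `n_classes` (no extra hidden width).  The hybrid
model feeds the convolutional feature sequence to an LSTM (hidden 250 for
`srad`, 300 for `e4l`, 200 otherwise; dropout 0.4 for `srad`, 0.5
otherwise) and classifies from the final hidden state.

Training: Adam (learning rate 0.001 by default), cross-entropy loss,
stratified 80/20 split, validation metrics recorded every 10 iterations.
Effective defaults are 20 epochs × mini-batch 30 for `srad` and 30 × 20
for the other profiles; all overridable.  Everything — split, Glorot
initialization, shuffling, dropout — derives from one seed, and reruns are
bitwise identical.

Two deliberate implementation choices: (i) the split shuffles indices once
*independently of the labels* and then takes per-class quotas, and
(ii) the final classification layer initializes at zero.  Together these
make training exactly equivariant under class relabelling (permuting the
labels permutes predictions and the confusion matrix, verified in the
suite), which is the property one wants from a classifier that claims no
preferred class.  The network engine is written directly in NumPy
(`drivestress.engine`); every layer's backward pass is checked against
central finite differences in the test suite.

## Metrics

Per-class metrics are one-vs-rest: ACC = (TP+TN)/N, RCL = TP/(TP+FN),
PRC = TP/(TP+FP), SPC = TN/(TN+FP), F1 the harmonic mean of PRC and RCL.
A zero-denominator ratio is reported as *undefined* (`None`), never 0 — a
silent zero would quietly poison a downstream decision matrix.  Display
rounding (e.g. one decimal in percent) never touches stored values.

## EDAS ranking

The eight steps are documented in `drivestress/edas.py`.  Two points of
orientation, fixed against the worked reference tables bundled in
`drivestress/reference.py`:

* For a beneficial criterion the **positive** distance is the shortfall
  below the column average, PI = max(0, ψ−X)/ψ, and the **negative**
  distance the surplus above it, NI = max(0, X−ψ)/ψ.  This inverts the
  textbook EDAS naming, but combined with the rank rule *lowest appraisal
  score wins* the final ordering coincides with the conventional method.
* The appraisal score is λ = (NSPI + NSNI)/2 with NSPI = SPI/max SPI and
  NSNI = 1 − SNI/max SNI (zero maxima make the ratio zero), giving
  λ ∈ [0, 1].

The bundled criteria weights (0.4176, 0.2850, 0.1453, 0.0844, 0.0676) sum
to 0.99993 and are used exactly as given; `DecisionMatrix.renormalized()`
rescales them on request (the ranking is invariant to the overall weight
scale, so this is cosmetic).  Rank ties share a dense rank when appraisal
scores differ by at most 5·10⁻⁵ — half of one 4-decimal rounding step.
The method is widely called "fuzzy EDAS" in the applied literature even
when, as here, inputs are crisp; no fuzzification step exists in the
procedure.

A caution established empirically during development and pinned by a
regression test: duplicating an alternative shifts the column averages and
*can* reverse the relative order of the others (rank reversal, a known
weakness of average-referenced MCDM).  The weaker true statement —
appending a row equal to the column means preserves everything — is the
property test.

## Synthetic data

The generator emulates the drive protocol: rest(900 s) → city(300 s) →
highway(600 s) → city(300 s) → rest(900 s), all durations multiplied by a
scale factor (default 0.1, so a drive synthesizes in well under a second).
Channels are statistical stand-ins with realistic sampling rates (ECG
496 Hz, EMG 495 Hz, GSR/RESP 31 Hz): baseline + per-stress-level offset +
oscillation + Poisson event process + white noise + baseline wander +
60 Hz powerline.  Defaults: HR baseline 70 bpm with +10/+20 bpm offsets
for medium/high stress at σ = 5 bpm; GSR tonic 5 µS with +1/+2 µS offsets
and phasic-response rates 0.01/0.05/0.1 events·s⁻¹ by level; EMG burst
rates rising with stress; respiration rate 0.20/0.25/0.30 Hz by level.
ECG is a pulse train whose beat rate follows the stress level — no
morphological realism is claimed.  `noise_scale` and `separation`
multiply the noise σs and the class offsets; cohorts draw per-drive seeds
and mild baseline jitter from one master seed.

What passing tests therefore show: the pipeline recovers *configured*
class structure (level shifts, event-rate changes) through cleaning,
segmentation, and training, deterministically.  What they do not show:
performance on real physiology, with its inter-subject variability,
artifacts, label noise, and far weaker effect sizes.  The bundled
benchmark tables exist precisely because the real-data accuracies cannot
be regenerated here.

## Problem sizes

The suite and the end-to-end checks run at desk scale by design: scale-0.1
drives (300 s), cohorts of 3–5 drives, ~230–300 windows of 80 samples × 5
channels, 8–10 training epochs.  At these sizes the full test suite runs
in about a minute on one CPU.
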