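# drivestress

Driver stress recognition from multimodal physiological signals: signal
cleaning, windowed segmentation, 1D CNN and hybrid 1D CNN-LSTM classifiers
for two- and three-level stress, per-class classification metrics, and an
EDAS multi-criteria ranking of competing models.

## The problem

Acute mental stress degrades driving performance, and ambulatory
physiology — ECG, heart rate, galvanic skin response (GSR/EDA), trapezius
EMG, respiration, plus wearable-device channels (chest strap, wrist
sensors) — carries enough signal to recognize it.  The standard real-drive
protocol brackets city and highway driving with two 15-minute rest periods;
rest, highway, and city phases are taken to induce low, medium, and high
stress respectively, giving the class labels.

`drivestress` implements the full desk-scale workflow:

1. **Cleaning** (`drivestress.signals`) — per-modality chains: 59–61 Hz
   mains notch + 1.5–150 Hz zero-phase FIR band-pass + min–max
   normalization for ECG/HR; 4 Hz low-pass + Gaussian smoothing +
   scale-to-maximum for GSR; 0.5–500 Hz Butterworth band-pass (edges
   clipped to 0.45·fs) + 60 Hz notch + min–max for EMG; 0.05 Hz high-pass +
   0.70 Hz low-pass for respiration.
2. **Segmentation** — channels are resampled to a common rate, stacked, and
   cut into equal-length sliding windows (default 10 s, 50 % overlap)
   labelled by majority phase coverage.
3. **Classification** (`drivestress.nets`) — 1D CNNs built from
   Conv1D(kernel 3, causal padding) → ReLU → LayerNorm blocks with filter
   ladders 8/32/64/128 (+ trailing 8-filter conv) or 128/64/32 depending on
   the device profile, closed by global average pooling and a softmax head;
   the hybrid variant replaces pooling with an LSTM (hidden 200–300,
   dropout 0.4–0.5).  Training uses Adam with cross-entropy loss on a
   stratified split and is bit-reproducible given a seed.  The network
   engine is pure NumPy with hand-verified gradients
   (`drivestress.engine`).
4. **Evaluation** (`drivestress.metrics`) — K×K confusion matrices and
   one-vs-rest per-class ACC, RCL, PRC, F1, SPC.
5. **Ranking** (`drivestress.edas`) — the eight-step EDAS ("Evaluation
   based on Distance from Average Solution") procedure: per-criterion
   averages ψ, positive/negative distance matrices, weighted sums
   SPI/SNI, normalizations, appraisal score λ = (NSPI + NSNI)/2 ∈ [0, 1],
   and dense ranks with the lowest λ first.
6. **Synthesis** (`drivestress.synth`) — a seeded generator of
   phase-annotated drives with stress-dependent channel statistics and the
   standard noise taxonomy (white noise, baseline wander, 60 Hz powerline
   interference), so the whole pipeline is exercisable without any
   download.

## Worked example

Rank the bundled six-device benchmark (relaxed-state CNN metrics) with the
published criteria weights (0.4176, 0.2850, 0.1453, 0.0844, 0.0676):

```sh
$ drivestress rank --out edas_out
rank 1: BH+E4-(L+R) (appraisal 0.0000)
rank 2: E4-(L+R) (appraisal 0.2850)
rank 3: SRAD (appraisal 0.4467)
rank 4: BH (appraisal 0.6586)
rank 5: E4-R (appraisal 0.7993)
rank 6: E4-L (appraisal 0.9133)
```

The fused chest-strap + both-wrists model (BH+E4-(L+R)) is weakly best on
every criterion, so its weighted shortfall SPI is 0, its surplus SNI is the
maximum, and its appraisal score is exactly 0 — rank 1.  `edas_out/`
contains the full intermediate chain (ψ, PI, NI, SPI/SNI, normalized sums,
appraisal, ranks) as delimited tables plus a JSON audit record, e.g.
`scores.csv`:

```
alternative,SPI,SNI,NSPI,NSNI,appraisal,rank
SRAD,0.008780,0.015807,0.166290,0.727078,0.446684,3
...
BH+E4-(L+R),0.000000,0.057917,0.000000,0.000000,0.000000,1
```

An end-to-end synthetic run (generate → clean → segment → train →
evaluate → rank) from a YAML config:

```sh
$ cat run.yaml
out_dir: run_out
seed: 5
scheme: two
n_drives: 3
scale: 0.1
epochs: 8
minibatch: 20
subsets:
  - {name: high-snr, noise_scale: 0.5}
  - {name: low-snr, noise_scale: 3.0}
$ drivestress pipeline --config run.yaml
manifest: run_out/manifest.json
```

which writes per-subset confusion matrices, a metrics table, the EDAS
tables, and a manifest from which the run is exactly reproducible.

## Scope notes

The bundled benchmark metrics are inputs, not results this package claims
to reproduce: retraining the published models requires the real SRAD
(PhysioNet "drivedb") and AffectiveROAD recordings, which are deliberately
out of scope.  See `docs/methods.md` for the model details, parameter
defaults, and the limits of what the synthetic generator shows.
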