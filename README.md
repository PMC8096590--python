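# kecnet

Lightweight, knowledge-reinforced ECG arrhythmia classification: a 1-D
convolutional network for 5-class AAMI heartbeat classification (N, S, V,
F, Q) of 10-second single-lead ECG segments, built for settings where
model size and noise robustness matter (wearables, mobile acquisition).

Two pieces of domain knowledge replace free-form network capacity:

1. **A learnable windowed-sinc bandpass filter bank** as the first
   convolution layer. Each kernel is the Hamming-windowed difference of
   two sinc low-pass responses,
   `g[n] = 2 f̂_H sinc(2π f̂_H n) − 2 f̂_L sinc(2π f̂_L n)`,
   parameterized only by its low/high cutoff frequencies — 2 trainable
   values per filter instead of L = 251 free taps, a
   `(1 − 2/L)·100 = 99.2%` per-layer parameter reduction. The learned
   cutoffs are directly readable as frequency bands, and the explicit
   bandpass structure rejects out-of-band noise.
2. **An RR-interval rhythm feature.** R-peaks are detected with the
   Pan–Tompkins algorithm; the coefficient of variation `CV = σ/t̄` of
   the RR-interval series (population SD over mean) is concatenated to
   the pooled feature vector before the dense head, injecting long-range
   rhythm information that convolution + global average pooling cannot
   see.

The package contains the full pipeline: WFDB-subset record reading,
AAMI label mapping, majority-label segmentation, Z-scoring, translation
augmentation, stratified splits, SNR-exact noise injection, the network
with hand-written gradients on numpy/scipy, filter-bank analysis
(bandwidth tables, cumulative frequency response), and a seeded
synthetic-ECG generator that provides ground truth for every stage.

## Worked example

`examples/rhythm_feature.py` — detection and the CV feature on synthetic
records:

```text
regular (N-like)        : 12 peaks detected (12 true, worst offset 0 samples), mean RR 0.801 s, CV = 0.0065
premature-rich (S-like) : 14 peaks detected (14 true, worst offset 1 samples), mean RR 0.699 s, CV = 0.3344

CV at 30 dB noise       : 0.0065 (clean 0.0065) - RR features resist noise because the R-peak is the dominant deflection
```

The detector recovers every generated beat within ±1 sample; the CV
separates regular rhythm (≈0.007) from a premature-beat-rich rhythm
(≈0.33) and is unchanged by 30 dB white noise.

`examples/train_classifier.py` — desk-scale training on 100 records per
class (a few minutes on one CPU):

```text
dataset: 500 segments, splits [350, 50, 100] (train/val/test)

training history (last 3 epochs):
 epoch  train_loss  train_acc  val_loss  val_acc
    12      0.6056     0.7914    0.4819   0.9200
    13      0.5466     0.8200    0.4454   0.9600
    14      0.5114     0.8257    0.4091   0.9400

trainable parameters: 4501 total; first (sinc) layer 64 (gain 99.20% vs free taps)

confusion matrix (rows = truth N,S,V,F,Q):
[[18  0  2  0  0]
 [ 0 20  0  0  0]
 [ 0  0 20  0  0]
 [ 0  0  0 20  0]
 [ 0  0  0  0 20]]
ACC 98.00%  SEN 98.00%  PRE 98.18%
```

The whole network is ~4.5k trainable values — the first layer's 32
filters cost 64 parameters instead of 8032 — and at this tiny training
size it already separates the five classes (the residual N→V confusions
vanish at the benchmark scale used in the test suite). The other
examples build filter banks (`filterbank_basics.py`) and compare noise
robustness of the sinc versus standard first layer
(`noise_robustness.py`).

There is also a thin CLI over the same functions:

```bash
kecnet synth --seed 0 --n-per-class 100 --out run/
kecnet train --dataset run/dataset.npz --epochs 10 --out run/
kecnet evaluate --dataset run/dataset.npz --checkpoint run/checkpoint.npz --out run/
kecnet analyze-filters --checkpoint run/checkpoint.npz --out run/
kecnet robustness --dataset run/dataset.npz --checkpoint run/checkpoint.npz --out run/
kecnet prepare --records 100,101 --data-dir mitdb/ --out run/   # real WFDB data
```

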