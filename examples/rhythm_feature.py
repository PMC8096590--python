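"""Detect R-peaks on synthetic ECG and compute the CV rhythm feature.

Generates one regular record and one with a premature-beat-rich rhythm,
runs the Pan-Tompkins detector against the generator's ground truth, and
shows how the coefficient of variation of the RR intervals separates the
two rhythms — including under added noise.
"""

import numpy as np

from kecnet.preprocessing import add_white_noise
from kecnet.rhythm import detect_r_peaks, segment_cv
from kecnet.synth import default_class_specs, synth_record

FS = 360.0
specs = default_class_specs()

for label, spec in (("regular (N-like)", specs["N"]),
                    ("premature-rich (S-like)", specs["S"])):
    rec = synth_record(spec, duration_s=10, fs=FS, seed=1)
    peaks = detect_r_peaks(rec.signal, FS)
    worst = max(abs(int(p) - int(t))
                for p, t in zip(peaks.indices, rec.true_r_peaks))
    feat = segment_cv(rec.signal, FS)
    print(f"{label:24s}: {len(peaks)} peaks detected "
          f"({len(rec.true_r_peaks)} true, worst offset {worst} samples), "
          f"mean RR {feat.mean_rr:.3f} s, CV = {feat.cv:.4f}")

rec = synth_record(specs["N"], duration_s=10, fs=FS, seed=1)
noisy = add_white_noise(rec.signal, snr_db=30.0, seed=7)
feat_clean = segment_cv(rec.signal, FS)
feat_noisy = segment_cv(noisy, FS)
print(f"\nCV at 30 dB noise       : {feat_noisy.cv:.4f} "
      f"(clean {feat_clean.cv:.4f}) - RR features resist noise because the "
      "R-peak is the dominant deflection")
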