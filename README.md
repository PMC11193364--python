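# swinbeat

ECG arrhythmia beat classification from wavelet time-frequency images,
for researchers working with MIT-BIH-style Holter recordings and the five
AAMI beat superclasses (N normal, S supraventricular ectopic, V ventricular
ectopic, F fusion, Q paced/unclassifiable).

The pipeline has three stages:

1. **Wavelet denoising** — db6 discrete wavelet decomposition to level 3;
   each detail band is soft-thresholded, ŵ = sgn(w)·(|w|−T) for |w| ≥ T and
   0 otherwise, with T chosen per band by minimizing Stein's unbiased risk
   estimate (the *rigrsure* rule) after a robust noise estimate
   σ = median(|d|)/0.6745.
2. **Time-frequency imaging** — complex Morlet CWT,
   ψ(t) = (πF_b)^(−1/2) e^(2iπF_c t) e^(−t²/F_b), over the scale sequence
   α_i = c/i with c = 2·F_c·totalscal, so the mapped frequencies
   F_a = F_c·f_s/α are exactly linear up to the Nyquist frequency f_s/2.
   Magnitudes are rendered through a warm–cold colormap into square RGB
   images (time horizontal, frequency ascending).
3. **Classification** — a hierarchical shifted-window attention network:
   4×4 patch embedding, four stages of paired W-MSA/SW-MSA transformer
   blocks computing softmax(QKᵀ/√d_k)V within M×M token windows (the
   shifted variant cyclically displaces the grid by ⌊M/2⌋ with a mask that
   forbids attention across wrapped fragments), 2×2 patch merging between
   stages (C → 2C → 4C → 8C channels), then layer norm, global average
   pooling and a linear head over the five classes. Training uses softmax
   cross-entropy with Adam. The network, including backpropagation, is
   implemented in NumPy.

Evaluation supports 10-fold cross-validation under the **intra-patient**
(beat-level split) and **inter-patient** (subject-disjoint split) paradigms
with per-fold accuracy, precision, sensitivity, specificity, F1 and macro
one-vs-rest AUC, aggregated with 95% normal-approximation confidence
intervals.

A seeded synthetic generator produces labelled five-class beats and
annotated WFDB records (Gaussian-bump P-QRS-T templates, white noise at a
target SNR, sinusoidal baseline wander), so the whole pipeline runs and is
tested without any data download. A minimal WFDB reader/writer (.hea/.dat
formats 16 and 212, .atr annotations) handles real records.

## Worked example

```python
import numpy as np
from swinbeat import (SyntheticConfig, generate_beats, WaveletDenoiser,
                      ScalogramTransformer, SwinClassifier)
from swinbeat.evaluate import crossval_images
from swinbeat.io import beats_to_array

cfg = SyntheticConfig(n_per_class=100, snr_db=15.0, seed=1)
X1d, y = beats_to_array(generate_beats(cfg))
X1d = WaveletDenoiser().fit_transform(X1d)                  # db6 + rigrsure
X = ScalogramTransformer(totalscal=64, out_size=32).fit_transform(X1d)
clf = SwinClassifier(epochs=15, lr=1e-3, seed=1)            # tiny config
agg, folds = crossval_images(X, y, clf, paradigm="intra", k=10, seed=1)
print(f"mean accuracy {agg.accuracy:.4f} "
      f"(95% CI {agg.ci['accuracy'][0]:.4f}-{agg.ci['accuracy'][1]:.4f})")
```

prints

```
mean accuracy 1.0000 (95% CI 1.0000-1.0000)
```

— with 15 dB noise the five synthetic morphologies are fully separable, so
the tiny model classifies every held-out fold perfectly; lower `snr_db` to
make the task harder. The same pipeline runs from the shell:

```sh
swinbeat simulate  --out run/sim --n-beats 50 --seed 7
swinbeat crossval  --out run/cv --n-per-class 100 --epochs 15 --seed 1
```

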