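"""Seeded generator of labelled five-class synthetic ECG beats and records.

Each AAMI class (N, S, V, F, Q) has a fixed noiseless beat template built
from Gaussian bumps for the P, Q, R, S and T deflections, with
class-specific positions, widths and amplitudes:

* **N** — full P-QRS-T complex with a narrow dominant R wave.
* **S** — supraventricular ectopic: no P wave, narrow early QRS, flat T.
* **V** — ventricular ectopic: wide high-amplitude QRS, discordant T, no P.
* **F** — fusion beat: morphology intermediate between N and V.
* **Q** — unclassifiable: low-amplitude, broad, irregular deflections.

Templates are zero-mean (AC-coupled recording). Beats are the template plus
white Gaussian noise scaled to a target SNR and a sinusoidal baseline
wander. Records concatenate beats at physiological RR intervals
(uniform 0.7–1.0 s) with an annotation at every synthetic R peak. All
randomness flows through one seeded generator, so equal configurations give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AAMI_CLASSES, BeatSegment, ECGRecord

#: representative MIT-BIH beat symbol emitted for each AAMI class
CLASS_TO_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "Q"}

# (centre s relative to R, width s, amplitude mV) per Gaussian deflection
_TEMPLATE_WAVES: dict[str, list[tuple[float, float, float]]] = {
    "N": [(-0.22, 0.025, 0.15), (-0.035, 0.010, -0.12), (0.0, 0.014, 1.20),
          (0.035, 0.012, -0.25), (0.22, 0.060, 0.30)],
    "S": [(-0.030, 0.010, -0.10), (0.0, 0.009, 0.95), (0.030, 0.018, -0.45),
          (0.155, 0.040, 0.15)],
    "V": [(0.0, 0.045, 1.50), (0.075, 0.050, -0.55), (0.28, 0.080, -0.45)],
    "F": [(-0.20, 0.025, 0.08), (0.0, 0.028, 1.05), (0.050, 0.030, -0.35),
          (0.25, 0.070, -0.12)],
    "Q": [(-0.15, 0.050, 0.22), (0.0, 0.020, 0.55), (0.10, 0.040, -0.28),
          (0.25, 0.090, 0.15)],
}


@dataclass
class SyntheticConfig:
    """Generation parameters for synthetic beats and records."""

    fs: float = 360.0                 #: sampling rate, Hz
    beat_len: int = 256               #: samples per beat window
    classes: tuple[str, ...] = AAMI_CLASSES
    n_per_class: int = 10
    snr_db: float = 15.0              #: white-noise SNR vs the clean template
    baseline_amp: float = 0.05        #: baseline-wander amplitude, mV
    baseline_freq: float = 0.3        #: baseline-wander frequency, Hz
    rr_range: tuple[float, float] = (0.7, 1.0)  #: RR interval bounds, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.beat_len <= 0:
            raise ValueError("beat_len must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        unknown = set(self.classes) - set(AAMI_CLASSES)
        if not self.classes or unknown:
            raise ValueError(f"invalid class set {self.classes!r}")


def class_template(label: str, beat_len: int = 256, fs: float = 360.0) -> np.ndarray:
    """Noiseless zero-mean beat template for one AAMI class."""
    if label not in _TEMPLATE_WAVES:
        raise ValueError(f"unknown class {label!r}")
    t = (np.arange(beat_len) - beat_len // 2) / fs
    x = np.zeros(beat_len)
    for centre, width, amp in _TEMPLATE_WAVES[label]:
        x += amp * np.exp(-((t - centre) ** 2) / (2.0 * width**2))
    return x - x.mean()


def _noise_sigma(clean: np.ndarray, snr_db: float) -> float:
    """White-noise standard deviation achieving ``snr_db`` against ``clean``."""
    if np.isinf(snr_db):
        return 0.0
    p_signal = float(np.mean(clean**2))
    return float(np.sqrt(p_signal / 10.0 ** (snr_db / 10.0)))


def measure_snr_db(noisy: np.ndarray, clean: np.ndarray) -> float:
    """SNR by definition: 10 log10(P_clean / P_(noisy - clean))."""
    p_noise = float(np.mean((noisy - clean) ** 2))
    p_signal = float(np.mean(clean**2))
    if p_noise == 0:
        return np.inf
    return 10.0 * np.log10(p_signal / p_noise)


def generate_beats(cfg: SyntheticConfig) -> list[BeatSegment]:
    """Generate ``n_per_class`` labelled beats per class, deterministically.

    Each beat is its class template plus baseline wander (random phase) plus
    white Gaussian noise scaled to ``cfg.snr_db`` against the template.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.beat_len) / cfg.fs
    beats: list[BeatSegment] = []
    for label in cfg.classes:
        template = class_template(label, cfg.beat_len, cfg.fs)
        sigma = _noise_sigma(template, cfg.snr_db)
        for i in range(cfg.n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            wander = cfg.baseline_amp * np.sin(
                2 * np.pi * cfg.baseline_freq * t + phase)
            noise = sigma * rng.standard_normal(cfg.beat_len) if sigma else 0.0
            beats.append(BeatSegment(
                samples=template + wander + noise, label=label,
                source_record=f"synthetic-{cfg.seed}",
                subject_id=f"synthetic-{cfg.seed}",
                r_index=cfg.beat_len // 2 + i * cfg.beat_len,
            ))
    return beats


def generate_record(cfg: SyntheticConfig, n_beats: int,
                    return_clean: bool = False):
    """Concatenate beats at physiological RR intervals into one record.

    Beat classes are drawn uniformly from ``cfg.classes``. The record carries
    one annotation per synthetic R peak, using each class's representative
    MIT-BIH symbol, so that segmentation recovers the labels. With
    ``return_clean=True`` also returns the noise-free signal (templates plus
    baseline wander) for SNR measurement.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    labels = [cfg.classes[rng.integers(len(cfg.classes))] for _ in range(n_beats)]
    rr = rng.uniform(cfg.rr_range[0], cfg.rr_range[1], size=n_beats - 1)
    half = cfg.beat_len // 2
    r_idx = np.empty(n_beats, dtype=int)
    r_idx[0] = half
    if n_beats > 1:
        r_idx[1:] = half + np.cumsum(np.round(rr * cfg.fs).astype(int))
    n = int(r_idx[-1] + half)

    template_sum = np.zeros(n)
    for lab, r in zip(labels, r_idx):
        template_sum[r - half : r + half] += class_template(lab, cfg.beat_len, cfg.fs)

    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0, 2 * np.pi)
    wander = cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq * t + phase)
    clean = template_sum + wander
    sigma = _noise_sigma(template_sum, cfg.snr_db)
    noisy = clean + (sigma * rng.standard_normal(n) if sigma else 0.0)

    rec = ECGRecord(
        signal=noisy, fs=cfg.fs, channel_names=["MLII"],
        annotations=[(int(r), CLASS_TO_SYMBOL[lab])
                     for r, lab in zip(r_idx, labels)],
        name=f"synthetic-{cfg.seed}", subject_id=f"synthetic-{cfg.seed}",
    )
    if return_clean:
        return rec, clean
    return rec
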