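"""Complex-Morlet continuous wavelet transform and time-frequency images.

The mother wavelet is the complex Morlet

    psi(t) = (pi*Fb)^(-1/2) * exp(2i*pi*Fc*t) * exp(-t^2 / Fb),

with bandwidth factor ``Fb`` and centre-frequency factor ``Fc``. Scale
``alpha`` (in samples) maps to physical frequency ``F_a = Fc * fs / alpha``.
The scale sequence is built from the constant ``c = 2 * Fc * totalscal`` as
``alpha_i = c / i`` for ``i = 1..totalscal``, which makes the mapped
frequencies exactly linear: ``F_a(i) = fs * i / (2 * totalscal)``, from
``fs/(2*totalscal)`` up to the Nyquist frequency ``fs/2``.

The CWT is the correlation of the signal with scaled, translated,
conjugated copies of psi, normalized by ``|alpha|^(-1/2)`` (the printed
``1/|alpha|`` variant is available via ``prefactor_exponent=-1.0``), and is
computed per scale by zero-padded FFT convolution; a direct O(N^2)
summation is available as an oracle. Magnitudes are rendered to RGB images
through a fixed warm-cold (jet) colormap after per-image min-max
normalization, with time on the horizontal axis and frequency ascending
upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.signal import fftconvolve

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MorletParams", "ScaleSequence", "Scalogram", "morlet_wavelet",
    "build_scale_sequence", "cwt", "render", "save_png", "ridge_frequency",
    "ScalogramTransformer",
]


@dataclass
class MorletParams:
    """Complex Morlet parameters: bandwidth Fb, centre frequency Fc."""

    fb: float = 1.5
    fc: float = 1.0
    norm_exponent: float = -0.5  # exponent of (pi*Fb) in the prefactor

    def __post_init__(self) -> None:
        if self.fb <= 0 or self.fc <= 0:
            raise ValueError("Fb and Fc must be positive")


@dataclass
class ScaleSequence:
    """Scales alpha_i = c/i and their mapped frequencies (ascending)."""

    scales: np.ndarray
    freqs: np.ndarray
    fs: float
    totalscal: int
    c: float


@dataclass
class Scalogram:
    """Complex CWT coefficients (scales x time) with axis annotations."""

    coeffs: np.ndarray          # complex, shape (totalscal, n_samples)
    times: np.ndarray           # seconds
    freqs: np.ndarray           # Hz, ascending, aligned with coeffs rows
    fs: float
    scales: np.ndarray | None = None
    prefactor_exponent: float = -0.5
    image: np.ndarray | None = field(default=None, repr=False)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coeffs)


def morlet_wavelet(t: np.ndarray, p: MorletParams | None = None) -> np.ndarray:
    """Evaluate the complex Morlet wavelet at times ``t``."""
    p = p or MorletParams()
    t = np.asarray(t, dtype=float)
    return ((np.pi * p.fb) ** p.norm_exponent
            * np.exp(2j * np.pi * p.fc * t)
            * np.exp(-(t**2) / p.fb))


def build_scale_sequence(fs: float, p: MorletParams | None = None,
                         totalscal: int = 256) -> ScaleSequence:
    """Build the length-``totalscal`` scale sequence with linear frequencies."""
    if totalscal < 2:
        raise ValueError("totalscal must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    p = p or MorletParams()
    c = 2.0 * p.fc * totalscal
    i = np.arange(1, totalscal + 1, dtype=float)
    scales = c / i                      # descending in alpha
    freqs = p.fc * fs / scales          # ascending: fs*i/(2*totalscal)
    return ScaleSequence(scales=scales, freqs=freqs, fs=fs,
                         totalscal=totalscal, c=c)


def _kernel(scale: float, p: MorletParams) -> np.ndarray:
    """conj(psi(-m/alpha)) sampled on integer offsets m, truncated support."""
    half = int(np.ceil(scale * np.sqrt(-p.fb * np.log(1e-12))))
    m = np.arange(-half, half + 1, dtype=float)
    return np.conj(morlet_wavelet(-m / scale, p))


def cwt(signal: np.ndarray, seq: ScaleSequence | None = None,
        p: MorletParams | None = None, method: str = "fft",
        prefactor_exponent: float = -0.5) -> Scalogram:
    """Continuous wavelet transform of a 1-D signal.

    ``method="fft"`` evaluates the per-scale correlation by zero-padded FFT
    convolution with 'same' output length; ``method="direct"`` computes the
    O(N^2) sum of the defining integral and serves as the reference.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D array")
    p = p or MorletParams()
    seq = seq or build_scale_sequence(360.0, p)
    coeffs = np.empty((seq.totalscal, x.size), dtype=complex)
    if method == "fft":
        for r, a in enumerate(seq.scales):
            kern = _kernel(a, p)
            coeffs[r] = np.abs(a) ** prefactor_exponent * fftconvolve(
                x, kern, mode="same")
    elif method == "direct":
        t = np.arange(x.size, dtype=float)
        for r, a in enumerate(seq.scales):
            # U(a, b) = |a|^q * sum_t x[t] * conj(psi((t - b)/a))
            grid = (t[None, :] - t[:, None]) / a
            coeffs[r] = np.abs(a) ** prefactor_exponent * (
                np.conj(morlet_wavelet(grid, p)) @ x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Scalogram(coeffs=coeffs, times=t_axis(x.size, seq.fs),
                     freqs=seq.freqs, fs=seq.fs, scales=seq.scales,
                     prefactor_exponent=prefactor_exponent)


def ridge_frequency(s: Scalogram, trim: float = 0.25) -> float:
    """Dominant frequency of a scalogram by brute-force ridge scan.

    Time-averages the magnitude over the central ``1 - 2*trim`` portion
    (edges carry convolution transients) after renormalizing every scale to
    the L1 convention (``1/|alpha|``), under which a pure tone's response
    peaks exactly at the scale whose mapped frequency matches the tone.
    Returns the mapped frequency of the maximizing scale.

    Reliable localization near the Nyquist frequency needs the smallest
    scale (``2*Fc`` samples) to stay above ~4 samples per cycle, i.e.
    ``Fc >= 2``; see the methods note.
    """
    if s.scales is None:
        raise ValueError("scalogram carries no scale axis")
    n = s.coeffs.shape[1]
    lo, hi = int(trim * n), max(int(trim * n) + 1, int((1 - trim) * n))
    renorm = np.asarray(s.scales) ** (-1.0 - s.prefactor_exponent)
    profile = s.magnitude[:, lo:hi].mean(axis=1) * renorm
    return float(s.freqs[int(np.argmax(profile))])


def t_axis(n: int, fs: float) -> np.ndarray:
    return np.arange(n) / fs


_CMAP = colormaps["jet"]  # fixed warm-cold map: blue (low) -> red (high)


def render(s: Scalogram, out_size: int = 224, global_range: tuple[float, float] | None = None) -> np.ndarray:
    """Render a scalogram magnitude to an ``out_size`` square RGB image.

    Magnitude is min-max normalized (per image unless ``global_range`` is
    given), mapped through the warm-cold colormap, and resized bilinearly.
    Row 0 of the returned uint8 array is the highest frequency (frequency
    ascends upward); columns follow time. A constant magnitude yields a
    uniform image.
    """
    mag = s.magnitude
    lo, hi = (float(mag.min()), float(mag.max())) if global_range is None \
        else global_range
    norm = np.zeros_like(mag) if hi <= lo else (mag - lo) / (hi - lo)
    rgb = (_CMAP(norm)[..., :3] * 255).astype(np.uint8)
    rgb = rgb[::-1]  # highest frequency on top
    img = Image.fromarray(rgb).resize((out_size, out_size), Image.BILINEAR)
    out = np.asarray(img, dtype=np.uint8)
    s.image = out
    return out


def save_png(image: np.ndarray, path: str) -> None:
    """Write a rendered RGB scalogram image as 8-bit PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


class ScalogramTransformer(TransformerMixin, BaseEstimator):
    """Map 1-D beats to float RGB time-frequency images in [0, 1].

    Parameters
    ----------
    fs : float, default 360.0
        Sampling rate of the input beats, Hz.
    fb, fc : float
        Complex Morlet bandwidth and centre-frequency factors.
    totalscal : int, default 256
        Number of CWT scales (linear frequency bins up to fs/2).
    out_size : int, default 224
        Side of the square rendered image.
    """

    def __init__(self, fs: float = 360.0, fb: float = 1.5, fc: float = 1.0,
                 totalscal: int = 256, out_size: int = 224):
        self.fs = fs
        self.fb = fb
        self.fc = fc
        self.totalscal = totalscal
        self.out_size = out_size

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_beats, beat_len)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_beats, beat_len)")
        p = MorletParams(fb=self.fb, fc=self.fc)
        seq = build_scale_sequence(self.fs, p, self.totalscal)
        out = np.empty((X.shape[0], self.out_size, self.out_size, 3))
        for i, row in enumerate(X):
            out[i] = render(cwt(row, seq, p), self.out_size) / 255.0
        return out
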