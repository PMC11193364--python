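"""WFDB-style ECG record I/O, AAMI label mapping, and beat segmentation.

Reads and writes the waveform-database family of files used by the MIT-BIH
Arrhythmia Database: a plain-text ``.hea`` header, a binary ``.dat`` signal
file (formats 16 and 212 supported for reading, 16 for writing) and a binary
``.atr`` beat-annotation file in the standard MIT annotation format.

Beat-level labels follow the five AAMI EC57 superclasses:

=====  =================================  =======================
class  meaning                            MIT-BIH beat symbols
=====  =================================  =======================
N      normal / bundle branch block       N L R e j
S      supraventricular ectopic           A a J S
V      ventricular ectopic                V E
F      fusion of ventricular and normal   F
Q      paced / unclassifiable             / f Q
=====  =================================  =======================

Non-beat annotations (rhythm changes, signal-quality flags, ...) map to
``None`` and are skipped during segmentation.
"""

from __future__ import annotations

import logging
import os
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: MIT-BIH beat symbol -> AAMI superclass (EC57 convention).
MITBIH_TO_AAMI: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

#: Records whose beats are predominantly paced; excluded by AAMI convention.
PACED_RECORDS: tuple[str, ...] = ("102", "104", "107", "217")

# Standard WFDB annotation type codes (annotation code -> mnemonic symbol).
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE: dict[str, int] = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# annotation-word field layout: bits 15..10 = type code, bits 9..0 = time delta
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class ECGRecord:
    """A sampled multichannel ECG with beat annotations.

    ``signal`` has shape ``(n_samples, n_channels)`` in physical units (mV);
    ``annotations`` is a list of ``(sample_index, symbol)`` pairs sorted by
    sample index.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=lambda: ["MLII"])
    annotations: list[tuple[int, str]] = field(default_factory=list)
    name: str = "record"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.signal.shape[0]
        for idx, _sym in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside [0, {n})")
        if not self.subject_id:
            self.subject_id = self.name

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class BeatSegment:
    """A fixed-length window centred on an annotated R peak."""

    samples: np.ndarray
    label: str
    source_record: str = ""
    subject_id: str = ""
    r_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("beat samples must be 1-D")
        if self.label not in AAMI_CLASSES:
            raise ValueError(f"label {self.label!r} not in {AAMI_CLASSES}")


def map_aami(symbol: str) -> str | None:
    """Map a single MIT-BIH annotation symbol to its AAMI class.

    Returns ``None`` for non-beat annotations (rhythm/quality markers) and
    for beat symbols outside the EC57 table (logged at debug level).
    """
    cls = MITBIH_TO_AAMI.get(symbol)
    if cls is None:
        logger.debug("non-beat or unknown annotation symbol %r -> None", symbol)
    return cls


# ---------------------------------------------------------------------------
# WFDB header / signal / annotation files
# ---------------------------------------------------------------------------

def write_record(rec: ECGRecord, directory: str, name: str | None = None,
                 gain: float = 200.0, adc_zero: int = 0) -> str:
    """Write ``rec`` as WFDB format-16 files (``.hea``, ``.dat``, ``.atr``).

    Samples are quantized as ``round(physical * gain) + adc_zero`` into
    little-endian int16, channel-interleaved. Returns the record prefix
    (path without extension).
    """
    name = name or rec.name
    prefix = os.path.join(directory, name)
    digital = np.round(rec.signal * gain).astype(np.int64) + adc_zero
    if digital.max() > 32767 or digital.min() < -32768:
        raise ValueError("signal exceeds int16 range at this gain")
    digital = digital.astype("<i2")

    lines = [f"{name} {rec.n_channels} {rec.fs:g} {rec.n_samples}"]
    for ch in range(rec.n_channels):
        chks = int(np.sum(digital[:, ch], dtype=np.int64) % 65536)
        if chks >= 32768:
            chks -= 65536
        desc = rec.channel_names[ch] if ch < len(rec.channel_names) else f"ch{ch}"
        lines.append(
            f"{name}.dat 16 {gain:g}({adc_zero})/mV 16 {adc_zero} "
            f"{int(digital[0, ch])} {chks} 0 {desc}"
        )
    with open(prefix + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    digital.reshape(-1).tofile(prefix + ".dat")
    if rec.annotations:
        write_annotations(prefix + ".atr", rec.annotations)
    return prefix


def write_annotations(path: str, annotations: list[tuple[int, str]]) -> None:
    """Write ``(sample_index, symbol)`` pairs in MIT annotation format."""
    out = bytearray()
    prev = 0
    for idx, sym in sorted(annotations):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            logger.warning("skipping annotation with unknown symbol %r", sym)
            continue
        delta = idx - prev
        if delta < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if delta > 1023:
            # SKIP word (time 0) followed by the 4-byte interval,
            # most-significant 16-bit word first, each little-endian
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = idx
    out += struct.pack("<H", 0)  # EOF
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def read_annotations(path: str) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into ``(sample_index, symbol)``."""
    with open(path, "rb") as fh:
        raw = fh.read()
    anns: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(raw) or (i + 1 == len(raw)):
        if i + 2 > len(raw):
            break
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", raw, i)
            i += 4
            pending_skip += (hi << 16) | lo
        elif code == _AUX:
            n = delta + (delta & 1)  # aux strings are padded to even length
            i += n
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += delta + pending_skip
            pending_skip = 0
            sym = _CODE_TO_SYMBOL.get(code)
            if sym is not None:
                anns.append((t, sym))
            else:
                logger.debug("unknown annotation code %d at t=%d", code, t)
    return anns


def _read_dat(path: str, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    """Decode a .dat file into digital samples of shape (n_samples, n_sig)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        data = data[: n_samples * n_sig].reshape(-1, n_sig)
    elif fmt == 212:
        # 2 samples packed into 3 bytes: 12-bit two's complement
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int32)
        n_pairs = len(b) // 3
        b = b[: n_pairs * 3].reshape(-1, 3)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        flat = np.empty(2 * n_pairs, dtype=np.int32)
        flat[0::2], flat[1::2] = s0, s1
        data = flat[: n_samples * n_sig].reshape(-1, n_sig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    return data


def read_record(path: str, channel: int | str | None = None) -> ECGRecord:
    """Read a WFDB record (header prefix or ``.hea`` path).

    ``channel`` selects a single channel by index or name; ``None`` keeps all
    channels. Sample values are converted to physical units (mV).
    """
    prefix = path[:-4] if path.endswith(".hea") else path
    hea = prefix + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"no such record header: {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    if len(lines) < 1 + n_sig:
        raise ValueError(f"corrupt header: expected {n_sig} signal lines")

    fmts, gains, baselines, names = [], [], [], []
    dat_name = None
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        dat_name = tok[0]
        fmts.append(int(tok[1].split("x")[0].split(":")[0].split("+")[0]))
        gain_spec = tok[2] if len(tok) > 2 else "200"
        g = gain_spec.split("/")[0]
        if "(" in g:
            gains.append(float(g[: g.index("(")]))
            baselines.append(int(g[g.index("(") + 1 : g.index(")")]))
        else:
            gains.append(float(g) if float(g) != 0 else 200.0)
            baselines.append(int(tok[4]) if len(tok) > 4 else 0)
        names.append(tok[-1])
    if len(set(fmts)) != 1:
        raise ValueError("mixed per-channel signal formats are not supported")

    dat_path = os.path.join(os.path.dirname(prefix) or ".", dat_name)
    digital = _read_dat(dat_path, fmts[0], n_sig, n_samples or -1)
    if n_samples == 0:
        n_samples = digital.shape[0]
    physical = (digital - np.asarray(baselines)) / np.asarray(gains, dtype=float)

    if channel is not None:
        if isinstance(channel, str):
            if channel not in names:
                raise ValueError(f"unknown channel {channel!r}; have {names}")
            channel = names.index(channel)
        if not 0 <= channel < n_sig:
            raise ValueError(f"channel index {channel} out of range")
        physical = physical[:, [channel]]
        names = [names[channel]]

    anns: list[tuple[int, str]] = []
    if os.path.exists(prefix + ".atr"):
        anns = [(t, s) for t, s in read_annotations(prefix + ".atr")
                if t < n_samples]
    return ECGRecord(signal=physical, fs=fs, channel_names=names,
                     annotations=anns, name=name)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_beats(rec: ECGRecord, beat_len: int = 256,
                  channel: int = 0) -> list[BeatSegment]:
    """Cut one fixed-length window per mapped beat annotation.

    Windows are centred on the annotation index (``beat_len/2`` samples each
    side); beats whose window would cross a record edge are dropped and
    counted in the log. Non-beat annotations are skipped.
    """
    if beat_len % 2 != 0:
        raise ValueError("beat_len must be even")
    if not rec.annotations:
        raise ValueError(f"record {rec.name!r} has no annotations")
    x = rec.signal[:, channel]
    half = beat_len // 2
    out: list[BeatSegment] = []
    dropped = 0
    for idx, sym in rec.annotations:
        label = map_aami(sym)
        if label is None:
            continue
        start, stop = idx - half, idx + half
        if start < 0 or stop > len(x):
            dropped += 1
            continue
        out.append(BeatSegment(samples=x[start:stop].copy(), label=label,
                               source_record=rec.name,
                               subject_id=rec.subject_id, r_index=idx))
    if dropped:
        logger.info("segment_beats: dropped %d edge beats in %s",
                    dropped, rec.name)
    return out


def segments_to_frame(beats: list[BeatSegment]) -> pd.DataFrame:
    """Segment metadata (record, subject, R index, label) as a DataFrame."""
    return pd.DataFrame(
        {
            "source_record": [b.source_record for b in beats],
            "subject_id": [b.subject_id for b in beats],
            "r_index": [b.r_index for b in beats],
            "label": [b.label for b in beats],
        }
    )


def beats_to_array(beats: list[BeatSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack beats into ``(X, y)``: samples ``(n, beat_len)`` and labels."""
    X = np.stack([b.samples for b in beats])
    y = np.array([b.label for b in beats])
    return X, y
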