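"""Minimal WFDB record I/O: header (.hea), signal (.dat, formats 16 and 212),
and MIT-format beat annotations (.atr).

Covers exactly what the beat pipeline needs from MIT-BIH-style records:
sampling rate, per-signal gain/baseline, digital-to-physical conversion, and
annotation (sample, symbol) pairs. Writing supports format 16 plus
annotations, enough to emit round-trippable fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WFDBHeader",
    "SignalInfo",
    "read_header",
    "read_signal",
    "read_annotations",
    "write_record",
    "write_annotations",
]

# Standard WFDB annotation code <-> symbol table (beat and non-beat codes).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str = "mV"
    description: str = ""


@dataclass
class WFDBHeader:
    record_name: str
    n_signals: int
    sampling_rate: float
    n_samples: int
    signals: list


def read_header(path: str) -> WFDBHeader:
    """Parse a .hea file. ``path`` may omit the extension."""
    hea = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing WFDB header file: {hea}")
    lines = []
    with open(hea) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    rec = lines[0].split()
    record_name = rec[0].split("/")[0]
    n_signals = int(rec[1])
    sampling_rate = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for spec in lines[1 : 1 + n_signals]:
        parts = spec.split()
        filename = parts[0]
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        if len(parts) > 2:
            gain_field = parts[2]
            if "/" in gain_field:
                gain_field, units = gain_field.split("/", 1)
            if "(" in gain_field:
                gain_field, base = gain_field.split("(")
                baseline = int(base.rstrip(")"))
            gain = float(gain_field) if gain_field else 200.0
            if gain == 0:
                gain = 200.0
        elif len(parts) > 4:
            baseline = int(parts[4])
        description = " ".join(parts[9:]) if len(parts) > 9 else ""
        signals.append(SignalInfo(filename, fmt, gain, baseline, units, description))
    return WFDBHeader(record_name, n_signals, sampling_rate, n_samples, signals)


def _decode_212(raw: bytes, n_samples_total: int) -> np.ndarray:
    """Unpack format 212: two 12-bit samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = b.size // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    samples = np.empty(2 * n_triplets, dtype=np.int32)
    samples[0::2] = first
    samples[1::2] = second
    samples[samples > 2047] -= 4096  # 12-bit two's complement
    return samples[:n_samples_total]


def read_signal(path: str, header: WFDBHeader | None = None) -> np.ndarray:
    """Read all leads of a record; returns physical units, shape (n_samples, n_signals)."""
    if header is None:
        header = read_header(path)
    base_dir = os.path.dirname(path if not path.endswith(".hea") else path[:-4])
    filename = header.signals[0].filename
    dat = os.path.join(base_dir, filename) if base_dir else filename
    if not os.path.exists(dat):
        raise FileNotFoundError(f"missing WFDB signal file: {dat}")
    with open(dat, "rb") as fh:
        raw = fh.read()
    fmt = header.signals[0].fmt
    n_sig = header.n_signals
    if fmt == 16:
        digital = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        total = header.n_samples * n_sig if header.n_samples else (len(raw) // 3) * 2
        digital = _decode_212(raw, total)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    n_frames = digital.size // n_sig
    digital = digital[: n_frames * n_sig].reshape(n_frames, n_sig)
    physical = np.empty(digital.shape, dtype=float)
    for i, sig in enumerate(header.signals):
        physical[:, i] = (digital[:, i] - sig.baseline) / sig.gain
    if header.n_samples:
        physical = physical[: header.n_samples]
    return physical


def read_annotations(path: str, extension: str = "atr"):
    """Read an MIT-format annotation file; returns (samples, symbols)."""
    base = path[:-4] if path.endswith(".hea") else path
    atr = base + "." + extension
    if not os.path.exists(atr):
        raise FileNotFoundError(f"missing WFDB annotation file: {atr}")
    with open(atr, "rb") as fh:
        words = np.frombuffer(fh.read(), dtype="<u2")
    samples, symbols = [], []
    t = 0
    i = 0
    while i < words.size:
        word = int(words[i])
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            # next two words: high then low half of a 32-bit interval
            high, low = int(words[i + 1]), int(words[i + 2])
            interval = (high << 16) | low
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (delta + 1) // 2
            continue
        t += delta
        samples.append(t)
        symbols.append(_CODE_TO_SYMBOL.get(code, "?"))
        i += 1
    return np.asarray(samples, dtype=int), symbols


def write_record(
    path: str,
    signal: np.ndarray,
    sampling_rate: float,
    gain: float = 200.0,
    units: str = "mV",
    descriptions=None,
) -> None:
    """Write a format-16 WFDB record (.hea + .dat) from physical-unit signal."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] < signal.shape[1]:
        signal = signal.T
    n_samples, n_sig = signal.shape
    record_name = os.path.basename(path)
    digital = np.rint(signal * gain).astype("<i2")
    with open(path + ".dat", "wb") as fh:
        fh.write(digital.reshape(-1).tobytes())
    lines = [f"{record_name} {n_sig} {sampling_rate:g} {n_samples}"]
    for i in range(n_sig):
        desc = descriptions[i] if descriptions else f"lead{i}"
        lines.append(f"{record_name}.dat 16 {gain:g}(0)/{units} 16 0 0 0 0 {desc}")
    with open(path + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_annotations(path: str, samples, symbols, extension: str = "atr") -> None:
    """Write MIT-format annotations; samples must be strictly increasing."""
    samples = np.asarray(samples, dtype=int)
    if samples.size and not (np.diff(samples) > 0).all():
        raise ValueError("annotation samples must be strictly increasing")
    words = []
    prev = 0
    for s, sym in zip(samples, symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unknown annotation symbol {sym!r}")
        delta = int(s) - prev
        if delta >= 1024:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = int(s)
    words.append(0)  # EOF
    with open(path + "." + extension, "wb") as fh:
        fh.write(np.asarray(words, dtype="<u2").tobytes())
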