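"""Minimal WFDB reader/writer for two-lead ECG records.

Supports the subset of the WFDB format family needed for ambulatory ECG
work: text headers (``.hea``), signal files (``.dat``) in formats 16
(16-bit little-endian) and 212 (packed 12-bit pairs, the MIT-BIH native
format), and MIT-format beat annotations (``.atr``).

Only single-segment records with all signals in one ``.dat`` file are
handled. Amplitudes are converted to millivolts via ``(adu - baseline) /
gain`` on read and the inverse on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

# MIT annotation type codes <-> display symbols (ecgcodes table).
ANNOTATION_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "'", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_ANNOTATION_CODE = {s: c for c, s in ANNOTATION_CODE_TO_SYMBOL.items()}

# Pseudo-annotation codes used by the .atr byte stream.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class WfdbFormatError(ValueError):
    """Raised when a WFDB file violates the supported subset."""


@dataclass
class SignalHeader:
    filename: str
    fmt: int
    gain: float
    baseline: int
    adc_zero: int
    description: str


def _parse_gain_field(tok: str) -> tuple[float, int | None]:
    """Parse ``gain``, ``gain(baseline)`` or ``gain(baseline)/units``."""
    units = tok.split("/", 1)[0]
    baseline = None
    if "(" in units:
        g, rest = units.split("(", 1)
        baseline = int(rest.rstrip(")"))
        units = g
    gain = float(units) if units else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def read_header(hea_path: str) -> tuple[str, int, float, int, list[SignalHeader]]:
    """Parse a ``.hea`` file -> (record name, n_sig, fs, n_samples, signals)."""
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"empty header: {hea_path}")
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = _parse_gain_field(tok[2]) if len(tok) > 2 else (200.0, None)
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalHeader(tok[0], fmt, gain, baseline, adc_zero, desc))
    if len(signals) != n_sig:
        raise WfdbFormatError(f"header lists {n_sig} signals, found {len(signals)}")
    return name, n_sig, fs, n_samples, signals


def _read_dat_16(raw: bytes, n_sig: int) -> np.ndarray:
    adu = np.frombuffer(raw, dtype="<i2")
    n = len(adu) // n_sig
    return adu[: n * n_sig].reshape(n, n_sig).astype(np.int32)


def _read_dat_212(raw: bytes, n_sig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    # sign-extend 12-bit two's complement
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(2 * len(b), dtype=np.int32)
    flat[0::2], flat[1::2] = first, second
    n = len(flat) // n_sig
    return flat[: n * n_sig].reshape(n, n_sig)


def read_signals(hea_path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a record's signals -> (T x n_sig array in mV, fs, lead names)."""
    name, n_sig, fs, n_samples, sigs = read_header(hea_path)
    fmts = {s.fmt for s in sigs}
    fnames = {s.filename for s in sigs}
    if len(fmts) != 1 or len(fnames) != 1:
        raise WfdbFormatError("mixed formats or multiple .dat files unsupported")
    fmt = fmts.pop()
    dat_path = os.path.join(os.path.dirname(hea_path), fnames.pop())
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    if fmt == 16:
        adu = _read_dat_16(raw, n_sig)
    elif fmt == 212:
        adu = _read_dat_212(raw, n_sig)
    else:
        raise WfdbFormatError(f"unsupported signal format {fmt}")
    if n_samples:
        adu = adu[:n_samples]
    mv = np.empty(adu.shape, dtype=np.float64)
    for j, s in enumerate(sigs):
        mv[:, j] = (adu[:, j] - s.baseline) / s.gain
    return mv, fs, [s.description for s in sigs]


def write_record(
    directory: str,
    record_id: str,
    signal_mv: np.ndarray,
    fs: float,
    lead_names: list[str] | None = None,
    fmt: int = 16,
    gain: float = 200.0,
    adc_zero: int = 0,
) -> str:
    """Write ``record_id.hea``/``record_id.dat``; returns the header path."""
    signal_mv = np.asarray(signal_mv, dtype=np.float64)
    if signal_mv.ndim != 2:
        raise WfdbFormatError("signal must be T x n_sig")
    t, n_sig = signal_mv.shape
    lead_names = lead_names or [f"lead{j}" for j in range(n_sig)]
    adu = np.rint(signal_mv * gain + adc_zero).astype(np.int32)
    if fmt == 16:
        lo, hi = -32768, 32767
    elif fmt == 212:
        lo, hi = -2048, 2047
    else:
        raise WfdbFormatError(f"unsupported signal format {fmt}")
    adu = np.clip(adu, lo, hi)
    os.makedirs(directory, exist_ok=True)
    dat_name = f"{record_id}.dat"
    with open(os.path.join(directory, dat_name), "wb") as fh:
        if fmt == 16:
            fh.write(adu.astype("<i2").tobytes())
        else:
            flat = adu.reshape(-1)
            if len(flat) % 2:
                flat = np.append(flat, 0)
            a, b = flat[0::2] & 0xFFF, flat[1::2] & 0xFFF
            packed = np.empty((len(a), 3), dtype=np.uint8)
            packed[:, 0] = a & 0xFF
            packed[:, 1] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
            packed[:, 2] = b & 0xFF
            fh.write(packed.tobytes())
    hea_path = os.path.join(directory, f"{record_id}.hea")
    with open(hea_path, "w") as fh:
        fh.write(f"{record_id} {n_sig} {fs:g} {t}\n")
        for j in range(n_sig):
            fh.write(
                f"{dat_name} {fmt} {gain:g}({adc_zero})/mV 16 {adc_zero} "
                f"{adu[0, j]} 0 0 {lead_names[j]}\n"
            )
    return hea_path


def read_annotations(atr_path: str) -> tuple[np.ndarray, list[str]]:
    """Read MIT-format annotations -> (sample indices, symbols)."""
    with open(atr_path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw[: (len(raw) // 2) * 2], dtype="<u2")
    samples: list[int] = []
    symbols: list[str] = []
    time = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == _SKIP:
            if i + 2 >= len(words):
                raise WfdbFormatError("truncated SKIP annotation")
            # 4-byte interval, high 16 bits first (PDP-11 long order)
            time += (int(words[i + 1]) << 16) | int(words[i + 2])
            i += 3
            continue
        if code == _AUX:
            n_aux = interval
            i += 1 + (n_aux + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        time += interval
        samples.append(time)
        symbols.append(ANNOTATION_CODE_TO_SYMBOL.get(code, "?"))
        i += 1
    return np.asarray(samples, dtype=np.int64), symbols


def write_annotations(atr_path: str, samples: np.ndarray, symbols: list[str]) -> None:
    """Write MIT-format annotations; samples must be strictly increasing."""
    samples = np.asarray(samples, dtype=np.int64)
    if len(samples) != len(symbols):
        raise ValueError("samples and symbols differ in length")
    if np.any(np.diff(samples) <= 0):
        raise ValueError("annotation samples must be strictly increasing")
    out = bytearray()
    prev = 0
    for s, sym in zip(samples, symbols):
        code = SYMBOL_TO_ANNOTATION_CODE.get(sym)
        if code is None:
            raise ValueError(f"unknown annotation symbol {sym!r}")
        interval = int(s) - prev
        if interval > 1023:
            out += int(_SKIP << 10).to_bytes(2, "little")
            out += ((interval >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (interval & 0xFFFF).to_bytes(2, "little")
            interval = 0
        out += ((code << 10) | interval).to_bytes(2, "little")
        prev = int(s)
    out += (0).to_bytes(2, "little")  # EOF
    with open(atr_path, "wb") as fh:
        fh.write(bytes(out))
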