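"""Minimal EDF reader/writer (16-bit, single sampling rate).

Covers the subset of EDF needed here: equal sampling rate on all channels,
microvolt physical units, 1-second data records.  The true per-channel sample
count is stored in each signal's reserved header field so that record padding
can be stripped on read.
"""

from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, samples: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a (channels, time) microvolt matrix as a 16-bit EDF file."""
    samples = np.asarray(samples, dtype=float)
    n_ch, n_samp = samples.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = max(1, math.ceil(n_samp / spr))

    # symmetric physical range per channel, never zero-width
    absmax = np.maximum(np.abs(samples).max(axis=1), 1e-6)
    phys_min, phys_max = -absmax, absmax

    header = b""
    header += _field("0", 8)
    header += _field("synthetic", 80)
    header += _field("erdpipe", 80)
    now = _dt.datetime(2000, 1, 1)
    header += _field(now.strftime("%d.%m.%y"), 8)
    header += _field(now.strftime("%H.%M.%S"), 8)
    header += _field(str(256 + 256 * n_ch), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)

    def sig_fields(fmt, width):
        return b"".join(_field(fmt(i), width) for i in range(n_ch))

    header += sig_fields(lambda i: labels[i], 16)
    header += sig_fields(lambda i: "", 80)
    header += sig_fields(lambda i: "uV", 8)
    header += sig_fields(lambda i: f"{phys_min[i]:.6g}"[:8], 8)
    header += sig_fields(lambda i: f"{phys_max[i]:.6g}"[:8], 8)
    header += sig_fields(lambda i: str(_DIG_MIN), 8)
    header += sig_fields(lambda i: str(_DIG_MAX), 8)
    header += sig_fields(lambda i: "", 80)
    header += sig_fields(lambda i: str(spr), 8)
    header += sig_fields(lambda i: f"n={n_samp}", 32)

    # re-read the physical bounds exactly as a reader will parse them, so the
    # digitization uses identical scaling on both sides
    pmin = np.array([float(f"{phys_min[i]:.6g}"[:8]) for i in range(n_ch)])
    pmax = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(n_ch)])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = samples
    dig = np.rint((padded - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(dig[:, sl].tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file written by :func:`write_edf` (or compatible).

    Returns (samples in microvolts, fs, labels).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("truncated EDF header")

    def s(a, b):
        return raw[a:b].decode("ascii", errors="replace").strip()

    n_rec = int(s(236, 244))
    rec_dur = float(s(244, 252))
    n_ch = int(s(252, 256))
    off = 256

    def sig(width):
        nonlocal off
        vals = [s(off + i * width, off + (i + 1) * width) for i in range(n_ch)]
        off += n_ch * width
        return vals

    labels = sig(16)
    sig(80)  # transducer
    sig(8)  # physical dimension
    pmin = np.array([float(v) for v in sig(8)])
    pmax = np.array([float(v) for v in sig(8)])
    dmin = np.array([float(v) for v in sig(8)])
    dmax = np.array([float(v) for v in sig(8)])
    sig(80)  # prefilter
    spr = [int(v) for v in sig(8)]
    reserved = sig(32)

    if len(set(spr)) != 1:
        raise ValueError("only uniform sampling rates are supported")
    spr0 = spr[0]
    fs = spr0 / rec_dur

    data = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_rec * n_ch * spr0
    if data.size < expected:
        raise ValueError("EDF data section shorter than header declares")
    data = data[:expected].reshape(n_rec, n_ch, spr0)
    dig = np.concatenate([data[r] for r in range(n_rec)], axis=1).astype(float)

    scale = (pmax - pmin) / (dmax - dmin)
    phys = (dig - dmin[:, None]) * scale[:, None] + pmin[:, None]

    # strip record padding if the writer recorded the true length
    n_true = None
    for r in reserved:
        if r.startswith("n="):
            n_true = int(r[2:])
            break
    if n_true is not None:
        phys = phys[:, :n_true]
    return phys, fs, labels
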