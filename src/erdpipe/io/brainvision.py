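"""BrainVision (.vhdr/.eeg/.vmrk) reader and a writer for test round-trips.

Supports multiplexed binary data in IEEE_FLOAT_32 or INT_16 with per-channel
resolution, which is the dialect produced by BrainAmp-family amplifiers.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np

_FORMATS = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}


def _read_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    text = path.read_text(encoding="utf-8", errors="replace")
    # strip the signature line ("Brain Vision Data Exchange ...")
    lines = [ln for ln in text.splitlines() if not ln.startswith("Brain Vision")]
    cp.read_string("\n".join(lines))
    return cp


def read_brainvision(vhdr_path) -> tuple[np.ndarray, float, list[str]]:
    """Read a BrainVision triplet; returns (samples in microvolts, fs, labels)."""
    vhdr_path = Path(vhdr_path)
    cp = _read_ini(vhdr_path)
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])  # interval is in microseconds

    binfmt = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if binfmt not in _FORMATS:
        raise ValueError(f"unsupported BinaryFormat {binfmt!r}")

    labels, resolutions = [], []
    chinfo = cp["Channel Infos"]
    for i in range(1, n_ch + 1):
        parts = chinfo[f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    data_file = vhdr_path.parent / common["DataFile"]
    raw = np.fromfile(data_file, dtype=_FORMATS[binfmt])
    if raw.size % n_ch:
        raise ValueError("data length is not a multiple of the channel count")
    samples = raw.reshape(-1, n_ch).T.astype(float)
    samples *= np.asarray(resolutions)[:, None]
    return samples, fs, labels


def read_brainvision_markers(vmrk_path, fs: float) -> list[tuple[int, str]]:
    """Return (position sample, description) for each stimulus marker."""
    cp = _read_ini(Path(vmrk_path))
    out = []
    for key, val in cp["Marker Infos"].items():
        if not key.lower().startswith("mk"):
            continue
        parts = val.split(",")
        if len(parts) < 3 or parts[0] != "Stimulus":
            continue
        # BrainVision positions are 1-based
        out.append((int(parts[2]) - 1, parts[1]))
    out.sort()
    return out


def write_brainvision(vhdr_path, samples: np.ndarray, fs: float,
                      labels: list[str],
                      markers: list[tuple[int, str]] | None = None) -> None:
    """Write a float32 multiplexed BrainVision triplet."""
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.stem
    eeg_name, vmrk_name = f"{stem}.eeg", f"{stem}.vmrk"
    samples = np.asarray(samples, dtype=float)
    n_ch = samples.shape[0]
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")

    hdr = ["Brain Vision Data Exchange Header File Version 1.0", "",
           "[Common Infos]",
           f"DataFile={eeg_name}",
           f"MarkerFile={vmrk_name}",
           "DataFormat=BINARY",
           "DataOrientation=MULTIPLEXED",
           f"NumberOfChannels={n_ch}",
           f"SamplingInterval={1e6 / fs:g}", "",
           "[Binary Infos]",
           "BinaryFormat=IEEE_FLOAT_32", "",
           "[Channel Infos]"]
    for i, lb in enumerate(labels, start=1):
        hdr.append(f"Ch{i}={lb},,1,uV")
    vhdr_path.write_text("\n".join(hdr) + "\n", encoding="utf-8")

    samples.T.astype("<f4").tofile(vhdr_path.parent / eeg_name)

    mrk = ["Brain Vision Data Exchange Marker File Version 1.0", "",
           "[Common Infos]",
           f"DataFile={eeg_name}", "",
           "[Marker Infos]"]
    for i, (pos, desc) in enumerate(markers or [], start=1):
        mrk.append(f"Mk{i}=Stimulus,{desc},{pos + 1},1,0")
    (vhdr_path.parent / vmrk_name).write_text("\n".join(mrk) + "\n", encoding="utf-8")
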