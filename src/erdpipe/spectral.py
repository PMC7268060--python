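"""Band power, ERD extraction, hemisphere mapping and SMR calibration.

ERD is the proportional band-power change of a movement window M against a
reference window R::

    ERD = (M - R) / R * 100  [%]

More negative values mean stronger desynchronization.  Welch parameters
default to 1-s Hann windows with 50% overlap (1 Hz resolution); band edges
are inclusive on both sides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from erdpipe.io.recording import EpochedTrials

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")


ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 25.0)
PRESET_BANDS = {"alpha": ALPHA, "beta": BETA}

LEFT_MOTOR = ("C3", "Cp3", "P3")
RIGHT_MOTOR = ("C4", "Cp4", "P4")

CENTRAL_PARIETAL = ("C3", "Cz", "C4", "Cp3", "Cp4", "P3", "Pz", "P4")


@dataclass(frozen=True)
class ERDSample:
    subject: str
    session_index: int
    hemisphere: str  # ipsilesional | contralesional
    band: str
    erd_percent: float
    n_trials_used: int


@dataclass
class SMRCalibration:
    bin_centers: np.ndarray
    r2: np.ndarray
    selected_band: tuple[float, float]
    selected_electrodes: list[str] = field(default_factory=list)

    @property
    def peak_frequency(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.r2))])


def erd_percent(m: float, r: float) -> float:
    """The core ERD arithmetic on precomputed powers."""
    if r == 0:
        raise ZeroDivisionError("reference power is zero; ERD undefined")
    return (m - r) / r * 100.0


def band_power(segment: np.ndarray, band: BandDefinition, fs: float,
               nperseg_s: float = 1.0) -> np.ndarray:
    """Mean Welch PSD over the band's bins, per channel.

    Returns one value per channel (mean of the PSD over all frequency bins
    with ``f_lo <= f <= f_hi``, edges inclusive).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.f_hi:g} Hz is not below "
            f"Nyquist ({fs / 2:g} Hz)"
        )
    nperseg = min(int(round(nperseg_s * fs)), segment.shape[1])
    if segment.shape[1] < nperseg or nperseg < 8:
        raise ValueError("segment shorter than one Welch window")
    freqs, psd = sps.welch(segment, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, axis=-1)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not mask.any():
        raise ValueError("band contains no PSD bins at this resolution")
    return psd[:, mask].mean(axis=1)


def map_hemispheres(lesion_side: str) -> dict[str, tuple[str, ...]]:
    """Channel sets per hemisphere role, given the lesioned side."""
    if lesion_side == "left":
        return {"ipsilesional": LEFT_MOTOR, "contralesional": RIGHT_MOTOR}
    if lesion_side == "right":
        return {"ipsilesional": RIGHT_MOTOR, "contralesional": LEFT_MOTOR}
    raise ValueError(f"unknown lesion side {lesion_side!r}")


def compute_erd(trials: EpochedTrials, band: BandDefinition,
                channels, hemisphere: str = "",
                method: str = "per_trial") -> ERDSample:
    """Session ERD from artifact-free trials over one hemisphere's channels.

    Per trial, M is the movement-phase band power and R the rest (reference)
    band power, each averaged over the hemisphere's three channels; no other
    spatial filtering is applied.  ``method='per_trial'`` averages per-trial
    ERD values over the session (default); ``method='pooled'`` averages the
    powers across trials first and applies the ERD formula once.
    """
    if method not in ("per_trial", "pooled"):
        raise ValueError("method must be 'per_trial' or 'pooled'")
    keep = ~trials.removed_mask()
    if not keep.any():
        raise ValueError("no artifact-free trials available")
    idx = [trials.channel_index(c) for c in channels]
    rest = trials.rest[keep][:, idx, :]
    move = trials.move[keep][:, idx, :]

    m_vals, r_vals = [], []
    for k in range(rest.shape[0]):
        r_vals.append(band_power(rest[k], band, trials.fs).mean())
        m_vals.append(band_power(move[k], band, trials.fs).mean())
    m_vals = np.asarray(m_vals)
    r_vals = np.asarray(r_vals)

    if method == "pooled":
        erd = erd_percent(m_vals.mean(), r_vals.mean())
        n_used = len(m_vals)
    else:
        ok = r_vals > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} trial(s) with zero reference power skipped"
            )
        if not ok.any():
            raise ValueError("all trials have zero reference power")
        erd = float(np.mean((m_vals[ok] - r_vals[ok]) / r_vals[ok] * 100.0))
        n_used = int(ok.sum())

    return ERDSample(
        subject=trials.subject_id,
        session_index=trials.session_index,
        hemisphere=hemisphere,
        band=band.name,
        erd_percent=float(erd),
        n_trials_used=n_used,
    )


def erd_table(samples: list[ERDSample]) -> pd.DataFrame:
    """Tidy table of ERD samples (one row per subject/session/hemisphere/band)."""
    return pd.DataFrame(
        [
            dict(subject=s.subject, session=s.session_index,
                 hemisphere=s.hemisphere, band=s.band,
                 erd_percent=s.erd_percent, n_trials=s.n_trials_used)
            for s in samples
        ]
    )


def calibrate_smr(rest_segments, move_segments, fs: float,
                  scan_range: tuple[float, float] = (6.0, 30.0),
                  bin_hz: float = 2.0,
                  channel_labels=None,
                  rel_threshold: float = 0.8) -> SMRCalibration:
    """Individual SMR-band calibration from rest/move segment discriminability.

    For each ``bin_hz``-wide bin in the scan range, r^2 is the squared
    point-biserial correlation between the condition label and log band power
    across segments (log for variance stabilization).  The selected band is
    the contiguous run of bins around the maximum whose r^2 stays above
    ``rel_threshold * max``; electrodes are ranked by per-channel r^2 within
    the selected band.
    """
    if len(rest_segments) < 10 or len(move_segments) < 10:
        raise ValueError("need at least 10 segments per condition")
    lo, hi = scan_range
    if hi >= fs / 2:
        raise ValueError("scan range exceeds Nyquist frequency")
    edges = np.arange(lo, hi, bin_hz)
    bands = [BandDefinition(f"scan{e:g}", e, min(e + bin_hz, hi)) for e in edges]
    centers = np.array([(b.f_lo + b.f_hi) / 2 for b in bands])

    labels = np.array([0] * len(rest_segments) + [1] * len(move_segments))
    segs = list(rest_segments) + list(move_segments)
    n_ch = np.atleast_2d(segs[0]).shape[0]

    # per segment, per band, per channel log power
    logp = np.empty((len(segs), len(bands), n_ch))
    for si, seg in enumerate(segs):
        for bi, b in enumerate(bands):
            logp[si, bi] = np.log(band_power(seg, b, fs) + 1e-300)

    def _r2(x: np.ndarray) -> float:
        if np.allclose(x.std(), 0):
            return 0.0
        return float(np.corrcoef(labels, x)[0, 1] ** 2)

    r2_mean = np.array([_r2(logp[:, bi].mean(axis=1)) for bi in range(len(bands))])

    peak = int(np.argmax(r2_mean))
    thresh = rel_threshold * r2_mean[peak]
    left = peak
    while left > 0 and r2_mean[left - 1] >= thresh:
        left -= 1
    right = peak
    while right < len(bands) - 1 and r2_mean[right + 1] >= thresh:
        right += 1
    selected = (bands[left].f_lo, bands[right].f_hi)

    electrodes: list[str] = []
    if channel_labels is not None:
        cp = [c for c in channel_labels if c in CENTRAL_PARIETAL]
        per_ch = {}
        for c in cp:
            ci = list(channel_labels).index(c)
            x = logp[:, left:right + 1, ci].mean(axis=1)
            per_ch[c] = _r2(x)
        electrodes = sorted(per_ch, key=per_ch.get, reverse=True)

    return SMRCalibration(
        bin_centers=centers, r2=r2_mean, selected_band=selected,
        selected_electrodes=electrodes,
    )
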