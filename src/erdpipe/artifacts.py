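"""Automated artifact-detection cascade and exclusion rules.

Order of operations on a session: EOG component removal on the continuous
EEG, then per-trial detectors (high-frequency cranial EMG, broadband offset,
limb-EMG contraction timing), then session- and subject-level exclusion.

All z-score statistics (mean/SD per channel) are computed over the
concatenated trials of one session; thresholds use a strict ``>``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA

from erdpipe.io.recording import ContinuousRecording, EpochedTrials

logger = logging.getLogger(__name__)

FLAG_NAMES = ("hf_emg", "offset", "emg_rest_paretic", "emg_move_healthy")


@dataclass
class RejectionConfig:
    hf_band: tuple[float, float] = (110.0, 140.0)
    hf_z_threshold: float = 4.0
    offset_z_threshold: float = 20.0
    emg_wl_sd_threshold: float = 3.0
    emg_wl_window_s: float = 0.25
    min_trials_per_session: int = 16
    min_fraction: float = 0.10
    max_removed_sessions_fraction: float = 0.5
    eog_component_corr_threshold: float = 0.7
    ica_seed: int = 97
    zscore_signed: bool = True  # z of signed (not rectified) filtered samples

    def __post_init__(self) -> None:
        for name in ("hf_z_threshold", "offset_z_threshold",
                     "emg_wl_sd_threshold", "emg_wl_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must lie in (0, 1)")
        if not 0 < self.eog_component_corr_threshold < 1:
            raise ValueError("eog_component_corr_threshold must lie in (0, 1)")


@dataclass
class SessionReport:
    subject: str
    session_index: int
    trials_in: int
    trials_removed: int
    flags: pd.DataFrame  # one row per trial, one bool column per flag
    removed_eog_components: list[int] = field(default_factory=list)
    excluded: bool = False

    @property
    def trials_out(self) -> int:
        return self.trials_in - self.trials_removed


@dataclass
class RejectionReport:
    sessions: list[SessionReport]
    subject_excluded: dict[str, bool]
    sessions_removed: dict[str, int]

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            rows.append(dict(
                subject=s.subject, session=s.session_index,
                trials_in=s.trials_in, trials_removed=s.trials_removed,
                trials_out=s.trials_out, session_excluded=s.excluded,
                subject_excluded=self.subject_excluded.get(s.subject, False),
            ))
        return pd.DataFrame(rows)


def remove_eog(rec: ContinuousRecording, config: RejectionConfig):
    """Zero independent EEG components correlated with any EOG channel.

    Returns the cleaned recording and the removed component indices.  The
    EOG channels themselves are left untouched.
    """
    eeg_idx = rec.pick("EEG")
    eog_idx = rec.pick("EOG")
    if len(eog_idx) == 0:
        raise ValueError("recording has no EOG channel; cannot identify components")

    X = rec.samples[eeg_idx]  # (n_eeg, T)
    # fit the unmixing on a strided subsample (plenty for 16 components),
    # then apply it to the full recording; keeps long sessions tractable
    stride = max(1, X.shape[1] // 20_000)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=len(eeg_idx), whiten="unit-variance",
                          random_state=config.ica_seed, max_iter=300, tol=1e-4)
            ica.fit(np.ascontiguousarray(X[:, ::stride].T))
    except Exception as exc:  # rank-deficient or otherwise degenerate data
        raise RuntimeError(
            "ICA decomposition failed (possibly rank-deficient data); "
            "check for duplicate or flat channels"
        ) from exc
    sources = (X.T - ica.mean_) @ ica.components_.T  # (T, n_comp)

    removed = []
    eog = rec.samples[eog_idx]
    for comp in range(sources.shape[1]):
        s = sources[:, comp]
        if np.allclose(s.std(), 0):
            continue
        for row in eog:
            if np.allclose(row.std(), 0):
                continue
            r = abs(float(np.corrcoef(s, row)[0, 1]))
            if r > config.eog_component_corr_threshold:
                removed.append(comp)
                break
    logger.info("EOG removal: zeroing components %s", removed)

    cleaned = sources.copy()
    cleaned[:, removed] = 0.0
    X_clean = ica.inverse_transform(cleaned).T

    out = ContinuousRecording(
        samples=rec.samples.copy(), fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        events=list(rec.events), subject_id=rec.subject_id,
        session_index=rec.session_index, lesion_side=rec.lesion_side,
        emg_sides=dict(rec.emg_sides),
    )
    out.samples[eeg_idx] = X_clean
    return out, removed


def _session_z(data: np.ndarray, signed: bool) -> np.ndarray:
    """Per-channel z over a (n_trials, n_channels, n_samples) stack."""
    if not signed:
        data = np.abs(data)
    mean = data.mean(axis=(0, 2), keepdims=True)
    sd = data.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (data - mean) / sd


def _flag_mean_z(data: np.ndarray, threshold: float, signed: bool) -> np.ndarray:
    z = _session_z(data, signed)
    mean_z = z.mean(axis=1)  # average across channels, per sample
    # deflections can go either way; threshold the magnitude (strict >)
    return (np.abs(mean_z) > threshold).any(axis=1)


def detect_hf_emg(trials: EpochedTrials, config: RejectionConfig) -> np.ndarray:
    """Flag trials with high-frequency (cranial EMG) activity.

    EEG channels are band-pass filtered in ``hf_band``, z-scored per channel
    against the whole session, z averaged across channels per sample; a trial
    is flagged when any sample's averaged z strictly exceeds the threshold.
    """
    lo, hi = config.hf_band
    if trials.fs < 2 * hi:
        raise ValueError("sampling rate too low for the high-frequency band")
    eeg = [i for i, k in enumerate(trials.channel_kinds) if k == "EEG"]
    data = trials.concatenated()[:, eeg, :]
    if data.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=trials.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, data, axis=-1)
    return _flag_mean_z(filtered, config.hf_z_threshold, config.zscore_signed)


def detect_offset(trials: EpochedTrials, config: RejectionConfig) -> np.ndarray:
    """Flag trials with broadband offset artifacts (threshold 20 SD)."""
    eeg = [i for i, k in enumerate(trials.channel_kinds) if k == "EEG"]
    data = trials.concatenated()[:, eeg, :]
    if data.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    return _flag_mean_z(data, config.offset_z_threshold, config.zscore_signed)


def waveform_length(segment: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Waveform length per non-overlapping window.

    WL of a window is the sum of absolute successive-sample differences
    within it.  Returns one value per full window.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    if segment.size == 0:
        raise ValueError("empty segment")
    win = int(round(window_s * fs))
    if win < 2 or segment.size < win:
        raise ValueError("segment shorter than one window")
    n_win = segment.size // win
    out = np.empty(n_win)
    for w in range(n_win):
        chunk = segment[w * win:(w + 1) * win]
        out[w] = np.abs(np.diff(chunk)).sum()
    return out


def detect_emg_movement(trials: EpochedTrials, config: RejectionConfig):
    """Flag trials with mistimed limb-muscle contractions.

    A contraction is a waveform-length window strictly above
    ``mean + k*SD`` of that channel's session WL distribution.  A trial is
    flagged when a paretic-side contraction overlaps the rest period
    (``emg_rest_paretic``) or a healthy-side contraction overlaps the
    movement phase (``emg_move_healthy``).
    """
    emg = [i for i, k in enumerate(trials.channel_kinds) if k == "EMG"]
    if emg and not trials.emg_sides:
        raise ValueError("EMG channels present but no paretic/healthy side labels")
    n = trials.n_trials
    flag_rest = np.zeros(n, dtype=bool)
    flag_move = np.zeros(n, dtype=bool)
    if not emg or n == 0:
        return flag_rest, flag_move

    phases = ("rest", "prep", "move")
    for ci in emg:
        label = trials.channel_labels[ci]
        side = trials.emg_sides.get(label)
        if side not in ("paretic", "healthy"):
            raise ValueError(f"EMG channel {label!r} lacks a paretic/healthy label")
        # WL windows per phase per trial; session stats pool everything
        wl_by = {ph: [] for ph in phases}
        for t in range(n):
            for ph in phases:
                seg = getattr(trials, ph)[t, ci, :]
                if seg.size >= int(round(config.emg_wl_window_s * trials.fs)):
                    wl_by[ph].append(
                        waveform_length(seg, config.emg_wl_window_s, trials.fs)
                    )
                else:
                    wl_by[ph].append(np.empty(0))
        pooled = np.concatenate([w for ph in phases for w in wl_by[ph]])
        if pooled.size == 0:
            continue
        thr = pooled.mean() + config.emg_wl_sd_threshold * pooled.std()
        check_phase = "rest" if side == "paretic" else "move"
        target = flag_rest if side == "paretic" else flag_move
        for t in range(n):
            if (wl_by[check_phase][t] > thr).any():
                target[t] = True
    return flag_rest, flag_move


def run_detection(trials: EpochedTrials, config: RejectionConfig,
                  removed_eog_components=None) -> SessionReport:
    """Run all trial-level detectors on a session and record flags."""
    hf = detect_hf_emg(trials, config)
    off = detect_offset(trials, config)
    emg_rest, emg_move = detect_emg_movement(trials, config)
    trials.flags = {
        "hf_emg": hf, "offset": off,
        "emg_rest_paretic": emg_rest, "emg_move_healthy": emg_move,
    }
    flags = pd.DataFrame({
        "trial": trials.trial_index,
        "hf_emg": hf, "offset": off,
        "emg_rest_paretic": emg_rest, "emg_move_healthy": emg_move,
    })
    removed = int(trials.removed_mask().sum())
    for row in flags.itertuples(index=False):
        reasons = [f for f in FLAG_NAMES if getattr(row, f)]
        if reasons:
            logger.info("trial %d flagged: %s", row.trial, ", ".join(reasons))
    return SessionReport(
        subject=trials.subject_id, session_index=trials.session_index,
        trials_in=trials.n_trials, trials_removed=removed, flags=flags,
        removed_eog_components=list(removed_eog_components or []),
    )


def session_min_trials(trials_in: int, config: RejectionConfig) -> int:
    """Minimum surviving-trial count for a session to be kept."""
    return max(config.min_trials_per_session,
               math.ceil(config.min_fraction * trials_in))


def apply_exclusions(reports: list[SessionReport],
                     config: RejectionConfig) -> RejectionReport:
    """Apply session- and subject-level exclusion rules.

    A session is excluded when fewer trials remain than
    ``max(min_trials, ceil(min_fraction * trials_in))``; a subject is excluded
    when at least half (``ceil(total/2)``) of their sessions were removed.
    """
    by_subject: dict[str, list[SessionReport]] = {}
    for rep in reports:
        rep.excluded = rep.trials_out < session_min_trials(rep.trials_in, config)
        by_subject.setdefault(rep.subject, []).append(rep)

    subject_excluded, sessions_removed = {}, {}
    for subject, reps in by_subject.items():
        total = len(reps)
        removed = sum(r.excluded for r in reps)
        sessions_removed[subject] = removed
        cutoff = math.ceil(config.max_removed_sessions_fraction * total)
        subject_excluded[subject] = removed >= cutoff
        if subject_excluded[subject]:
            logger.info("subject %s excluded: %d of %d sessions removed",
                        subject, removed, total)
    return RejectionReport(
        sessions=reports, subject_excluded=subject_excluded,
        sessions_removed=sessions_removed,
    )
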