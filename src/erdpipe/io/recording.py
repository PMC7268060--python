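"""Core recording containers and epoching.

Time convention: sample indices are 0-based and all epochs are half-open
intervals ``[start, end)`` in samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 16-channel scalp montage used throughout.
EEG_MONTAGE = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "Cp3", "Cp4", "P3", "Pz", "P4", "Oz",
)

#: Channels required for hemisphere-level ERD extraction.
MOTOR_CHANNELS = ("C3", "Cp3", "P3", "C4", "Cp4", "P4")

VALID_KINDS = ("EEG", "EOG", "EMG")


@dataclass(frozen=True)
class TrialEvent:
    """One trial marker.

    ``onset`` is the sample index of the ITI/preparation boundary, i.e. the
    first sample of the preparation phase.  The reference (rest) window is the
    last 4 s of the preceding inter-trial interval, ``[onset - 4*fs, onset)``.
    """

    onset: int
    iti_s: float
    prep_s: float = 2.0
    move_s: float = 5.0


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording in microvolts."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]  # EEG | EOG | EMG, parallel to labels
    events: list[TrialEvent] = field(default_factory=list)
    subject_id: str = ""
    session_index: int = 0
    lesion_side: str = "left"
    emg_sides: dict[str, str] = field(default_factory=dict)  # label -> paretic|healthy

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.channel_kinds) != len(self.channel_labels):
            raise ValueError("one kind per channel required")
        for k in self.channel_kinds:
            if k not in VALID_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")
        onsets = [ev.onset for ev in self.events]
        if onsets != sorted(onsets) or len(set(onsets)) != len(onsets):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def pick(self, kind: str) -> np.ndarray:
        """Row indices of all channels of the given kind."""
        return np.array(
            [i for i, k in enumerate(self.channel_kinds) if k == kind], dtype=int
        )

    def get(self, labels: list[str]) -> np.ndarray:
        return self.samples[[self.channel_index(lb) for lb in labels]]


@dataclass
class EpochedTrials:
    """Phase-segmented trials of one session.

    ``rest`` holds the last 4 s of each ITI, ``prep`` the 2 s preparation
    phase and ``move`` the 5 s movement phase, each as a
    ``(n_trials, n_channels, n_phase_samples)`` array.
    """

    rest: np.ndarray
    prep: np.ndarray
    move: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]
    trial_index: list[int]
    subject_id: str = ""
    session_index: int = 0
    lesion_side: str = "left"
    emg_sides: dict[str, str] = field(default_factory=dict)
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    dropped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.rest.shape[0]

    def concatenated(self) -> np.ndarray:
        """Full trials, phases joined: (n_trials, n_channels, total_samples)."""
        return np.concatenate([self.rest, self.prep, self.move], axis=2)

    def phase_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open sample spans of each phase inside a concatenated trial."""
        r = self.rest.shape[2]
        p = self.prep.shape[2]
        m = self.move.shape[2]
        return {"rest": (0, r), "prep": (r, r + p), "move": (r + p, r + p + m)}

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def removed_mask(self) -> np.ndarray:
        """Boolean mask of trials carrying at least one artifact flag."""
        mask = np.zeros(self.n_trials, dtype=bool)
        for arr in self.flags.values():
            mask |= np.asarray(arr, dtype=bool)
        return mask


REST_S = 4.0  # fixed reference-window duration


def epoch_trials(rec: ContinuousRecording) -> EpochedTrials:
    """Cut a continuous recording into phase-labeled trials.

    Trials with an ITI shorter than 4 s are dropped (the reference window has
    fixed length), as are trials whose phase spans fall outside the
    recording; both are logged with a reason.
    """
    fs = rec.fs
    n_rest = int(round(REST_S * fs))
    if not rec.events:
        warnings.warn("recording contains no events; returning empty trials")
        empty = np.empty((0, len(rec.channel_labels), 0))
        return EpochedTrials(
            rest=np.empty((0, len(rec.channel_labels), n_rest)),
            prep=empty, move=empty, fs=fs,
            channel_labels=list(rec.channel_labels),
            channel_kinds=list(rec.channel_kinds),
            trial_index=[],
            subject_id=rec.subject_id, session_index=rec.session_index,
            lesion_side=rec.lesion_side, emg_sides=dict(rec.emg_sides),
        )

    rest_segs, prep_segs, move_segs, kept, dropped = [], [], [], [], []
    for i, ev in enumerate(rec.events):
        if ev.iti_s < REST_S:
            dropped.append((i, f"iti {ev.iti_s:g}s < {REST_S:g}s"))
            logger.info("trial %d dropped: ITI %.2fs below %.0fs", i, ev.iti_s, REST_S)
            continue
        n_prep = int(round(ev.prep_s * fs))
        n_move = int(round(ev.move_s * fs))
        r0, r1 = ev.onset - n_rest, ev.onset
        m1 = ev.onset + n_prep + n_move
        if r0 < 0 or m1 > rec.n_samples:
            dropped.append((i, "phase span outside recording"))
            logger.info("trial %d dropped: outside recording bounds", i)
            continue
        rest_segs.append(rec.samples[:, r0:r1])
        prep_segs.append(rec.samples[:, r1:r1 + n_prep])
        move_segs.append(rec.samples[:, r1 + n_prep:m1])
        kept.append(i)

    def _stack(segs, width):
        if not segs:
            return np.empty((0, len(rec.channel_labels), width))
        return np.stack(segs)

    return EpochedTrials(
        rest=_stack(rest_segs, n_rest),
        prep=_stack(prep_segs, 0),
        move=_stack(move_segs, 0),
        fs=fs,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        trial_index=kept,
        subject_id=rec.subject_id,
        session_index=rec.session_index,
        lesion_side=rec.lesion_side,
        emg_sides=dict(rec.emg_sides),
        dropped=dropped,
    )


def infer_channel_kinds(labels: list[str]) -> list[str]:
    """Heuristic channel-kind assignment from labels (overridable via config)."""
    kinds = []
    for lb in labels:
        u = lb.upper()
        if u.startswith("EOG"):
            kinds.append("EOG")
        elif u.startswith("EMG"):
            kinds.append("EMG")
        else:
            kinds.append("EEG")
    return kinds


def load_events_tsv(path, fs: float) -> list[TrialEvent]:
    """Read a sidecar events table with columns onset_s, iti_s [, prep_s, move_s]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "iti_s"):
        if col not in df.columns:
            raise ValueError(f"events file missing required column {col!r}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            TrialEvent(
                onset=int(round(row.onset_s * fs)),
                iti_s=float(row.iti_s),
                prep_s=float(getattr(row, "prep_s", 2.0)),
                move_s=float(getattr(row, "move_s", 5.0)),
            )
        )
    return events


def save_events_tsv(events: list[TrialEvent], fs: float, path) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [ev.onset / fs for ev in events],
            "iti_s": [ev.iti_s for ev in events],
            "prep_s": [ev.prep_s for ev in events],
            "move_s": [ev.move_s for ev in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)
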