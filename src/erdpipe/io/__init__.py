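"""Recording I/O: format readers, channel-role mapping, epoching."""

from __future__ import annotations

from pathlib import Path

import yaml

from erdpipe.io.brainvision import (
    read_brainvision,
    read_brainvision_markers,
    write_brainvision,
)
from erdpipe.io.edf import read_edf, write_edf
from erdpipe.io.recording import (
    EEG_MONTAGE,
    MOTOR_CHANNELS,
    ContinuousRecording,
    EpochedTrials,
    TrialEvent,
    epoch_trials,
    infer_channel_kinds,
    load_events_tsv,
    save_events_tsv,
)

__all__ = [
    "ContinuousRecording", "EpochedTrials", "TrialEvent",
    "EEG_MONTAGE", "MOTOR_CHANNELS",
    "epoch_trials", "infer_channel_kinds", "read_recording",
    "load_events_tsv", "save_events_tsv",
    "read_edf", "write_edf",
    "read_brainvision", "read_brainvision_markers", "write_brainvision",
]

#: channels that downstream ERD extraction cannot do without
DEFAULT_REQUIRED = list(MOTOR_CHANNELS)


def read_recording(path, format: str, *, events=None, channel_config=None,
                   subject_id: str = "", session_index: int = 0,
                   lesion_side: str = "left",
                   required_channels=None) -> ContinuousRecording:
    """Read an EDF or BrainVision recording into a :class:`ContinuousRecording`.

    Parameters
    ----------
    path
        EDF file or BrainVision ``.vhdr`` header.
    format
        ``"edf"`` or ``"brainvision"``.
    events
        Sidecar events TSV path (onset_s, iti_s columns), a list of
        :class:`TrialEvent`, or ``None``.
    channel_config
        YAML path or dict with optional keys ``kinds`` (label -> EEG/EOG/EMG),
        ``emg_sides`` (label -> paretic/healthy) and ``required`` (labels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        samples, fs, labels = read_edf(path)
    elif format == "brainvision":
        samples, fs, labels = read_brainvision(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'brainvision'")

    cfg = {}
    if channel_config is not None:
        if isinstance(channel_config, (str, Path)):
            cfg = yaml.safe_load(Path(channel_config).read_text()) or {}
        else:
            cfg = dict(channel_config)

    kinds = infer_channel_kinds(labels)
    for lb, kind in (cfg.get("kinds") or {}).items():
        if lb in labels:
            kinds[labels.index(lb)] = kind
    emg_sides = dict(cfg.get("emg_sides") or {})

    required = required_channels
    if required is None:
        required = cfg.get("required", DEFAULT_REQUIRED)
    missing = [lb for lb in required if lb not in labels]
    if missing:
        raise ValueError(
            "recording is missing required channels: " + ", ".join(missing)
        )

    if events is None:
        evts = []
    elif isinstance(events, (str, Path)):
        evts = load_events_tsv(events, fs)
    else:
        evts = list(events)

    return ContinuousRecording(
        samples=samples, fs=fs, channel_labels=list(labels),
        channel_kinds=kinds, events=evts, subject_id=subject_id,
        session_index=session_index, lesion_side=lesion_side,
        emg_sides=emg_sides,
    )
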