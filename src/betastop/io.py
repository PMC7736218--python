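"""Real-data ingestion: raw EEG readers and epoching into :class:`EpochSet`.

The synthetic path never touches these; they are the entry point for
recorded data.  File reading delegates to MNE-Python (EDF and BrainVision
``.vhdr/.vmrk/.eeg`` among others); epoching cuts fixed windows around
event samples and attaches trial labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectral import EpochSet

__all__ = ["read_raw", "epoch_array", "epochs_from_raw"]


def read_raw(path: str | Path):
    """Load a raw EEG recording via MNE (format inferred from the suffix)."""
    import mne

    return mne.io.read_raw(str(path), preload=True, verbose="ERROR")


def epoch_array(
    data: np.ndarray,
    fs_hz: float,
    channel_names: tuple[str, ...],
    event_samples: np.ndarray,
    trial_labels: np.ndarray,
    *,
    window_ms: tuple[float, float] = (-2000.0, 1500.0),
    lock_event: str = "stop",
) -> EpochSet:
    """Cut fixed windows around event samples of a channels x samples array.

    Events whose window would fall outside the recording are dropped (the
    returned ``trial_index`` keeps the original event positions, so a
    caller can align ancillary tables).
    """
    if data.ndim != 2 or data.shape[0] != len(channel_names):
        raise ValueError("data must be channels x samples")
    i0 = int(round(window_ms[0] * fs_hz / 1000.0))
    i1 = int(round(window_ms[1] * fs_hz / 1000.0))
    keep, chunks = [], []
    for k, s in enumerate(np.asarray(event_samples, dtype=int)):
        if s + i0 < 0 or s + i1 > data.shape[1]:
            continue
        keep.append(k)
        chunks.append(data[:, s + i0:s + i1])
    if not chunks:
        raise ValueError("no event fits inside the recording")
    return EpochSet(
        data=np.stack(chunks), fs_hz=fs_hz,
        channel_names=tuple(channel_names), window_ms=window_ms,
        lock_event=lock_event,
        trial_labels=np.asarray(trial_labels)[keep],
        trial_index=np.asarray(keep),
    )


def epochs_from_raw(raw, event_samples, trial_labels, **kwargs) -> EpochSet:
    """Epoch an MNE Raw object (EEG channels only) into an :class:`EpochSet`."""
    picks = [i for i, ch in enumerate(raw.get_channel_types())
             if ch == "eeg"]
    data = raw.get_data(picks=picks)
    names = tuple(np.array(raw.ch_names)[picks])
    return epoch_array(data, raw.info["sfreq"], names,
                       event_samples, trial_labels, **kwargs)
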