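"""Single-trial EMG burst landmarking and CancelTime.

The algorithm operates per trial on a 1000-Hz surface-EMG trace:

1. 4th-order Butterworth band-stop (58-62 Hz, zero-phase) to remove line
   noise.
2. Centered 50-ms sliding RMS envelope (edges use the truncated window).
3. Burst detection: the envelope must exceed the baseline mean (fixation to
   go window) by more than 8 baseline SDs; the burst peak is the global
   envelope maximum after the go signal.
4. Onset: walk back from the peak to the first run of >= 5 consecutive
   samples below 20% of the peak; the onset is the sample adjacent to that
   run on the peak side.  Go-signal-to-onset is the EMG response time.
5. Decline: the first run of 5 strictly decreasing consecutive samples
   after the peak; its start marks where motor drive is withdrawn.
6. CancelTime (successful stops only) = decline - stop signal; negative
   values are excluded.

Peak amplitudes are normalized to the mean Go-trial peak per muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EmgTrace",
    "EmgBurstEvent",
    "notch_filter",
    "rms_envelope",
    "detect_emg_burst",
    "find_onset",
    "find_decline",
    "cancel_time",
    "analyze_trace",
    "normalize_amplitudes",
]


@dataclass
class EmgTrace:
    """Raw EMG samples with embedded event markers (times in ms)."""

    samples: np.ndarray
    fs_hz: float
    fixation_ms: float
    go_ms: float
    stop_ms: float | None
    muscle: str = "FDI"

    def __post_init__(self) -> None:
        dur = len(self.samples) / self.fs_hz * 1000.0
        if not (0 <= self.fixation_ms < self.go_ms < dur):
            raise ValueError("markers must satisfy 0 <= fixation < go < end")
        # ssd may be clamped to the 0-ms staircase floor, so stop == go is legal
        if self.stop_ms is not None and not (self.go_ms <= self.stop_ms < dur):
            raise ValueError("stop marker must lie between go and trace end")

    def ms_to_idx(self, t_ms: float) -> int:
        return int(round(t_ms * self.fs_hz / 1000.0))


@dataclass
class EmgBurstEvent:
    """Detected burst landmarks for one trial (times relative to go signal)."""

    onset_ms: float
    peak_ms: float
    decline_ms: float | None
    peak_amp: float
    cancel_time_ms: float | None = None
    amp_pct_go: float | None = None
    flags: list[str] = field(default_factory=list)


def notch_filter(x: np.ndarray, fs: float, *, band: tuple[float, float] = (58.0, 62.0),
                 order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-stop for line-noise removal."""
    sos = sps.butter(order, band, btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def rms_envelope(x: np.ndarray, fs: float, window_ms: float = 50.0) -> np.ndarray:
    """Centered sliding RMS; edge samples use the truncated window."""
    n_win = int(round(window_ms * fs / 1000.0))
    if n_win % 2 == 0:
        n_win += 1
    if len(x) < n_win:
        raise ValueError("trace shorter than the RMS window")
    sq = np.asarray(x, dtype=float) ** 2
    kernel = np.ones(n_win)
    num = np.convolve(sq, kernel, mode="same")
    den = np.convolve(np.ones_like(sq), kernel, mode="same")
    return np.sqrt(num / den)


def detect_emg_burst(
    envelope: np.ndarray,
    fs: float,
    fixation_ms: float,
    go_ms: float,
    *,
    pooled_sd: float | None = None,
) -> tuple[int | None, list[str]]:
    """Find the burst peak index, or None when nothing crosses threshold.

    Threshold = baseline mean + 8 * baseline SD, both computed on the RMS
    envelope over the fixation-to-go window (strict inequality).  A zero
    baseline SD falls back to ``pooled_sd`` (across-trial), flagged.
    """
    i_fix = int(round(fixation_ms * fs / 1000.0))
    i_go = int(round(go_ms * fs / 1000.0))
    if (i_go - i_fix) / fs * 1000.0 < 100.0:
        raise ValueError("baseline window must span at least 100 ms")
    base = envelope[i_fix:i_go]
    sd = float(base.std())
    flags: list[str] = []
    if sd == 0.0:
        if pooled_sd is None or pooled_sd <= 0:
            raise ValueError("zero baseline SD and no pooled SD fallback")
        sd = float(pooled_sd)
        flags.append("pooled_sd")
    thr = float(base.mean()) + 8.0 * sd
    post = envelope[i_go:]
    above = post > thr  # strictly 'by more than'
    if not above.any():
        return None, flags
    peak = i_go + int(np.argmax(np.where(above, post, -np.inf)))
    return peak, flags


def find_onset(envelope: np.ndarray, peak_idx: int, go_idx: int,
               run_len: int = 5) -> tuple[int, list[str]]:
    """Backtrack from the peak to the burst onset.

    The onset is the sample adjacent (peak side) to the first run of
    ``run_len`` consecutive samples below 20% of the peak amplitude.  If no
    such run exists before the go signal, the onset clamps to go, flagged.
    """
    thr = 0.2 * envelope[peak_idx]
    below = envelope[go_idx:peak_idx] < thr
    run = 0
    for j in range(len(below) - 1, -1, -1):
        run = run + 1 if below[j] else 0
        if run >= run_len:
            return go_idx + j + run_len, []
    return go_idx, ["onset_clamped"]


def find_decline(envelope: np.ndarray, peak_idx: int,
                 run_len: int = 5) -> tuple[int | None, list[str]]:
    """First run of ``run_len`` strictly decreasing samples after the peak.

    Returns the start of the run, or None (flagged) when activity never
    declines before the end of the trace.
    """
    seg = envelope[peak_idx:]
    dec = np.diff(seg) < 0
    run = 0
    for j, d in enumerate(dec):
        run = run + 1 if d else 0
        if run >= run_len - 1:  # run_len samples = run_len-1 decreasing steps
            return peak_idx + j - (run_len - 2), []
    return None, ["no_decline"]


def cancel_time(decline_ms: float, stop_ms: float) -> float | None:
    """Stop signal to EMG decline; negative values are excluded (None)."""
    ct = decline_ms - stop_ms
    return ct if ct > 0 else None


def analyze_trace(
    trace: EmgTrace,
    *,
    is_successful_stop: bool = False,
    pooled_sd: float | None = None,
    notch: bool = True,
) -> EmgBurstEvent | None:
    """Run the full landmarking chain on one trace.

    Returns None when no burst is detected.  ``cancel_time_ms`` is filled
    only for successful stop trials with a stop marker; a pre-stop decline
    leaves it None with an ``excluded_negative_cancel`` flag.
    """
    x = trace.samples
    if notch and len(x) > 30:
        x = notch_filter(x, trace.fs_hz)
    env = rms_envelope(x, trace.fs_hz)
    peak_idx, flags = detect_emg_burst(env, trace.fs_hz, trace.fixation_ms,
                                       trace.go_ms, pooled_sd=pooled_sd)
    if peak_idx is None:
        return None
    go_idx = trace.ms_to_idx(trace.go_ms)
    onset_idx, f_on = find_onset(env, peak_idx, go_idx)
    decline_idx, f_dec = find_decline(env, peak_idx)
    flags += f_on + f_dec
    ms = 1000.0 / trace.fs_hz
    event = EmgBurstEvent(
        onset_ms=onset_idx * ms - trace.go_ms,
        peak_ms=peak_idx * ms - trace.go_ms,
        decline_ms=None if decline_idx is None else decline_idx * ms - trace.go_ms,
        peak_amp=float(env[peak_idx]),
        flags=flags,
    )
    if is_successful_stop:
        if trace.stop_ms is None:
            raise ValueError("successful stop trial without a stop marker")
        if event.decline_ms is not None:
            ct = cancel_time(event.decline_ms + trace.go_ms, trace.stop_ms)
            if ct is None:
                event.flags.append("excluded_negative_cancel")
            event.cancel_time_ms = ct
    return event


def normalize_amplitudes(events: pd.DataFrame) -> pd.DataFrame:
    """Add ``amp_pct_go``: peak amplitude as % of the mean Go peak per muscle.

    ``events`` needs columns ``muscle``, ``classification``, ``peak_amp``.
    """
    out = events.copy()
    out["amp_pct_go"] = np.nan
    for muscle, grp in events.groupby("muscle"):
        go_peaks = grp.loc[grp["classification"] == "CorrectGo", "peak_amp"]
        if go_peaks.empty:
            raise ValueError(f"no Go reference events for muscle {muscle!r}")
        ref = go_peaks.mean()
        if ref == 0:
            raise ValueError(f"zero mean Go amplitude for muscle {muscle!r}")
        out.loc[grp.index, "amp_pct_go"] = 100.0 * grp["peak_amp"] / ref
    return out
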