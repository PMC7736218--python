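"""Beta-burst extraction and burst statistics on a projected component.

Burst thresholds come from the analytic beta amplitude in per-trial-type
baseline windows (-1000 to -500 ms before the stop signal on stop trials;
mean SSD - 1000 to mean SSD - 500 ms after go on go trials), pooled across
all trial types: a burst must exceed ``median + 1.5 SD`` of that pooled
baseline, its peak time is the BurstTime, and its width spans the
surrounding crossings of a lower ``median + 1 SD`` threshold.

burst% counts, per window of interest (stop signal to SSRT, or the go-stop
baseline window), the percentage of trials containing at least one burst
peak inside the window; a per-sample suprathreshold timecourse variant is
also provided for burst-probability traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg import EmgBurstEvent
from .spectral import EpochSet

__all__ = [
    "BurstThresholds",
    "BetaBurstEvent",
    "burst_thresholds",
    "detect_bursts",
    "burst_fraction",
    "burst_timecourse",
    "mean_burst_time",
    "pair_bursts_with_emg",
]

STOP_BASELINE_MS = (-1000.0, -500.0)  # relative to the stop signal


@dataclass(frozen=True)
class BurstThresholds:
    """Pooled baseline statistics and the derived burst thresholds."""

    baseline_median: float
    baseline_sd: float

    @property
    def upper(self) -> float:  # burst-defining threshold
        return self.baseline_median + 1.5 * self.baseline_sd

    @property
    def lower(self) -> float:  # width-defining threshold
        return self.baseline_median + 1.0 * self.baseline_sd


@dataclass
class BetaBurstEvent:
    """One detected burst: peak time (BurstTime), width, height."""

    trial_index: int
    burst_time_ms: float
    width_ms: float
    height: float
    width_truncated: bool = False


def burst_thresholds(
    amp_stop: np.ndarray | None,
    epochs_stop: EpochSet | None,
    amp_go: np.ndarray | None,
    epochs_go: EpochSet | None,
    mean_ssd_ms: float,
) -> BurstThresholds:
    """Median and SD of baseline beta amplitude pooled across trial types.

    ``amp_*`` are analytic-amplitude arrays (trials x samples) aligned with
    the corresponding EpochSet.  Baselines: -1000..-500 ms before the stop
    signal (stop-locked trials) and mean SSD - 1000..mean SSD - 500 ms
    after go (go-locked trials).
    """
    pools = []
    if amp_stop is not None and len(amp_stop):
        mask = epochs_stop.time_slice(*STOP_BASELINE_MS)
        if not mask.any():
            raise ValueError("stop baseline window outside the epoch")
        pools.append(np.asarray(amp_stop)[:, mask].ravel())
    if amp_go is not None and len(amp_go):
        lo, hi = mean_ssd_ms - 1000.0, mean_ssd_ms - 500.0
        mask = epochs_go.time_slice(lo, hi)
        if not mask.any():
            raise ValueError("go baseline window outside the epoch")
        pools.append(np.asarray(amp_go)[:, mask].ravel())
    if not pools:
        raise ValueError("no trials to pool a baseline from")
    pooled = np.concatenate(pools)
    if pooled.size < 20:
        raise ValueError("too few baseline samples")
    return BurstThresholds(
        baseline_median=float(np.median(pooled)),
        baseline_sd=float(pooled.std()),
    )


def detect_bursts(
    amp: np.ndarray,
    times_ms: np.ndarray,
    thresholds: BurstThresholds,
    trial_index: int = 0,
) -> list[BetaBurstEvent]:
    """Detect bursts in one trial's amplitude series.

    A burst is a maximal contiguous run above the upper threshold; its
    BurstTime is the in-run amplitude peak, its width the distance between
    the lower-threshold crossings that bracket the peak (flagged truncated
    when the lower threshold is never re-crossed inside the epoch).
    """
    amp = np.asarray(amp, dtype=float)
    above = amp > thresholds.upper
    if not above.any():
        return []
    # run boundaries of the suprathreshold stretches
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [e + 1 for e in edges if not above[e]]
    ends = [e + 1 for e in edges if above[e]]
    if above[-1]:
        ends.append(len(amp))
    below_lower = amp <= thresholds.lower
    events = []
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(amp[s:e]))
        left = np.flatnonzero(below_lower[:peak])
        right = np.flatnonzero(below_lower[peak + 1:])
        truncated = False
        if len(left):
            i0 = left[-1] + 1
        else:
            i0, truncated = 0, True
        if len(right):
            i1 = peak + 1 + right[0] - 1
        else:
            i1, truncated = len(amp) - 1, True
        events.append(BetaBurstEvent(
            trial_index=trial_index,
            burst_time_ms=float(times_ms[peak]),
            width_ms=float(times_ms[i1] - times_ms[i0]),
            height=float(amp[peak]),
            width_truncated=truncated,
        ))
    return events


def burst_fraction(
    events_per_trial: list[list[BetaBurstEvent]],
    window_ms: tuple[float, float],
) -> float:
    """Percentage of trials with >= 1 burst peak inside the window."""
    if not events_per_trial:
        return float("nan")
    hits = sum(
        any(window_ms[0] <= ev.burst_time_ms < window_ms[1] for ev in evs)
        for evs in events_per_trial
    )
    return 100.0 * hits / len(events_per_trial)


def burst_timecourse(
    amp: np.ndarray, thresholds: BurstThresholds
) -> np.ndarray:
    """Per-sample fraction of trials above the lower threshold within bursts.

    For each trial, samples belong to the timecourse when they are above
    the lower threshold and connected to a suprathreshold (upper) run.
    """
    amp = np.asarray(amp, dtype=float)
    out = np.zeros(amp.shape[1])
    for row in amp:
        above_u = row > thresholds.upper
        above_l = row > thresholds.lower
        if not above_u.any():
            continue
        # propagate upper-run membership across connected lower-run samples
        lab = np.cumsum(np.diff(np.concatenate([[0], above_l.astype(int)])) == 1)
        lab = lab * above_l
        good = np.unique(lab[above_u & (lab > 0)])
        out += np.isin(lab, good) & above_l
    return 100.0 * out / amp.shape[0]


def _best_in_window(
    events: list[BetaBurstEvent], window_ms: tuple[float, float]
) -> BetaBurstEvent | None:
    inside = [e for e in events
              if window_ms[0] <= e.burst_time_ms < window_ms[1]]
    if not inside:
        return None
    return max(inside, key=lambda e: e.height)


def mean_burst_time(
    events_per_trial: list[list[BetaBurstEvent]],
    window_ms: tuple[float, float],
) -> float | None:
    """Mean BurstTime over trials with an in-window burst (largest height).

    Returns None when no trial qualifies.
    """
    picks = [_best_in_window(evs, window_ms) for evs in events_per_trial]
    times = [p.burst_time_ms for p in picks if p is not None]
    return float(np.mean(times)) if times else None


def pair_bursts_with_emg(
    beta_events: dict[int, list[BetaBurstEvent]],
    emg_events: dict[int, EmgBurstEvent],
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Pair BurstTime with CancelTime on Successful Stop trials.

    Keeps trials with an EMG burst (valid CancelTime) and at least one beta
    burst whose peak lies between the stop signal and the EMG decline;
    among several the largest height wins.  Returns one row per retained
    trial: trial_index, burst_time_ms, cancel_time_ms.
    """
    rows = []
    ss = trials[trials["classification"] == "SuccessfulStop"]
    for idx in ss["trial_index"]:
        emg_ev = emg_events.get(int(idx))
        if emg_ev is None or emg_ev.cancel_time_ms is None:
            continue
        best = _best_in_window(beta_events.get(int(idx), []),
                               (0.0, emg_ev.cancel_time_ms))
        if best is None:
            continue
        rows.append({
            "trial_index": int(idx),
            "burst_time_ms": best.burst_time_ms,
            "cancel_time_ms": emg_ev.cancel_time_ms,
        })
    return pd.DataFrame(rows, columns=["trial_index", "burst_time_ms",
                                       "cancel_time_ms"])
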