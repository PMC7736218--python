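"""Behavioral stop-signal measures: session summaries, SSRT, TMS contrasts.

SSRT uses the integration method: sort the Go RT distribution ascending with
omissions replaced by the maximum observed RT, take the ceil(p*n)-th order
statistic at p = P(respond | stop signal), and subtract the mean SSD.  The
Failed-Stop latency proxy (median Failed Stop RT minus SSD, aggregated
across delays) provides a TMS-sensitive alternative that uses only trials
where the pulse came early enough to matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorSummary",
    "summarize_behavior",
    "ssrt_integration",
    "failed_stop_latency_proxy",
    "percent_change",
    "relative_tms_time",
]


@dataclass
class BehaviorSummary:
    """Session-level behavioral measures (None when a subset is empty)."""

    go_rt_mean: float | None
    failed_stop_rt_mean: float | None
    correct_stop_pct: float | None
    mean_ssd: float | None
    ssrt: float | None
    correct_go_pct: float | None
    n_go: int
    n_stop: int


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Summarize a trial table (requires >= 1 go and >= 1 stop trial)."""
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if go.empty or stop.empty:
        raise ValueError("need at least one go and one stop trial")

    def _mean(x: pd.Series) -> float | None:
        x = x.dropna()
        return float(x.mean()) if len(x) else None

    n_succ = int((stop["classification"] == "SuccessfulStop").sum())
    correct_stop_pct = 100.0 * n_succ / len(stop)
    correct_go_pct = 100.0 * (go["classification"] == "CorrectGo").mean()
    p_respond = 1.0 - n_succ / len(stop)
    mean_ssd = _mean(stop["ssd_ms"])
    ssrt = None
    go_rts = go["rt_ms"].to_numpy(dtype=float)  # omissions are NaN
    if 0.0 < p_respond < 1.0 and np.isfinite(go_rts).sum() >= 20:
        ssrt = ssrt_integration(go_rts, p_respond, mean_ssd)
    return BehaviorSummary(
        go_rt_mean=_mean(go["rt_ms"]),
        failed_stop_rt_mean=_mean(
            stop.loc[stop["classification"] == "FailedStop", "rt_ms"]),
        correct_stop_pct=correct_stop_pct,
        mean_ssd=mean_ssd,
        ssrt=ssrt,
        correct_go_pct=float(correct_go_pct),
        n_go=len(go),
        n_stop=len(stop),
    )


def ssrt_integration(
    go_rts: np.ndarray, p_respond: float, mean_ssd: float
) -> float:
    """Integration-method SSRT.

    Go omissions (NaN entries) are replaced by the maximum observed RT;
    the ceil(p*n)-th ascending order statistic minus the mean SSD is the
    SSRT estimate.
    """
    if not (0.0 < p_respond < 1.0):
        raise ValueError("p_respond must lie strictly in (0, 1); "
                         "the staircase is degenerate otherwise")
    rts = np.asarray(go_rts, dtype=float)
    finite = rts[np.isfinite(rts)]
    if len(finite) < 20:
        raise ValueError("need at least 20 go RTs")
    filled = np.where(np.isfinite(rts), rts, finite.max())
    filled.sort()
    k = math.ceil(p_respond * len(filled))
    return float(filled[k - 1] - mean_ssd)


def failed_stop_latency_proxy(
    trials_by_condition: dict[str, pd.DataFrame],
    *,
    min_obs: int = 3,
    min_pulse_lead_ms: float = 60.0,
    require_pulse: bool = True,
) -> dict[str, float | None]:
    """Failed-Stop latency proxy per condition, matched across SSD levels.

    Per condition, keep Failed Stop trials whose pulse (``tms_abs_ms``)
    preceded the response by at least ``min_pulse_lead_ms`` (skipped when
    ``require_pulse`` is False or the condition has no pulses).  Retain only
    SSD levels with >= ``min_obs`` observations in *every* condition, then
    compute median RT - SSD per level and aggregate with trial-count
    weights.  A condition with no surviving level maps to None.
    """
    filtered: dict[str, pd.DataFrame] = {}
    for cond, df in trials_by_condition.items():
        fs = df[(df["trial_type"] == "stop")
                & (df["classification"] == "FailedStop")].copy()
        if require_pulse and "tms_abs_ms" in fs and fs["tms_abs_ms"].notna().any():
            fs = fs[fs["tms_abs_ms"] <= fs["rt_ms"] - min_pulse_lead_ms]
        filtered[cond] = fs

    counts = {cond: df.groupby("ssd_ms").size() for cond, df in filtered.items()}
    all_ssds = set().union(*[set(c.index) for c in counts.values()]) if counts else set()
    kept = sorted(
        s for s in all_ssds
        if all(c.get(s, 0) >= min_obs for c in counts.values())
    )
    out: dict[str, float | None] = {}
    for cond, df in filtered.items():
        vals, weights = [], []
        for s in kept:
            grp = df.loc[df["ssd_ms"] == s, "rt_ms"]
            vals.append(float(grp.median()) - s)
            weights.append(len(grp))
        out[cond] = (float(np.average(vals, weights=weights)) if vals else None)
    return out


def percent_change(value_real: float, value_sham: float) -> float:
    """((real - sham) / sham) * 100."""
    if value_sham == 0:
        raise ValueError("sham reference must be nonzero")
    return 100.0 * (value_real - value_sham) / value_sham


def relative_tms_time(tms_time_ms: float, cancel_time_sham_ms: float) -> float:
    """Pulse latency as a percentage of the sham-condition CancelTime."""
    if cancel_time_sham_ms <= 0:
        raise ValueError("cancel time must be positive")
    return 100.0 * tms_time_ms / cancel_time_sham_ms
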