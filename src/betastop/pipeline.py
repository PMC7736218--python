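"""Orchestration: per-subject processing, group tables, on-disk layout.

``process_subject`` runs the full chain on one simulated subject: behavior
summary -> EMG landmarking (CancelTime) -> GED spatial filter -> peak-beta
selection from the Morlet map -> beta-burst extraction -> burst statistics
and BurstTime/CancelTime pairing.  ``run_all`` iterates a cohort, writes
per-subject and group TSV tables (behavior/EMG/EEG summary rows, paired
trial latencies, group statistics) plus a manifest, and is deterministic
given the config seed.

TMS cohorts (real + sham sessions, EMG only) instead produce the
percent-change contrasts: CancelTime, SSRT, response times, the
Failed-Stop latency proxy, and the relative-TMS-time correlate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (BehaviorSummary, failed_stop_latency_proxy,
                       percent_change, relative_tms_time, summarize_behavior)
from .betaburst import (BetaBurstEvent, burst_fraction, burst_thresholds,
                        detect_bursts, mean_burst_time, pair_bursts_with_emg)
from .emg import analyze_trace, normalize_amplitudes
from .gedfilter import SpatialFilter, project, select_spatial_filter
from .spectral import EpochSet, morlet_tfr, narrowband_amplitude, peak_beta_frequency
from .stats import one_sample_t, paired_t, pearson, rmcorr
from .synthgen import CohortConfig, SubjectData, simulate_cohort

__all__ = [
    "RunConfig",
    "SubjectResult",
    "process_subject",
    "run_all",
    "make_fixtures",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass
class RunConfig:
    """Run-level knobs around a cohort configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str = "results/run"
    with_emg: bool = True
    with_eeg: bool = True
    rf_threshold: float = 1.2
    shrinkage: float = 0.01
    write_signals: bool = False


@dataclass
class SubjectResult:
    """Everything the group stage needs from one subject."""

    subject_id: int
    behavior: dict[str, BehaviorSummary]
    emg_events: pd.DataFrame
    spatial_filter: SpatialFilter | None
    peak_beta_hz: float | None
    burst_events: dict[int, list[BetaBurstEvent]]
    pairs: pd.DataFrame
    summary: dict


def _emg_stage(subject: SubjectData, session: str) -> pd.DataFrame:
    """Landmark every trace of a session; one row per detected burst."""
    sess = subject.sessions[session]
    trials = sess["trials"].set_index("trial_index")
    rows = []
    for idx, trace in sess["emg"].items():
        cls = trials.loc[idx, "classification"]
        ev = analyze_trace(trace, is_successful_stop=(cls == "SuccessfulStop"))
        if ev is None:
            continue
        rows.append({
            "trial_index": idx, "classification": cls, "muscle": trace.muscle,
            "onset_ms": ev.onset_ms, "peak_ms": ev.peak_ms,
            "decline_ms": ev.decline_ms, "peak_amp": ev.peak_amp,
            "cancel_time_ms": ev.cancel_time_ms,
            "flags": ";".join(ev.flags),
        })
    cols = ["trial_index", "classification", "muscle", "onset_ms", "peak_ms",
            "decline_ms", "peak_amp", "cancel_time_ms", "flags"]
    events = pd.DataFrame(rows, columns=cols)
    if not events.empty and (events["classification"] == "CorrectGo").any():
        events = normalize_amplitudes(events)
    return events


def _emg_event_objects(events: pd.DataFrame):
    """Index EmgBurstEvent-like rows by trial for pairing."""
    from .emg import EmgBurstEvent

    out = {}
    for _, r in events.iterrows():
        out[int(r["trial_index"])] = EmgBurstEvent(
            onset_ms=r["onset_ms"], peak_ms=r["peak_ms"],
            decline_ms=r["decline_ms"], peak_amp=r["peak_amp"],
            cancel_time_ms=(None if pd.isna(r["cancel_time_ms"])
                            else float(r["cancel_time_ms"])),
        )
    return out


def _eeg_stage(
    subject: SubjectData,
    beh: BehaviorSummary,
    cfg: RunConfig,
) -> tuple[SpatialFilter | None, float | None, dict, dict]:
    """Spatial filter, peak beta frequency, burst events and summaries."""
    ssrt = beh.ssrt if beh.ssrt is not None else 200.0
    mean_ssd = beh.mean_ssd if beh.mean_ssd is not None else 200.0
    ep_stop, ep_go = subject.epochs_stop, subject.epochs_go

    sf = select_spatial_filter(
        ep_stop, ssrt_ms=ssrt, mean_ssd_ms=mean_ssd,
        rf_threshold=cfg.rf_threshold, shrinkage=cfg.shrinkage,
    )
    if sf is None:
        return None, None, {}, {}

    # peak beta frequency from the Morlet map of Successful Stop trials
    ss = ep_stop.select(ep_stop.trial_labels == "SuccessfulStop").crop(-1300.0, 700.0)
    comp_ss = project(ss.data, sf.weights)
    tfr_epochs = EpochSet(comp_ss[:, None, :], ss.fs_hz, ("component",),
                          ss.window_ms, ss.lock_event,
                          ss.trial_labels, ss.trial_index)
    tfr = morlet_tfr(tfr_epochs,
                     baseline_ms=(-mean_ssd - 500.0, -mean_ssd - 200.0))
    f_peak, _ = peak_beta_frequency(tfr, (0.0, ssrt))

    # analytic beta amplitude of the projected component, all trial types
    crop_stop = ep_stop.crop(-1300.0, 700.0)
    crop_go = ep_go.crop(-1300.0, 700.0)
    amp_stop = narrowband_amplitude(project(crop_stop.data, sf.weights),
                                    ep_stop.fs_hz, f_peak)
    amp_go = narrowband_amplitude(project(crop_go.data, sf.weights),
                                  ep_go.fs_hz, f_peak)
    thr = burst_thresholds(amp_stop, crop_stop, amp_go, crop_go, mean_ssd)

    bursts: dict[int, list[BetaBurstEvent]] = {}
    for tidx, amp in zip(crop_stop.trial_index, amp_stop):
        bursts[int(tidx)] = detect_bursts(amp, crop_stop.times, thr, int(tidx))
    bursts_go: dict[int, list[BetaBurstEvent]] = {}
    for tidx, amp in zip(crop_go.trial_index, amp_go):
        bursts_go[int(tidx)] = detect_bursts(amp, crop_go.times, thr, int(tidx))

    # stop window: stop signal -> SSRT.  The baseline window sits in the
    # go -> stop period, anchored at go and duration-matched to the stop
    # window so the two burst fractions are comparable per trial.
    stop_win = (0.0, ssrt)
    base_len = min(ssrt, mean_ssd)
    base_win = (-mean_ssd, -mean_ssd + base_len)
    go_stop_win = (mean_ssd, mean_ssd + ssrt)  # go-locked analog
    go_base_win = (0.0, base_len)

    def _by_class(label: str) -> list[list[BetaBurstEvent]]:
        return [bursts[int(t)] for t, lab in
                zip(crop_stop.trial_index, crop_stop.trial_labels)
                if lab == label]

    go_events = list(bursts_go.values())
    burst_summary = {
        "burst_pct_ss_stopwin": burst_fraction(_by_class("SuccessfulStop"), stop_win),
        "burst_pct_ss_basewin": burst_fraction(_by_class("SuccessfulStop"), base_win),
        "burst_pct_fs_stopwin": burst_fraction(_by_class("FailedStop"), stop_win),
        "burst_pct_fs_basewin": burst_fraction(_by_class("FailedStop"), base_win),
        "burst_pct_go_stopwin": burst_fraction(go_events, go_stop_win),
        "burst_pct_go_basewin": burst_fraction(go_events, go_base_win),
        "mean_burst_time_ss": mean_burst_time(_by_class("SuccessfulStop"), stop_win),
        "mean_burst_time_fs": mean_burst_time(_by_class("FailedStop"), stop_win),
    }
    return sf, f_peak, bursts, burst_summary


def process_subject(subject: SubjectData, cfg: RunConfig) -> SubjectResult:
    """Run behavior, EMG and (when present) the EEG chain on one subject."""
    session = "main" if "main" in subject.sessions else "sham"
    beh = {name: summarize_behavior(s["trials"])
           for name, s in subject.sessions.items()}
    emg_events = (_emg_stage(subject, session) if cfg.with_emg
                  else pd.DataFrame())

    sf, f_peak, bursts, burst_summary = None, None, {}, {}
    pairs = pd.DataFrame(columns=["trial_index", "burst_time_ms",
                                  "cancel_time_ms"])
    if cfg.with_eeg and subject.epochs_stop is not None:
        sf, f_peak, bursts, burst_summary = _eeg_stage(
            subject, beh[session], cfg)
        if sf is not None:
            trials = subject.sessions[session]["trials"]
            pairs = pair_bursts_with_emg(
                bursts, _emg_event_objects(emg_events), trials)

    b = beh[session]
    ss_events = (emg_events[emg_events["classification"] == "SuccessfulStop"]
                 if not emg_events.empty else pd.DataFrame())
    summary = {
        "subject_id": subject.subject_id,
        "go_rt_ms": b.go_rt_mean,
        "failed_stop_rt_ms": b.failed_stop_rt_mean,
        "correct_stop_pct": b.correct_stop_pct,
        "mean_ssd_ms": b.mean_ssd,
        "ssrt_ms": b.ssrt,
        "correct_go_pct": b.correct_go_pct,
        "cancel_time_ms": (float(ss_events["cancel_time_ms"].dropna().mean())
                           if len(ss_events) else np.nan),
        "ss_amp_pct_go": (float(ss_events["amp_pct_go"].dropna().mean())
                          if "amp_pct_go" in ss_events and len(ss_events)
                          else np.nan),
        "ged_freq_hz": None if sf is None else sf.freq_hz,
        "peak_beta_hz": f_peak,
        "mean_burst_time_ms": burst_summary.get("mean_burst_time_ss"),
        **{k: v for k, v in burst_summary.items()
           if k.startswith("burst_pct")},
    }
    return SubjectResult(
        subject_id=subject.subject_id, behavior=beh, emg_events=emg_events,
        spatial_filter=sf, peak_beta_hz=f_peak, burst_events=bursts,
        pairs=pairs, summary=summary,
    )


# --------------------------------------------------------------------------
# TMS contrast (real vs sham sessions, EMG-based)


def tms_contrast(subject: SubjectData, cfg: RunConfig) -> dict:
    """Per-subject TMS_Real vs TMS_Sham measures.

    Percent change in CancelTime and SSRT, the relative TMS time (pulse
    latency as % of sham CancelTime), and the Failed-Stop latency proxy per
    coil (SSD levels matched across coils).
    """
    assert subject.sessions.keys() >= {"real", "sham"}
    out: dict = {"subject_id": subject.subject_id}
    cancel: dict[str, float] = {}
    for coil in ("sham", "real"):
        beh = summarize_behavior(subject.sessions[coil]["trials"])
        events = _emg_stage(subject, coil)
        ss = events[events["classification"] == "SuccessfulStop"]
        cancel[coil] = (float(ss["cancel_time_ms"].dropna().mean())
                        if len(ss) else np.nan)
        out[f"cancel_time_{coil}"] = cancel[coil]
        out[f"ssrt_{coil}"] = beh.ssrt
        out[f"go_rt_{coil}"] = beh.go_rt_mean
        out[f"fs_rt_{coil}"] = beh.failed_stop_rt_mean
    proxy = failed_stop_latency_proxy(
        {c: subject.sessions[c]["trials"] for c in ("real", "sham")})
    out["fs_proxy_real"] = proxy["real"]
    out["fs_proxy_sham"] = proxy["sham"]
    if np.isfinite(cancel["sham"]) and np.isfinite(cancel["real"]):
        out["cancel_pct_change"] = percent_change(cancel["real"], cancel["sham"])
        tms_ms = (subject.sessions["real"]["trials"]["tms_time_ms"]
                  .dropna().mean())
        out["relative_tms_time_pct"] = relative_tms_time(
            float(tms_ms), cancel["sham"])
    return out


# --------------------------------------------------------------------------
# group stage and disk layout


def group_tables(results: list[SubjectResult]) -> dict[str, pd.DataFrame]:
    """Group summary and trial-level statistics tables."""
    summary = pd.DataFrame([r.summary for r in results])
    tables = {"subject_summary": summary}

    pairs = pd.concat(
        [r.pairs.assign(subject_id=r.subject_id) for r in results
         if len(r.pairs)], ignore_index=True) if any(
        len(r.pairs) for r in results) else pd.DataFrame(
        columns=["trial_index", "burst_time_ms", "cancel_time_ms",
                 "subject_id"])
    tables["paired_latencies"] = pairs

    rows = []
    usable = pairs.groupby("subject_id").size()
    good = usable[usable >= 3].index if len(pairs) else []
    sub = pairs[pairs["subject_id"].isin(good)] if len(pairs) else pairs
    if len(good) >= 2:
        rm = rmcorr(sub["burst_time_ms"].to_numpy(),
                    sub["cancel_time_ms"].to_numpy(),
                    sub["subject_id"].to_numpy())
        rows.append({"measure": "rmcorr_bursttime_canceltime",
                     "statistic": rm.r_m, "df": rm.df, "p_value": rm.p_value,
                     "effect_size": rm.common_slope, "bf10": np.nan})
    both = summary.dropna(subset=["mean_burst_time_ms", "cancel_time_ms"])
    if len(both) >= 3:
        pr = pearson(both["mean_burst_time_ms"].to_numpy(),
                     both["cancel_time_ms"].to_numpy())
        rows.append({"measure": "pearson_bursttime_canceltime",
                     "statistic": pr.statistic, "df": pr.df,
                     "p_value": pr.p_value, "effect_size": pr.effect_size,
                     "bf10": np.nan})
    for a, bcol, name in [
        ("burst_pct_ss_stopwin", "burst_pct_ss_basewin", "ss_stop_vs_base"),
        ("burst_pct_ss_stopwin", "burst_pct_go_stopwin", "ss_vs_go_stopwin"),
        ("burst_pct_ss_stopwin", "burst_pct_fs_stopwin", "ss_vs_fs_stopwin"),
    ]:
        d = summary.dropna(subset=[a, bcol])
        if len(d) >= 3:
            t = paired_t(d[a].to_numpy(), d[bcol].to_numpy())
            rows.append({"measure": f"burst_pct_{name}",
                         "statistic": t.statistic, "df": t.df,
                         "p_value": t.p_value, "effect_size": t.effect_size,
                         "bf10": t.bf10})
    tables["group_stats"] = pd.DataFrame(
        rows, columns=["measure", "statistic", "df", "p_value",
                       "effect_size", "bf10"])
    return tables


def group_tms_tables(contrasts: list[dict]) -> dict[str, pd.DataFrame]:
    """TMS cohort tables: per-subject contrasts and the group tests."""
    per = pd.DataFrame(contrasts)
    rows = []
    d = per.dropna(subset=["cancel_time_real", "cancel_time_sham"])
    if len(d) >= 3:
        t = paired_t(d["cancel_time_real"].to_numpy(),
                     d["cancel_time_sham"].to_numpy())
        rows.append({"measure": "cancel_time_real_vs_sham",
                     "statistic": t.statistic, "df": t.df,
                     "p_value": t.p_value, "effect_size": t.effect_size,
                     "bf10": t.bf10})
        t1 = one_sample_t(d["cancel_pct_change"].to_numpy())
        rows.append({"measure": "cancel_pct_change_vs_zero",
                     "statistic": t1.statistic, "df": t1.df,
                     "p_value": t1.p_value, "effect_size": t1.effect_size,
                     "bf10": t1.bf10})
        if len(d) >= 3:
            pr = pearson(d["relative_tms_time_pct"].to_numpy(),
                         d["cancel_pct_change"].to_numpy())
            rows.append({"measure": "pct_change_vs_relative_tms_time",
                         "statistic": pr.statistic, "df": pr.df,
                         "p_value": pr.p_value, "effect_size": pr.effect_size,
                         "bf10": np.nan})
    p = per.dropna(subset=["fs_proxy_real", "fs_proxy_sham"])
    if len(p) >= 3:
        t = paired_t(p["fs_proxy_real"].to_numpy(),
                     p["fs_proxy_sham"].to_numpy())
        rows.append({"measure": "fs_latency_proxy_real_vs_sham",
                     "statistic": t.statistic, "df": t.df,
                     "p_value": t.p_value, "effect_size": t.effect_size,
                     "bf10": t.bf10})
    stats = pd.DataFrame(rows, columns=["measure", "statistic", "df",
                                        "p_value", "effect_size", "bf10"])
    return {"tms_subjects": per, "tms_stats": stats}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_subject(subject: SubjectData, out_dir: Path,
                  write_signals: bool = False) -> None:
    """Persist one subject: trial tables, ground truth, optional signals."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, sess in subject.sessions.items():
        _write_tsv(sess["trials"], out_dir / f"trials_{name}.tsv")
    if subject.ground_truth is not None:
        _write_tsv(subject.ground_truth, out_dir / "ground_truth.tsv")
    if write_signals and subject.epochs_stop is not None:
        for tag, ep in (("stop", subject.epochs_stop),
                        ("go", subject.epochs_go)):
            raw = out_dir / f"epochs_{tag}.float32.raw"
            ep.data.astype(np.float32).tofile(raw)
            sidecar = {
                "fs_hz": ep.fs_hz, "shape": list(ep.data.shape),
                "channel_names": list(ep.channel_names),
                "window_ms": list(ep.window_ms), "lock_event": ep.lock_event,
                "trial_labels": ep.trial_labels.tolist(),
                "trial_index": ep.trial_index.tolist(),
            }
            (out_dir / f"epochs_{tag}.json").write_text(
                json.dumps(sidecar, indent=1))


def _manifest(cfg: RunConfig) -> dict:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return {
        "version": __version__,
        "seed": cfg.cohort.seed,
        "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
    }


def run_all(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Full pipeline over a cohort; writes TSV tables under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    is_tms = cfg.cohort.tms is not None
    results: list[SubjectResult] = []
    contrasts: list[dict] = []
    for subject in simulate_cohort(cfg.cohort):
        sdir = out / f"sub-{subject.subject_id:02d}"
        write_subject(subject, sdir, write_signals=cfg.write_signals)
        if is_tms:
            contrasts.append(tms_contrast(subject, cfg))
        else:
            res = process_subject(subject, cfg)
            _write_tsv(res.emg_events, sdir / "emg_events.tsv")
            _write_tsv(res.pairs, sdir / "paired_latencies.tsv")
            results.append(res)
    tables = (group_tms_tables(contrasts) if is_tms
              else group_tables(results))
    for name, df in tables.items():
        _write_tsv(df, out / f"{name}.tsv")
    (out / "manifest.json").write_text(json.dumps(_manifest(cfg), indent=1))
    return tables


def make_fixtures(size: str = "tiny") -> CohortConfig:
    """Reference cohort configurations for tests and examples.

    'tiny': 3 subjects x 120 trials (90 go / 30 stop, the 25% stop rule),
    generated in seconds for CI-style runs; 'default': the full study-scale
    configuration.
    """
    if size == "tiny":
        return CohortConfig(n_subjects=3, n_go_trials=90, n_stop_trials=30,
                            seed=7)
    if size == "default":
        return CohortConfig(seed=7)
    raise ValueError("size must be 'tiny' or 'default'")


def config_to_yaml(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def config_from_yaml(path: str | Path) -> RunConfig:
    from .synthgen import EegSynthParams, RaceParams, TmsEffectParams

    raw = yaml.safe_load(Path(path).read_text())
    cohort = raw.pop("cohort", {})
    race = RaceParams(**cohort.pop("race", {}))
    eeg = EegSynthParams(**cohort.pop("eeg", {}))
    tms_raw = cohort.pop("tms", None)
    tms = TmsEffectParams(**tms_raw) if tms_raw else None
    return RunConfig(cohort=CohortConfig(race=race, eeg=eeg, tms=tms,
                                         **cohort), **raw)
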