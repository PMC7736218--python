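"""Synthetic stop-signal cohorts with EMG traces and EEG epochs.

The generator emulates the data-generating structure the downstream analysis
assumes, so that every stage (EMG CancelTime landmarking, GED spatial
filtering, beta-burst extraction, behavioral and trial-level statistics) is
testable without recorded data.

Model
-----
Each trial is a horse race between a go process and (on stop trials) a stop
process:

* EMG-onset latency from the go signal is ex-Gaussian
  (``mu_on, sigma_on, tau_on``); the key press follows the EMG onset by an
  electromechanical delay (``emd_mean, emd_sd``, ~135 ms).
* On stop trials the stop process completes ``cancel`` ms after the stop
  signal (truncated Gaussian, ``cancel_mean/cancel_sd/cancel_min``).  If it
  completes before EMG onset the trial is a clean Successful Stop; if it
  completes between EMG onset and the key press the muscle burst is cut
  short at the cancellation time (partial burst); otherwise the key press
  escapes (Failed Stop).
* The stop-signal delay (SSD) runs on two independent 1-up/1-down
  staircases (one per response direction), stepping 50 ms after every
  stop-trial outcome, which converges to ~50% stopping success.

EEG epochs contain spatially correlated 1/f background noise plus, on stop
trials, a right-frontal beta burst (Hanning-windowed sinusoid) whose peak
precedes the cancellation time by a lagged, jittered lead -- the generative
counterpart of the BurstTime/CancelTime coupling.  An optional TMS condition
elongates the cancellation latency depending on pulse-to-burst proximity;
this temporal tuning is a synthetic stand-in, not an empirical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .emg import EmgTrace
from .montage import Montage, gaussian_mixing, load_montage
from .spectral import EpochSet, analytic_amplitude, gaussian_bandpass

__all__ = [
    "RaceParams",
    "EegSynthParams",
    "TmsEffectParams",
    "CohortConfig",
    "TrialOutcome",
    "SubjectData",
    "race_outcome",
    "simulate_trial",
    "run_staircase_session",
    "apply_tms_effect",
    "synth_emg_trace",
    "synth_eeg_epochs",
    "simulate_subject",
    "simulate_cohort",
    "trials_to_frame",
]


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RaceParams:
    """Race-model and staircase parameters (all times in ms).

    Defaults are calibrated so cohort means approximate the typical group
    values of the task: EMG onset ~256 ms, Go RT ~393 ms, cancellation
    latency ~160 ms, 50-ms staircases starting at 200 ms.
    """

    mu_on: float = 200.0
    sigma_on: float = 30.0
    tau_on: float = 60.0
    emd_mean: float = 135.0
    emd_sd: float = 10.0
    cancel_mean: float = 160.0
    cancel_sd: float = 30.0
    cancel_min: float = 80.0
    p_go_omission: float = 0.01
    ssd_start: float = 200.0
    ssd_step: float = 50.0
    ssd_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_on", "sigma_on", "tau_on", "emd_mean", "emd_sd",
                     "cancel_mean", "cancel_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.p_go_omission <= 1.0):
            raise ValueError("p_go_omission must be in [0, 1]")
        if self.cancel_min >= self.cancel_mean:
            raise ValueError("cancel_min must be < cancel_mean")
        if self.ssd_step <= 0:
            raise ValueError("ssd_step must be > 0")


@dataclass(frozen=True)
class EegSynthParams:
    """Synthetic EEG parameters.

    ``snr`` scales the injected burst amplitude relative to the median
    narrowband background amplitude at the mixing-center channel.
    ``burst_lead_mean/sd`` give the lead of the burst peak before the
    cancellation time; ``coupling_jitter_sd`` adds independent per-trial
    jitter on top.
    """

    n_channels: int = 64
    fs_hz: float = 512.0
    peak_beta_hz: int = 18
    burst_width_ms: float = 150.0
    burst_prob: float = 0.5
    burst_lead_mean: float = 30.0
    burst_lead_sd: float = 10.0
    coupling_jitter_sd: float = 25.0
    snr: float = 4.0
    mixing_center: str = "F6"
    mixing_spread: float = 0.35
    epoch_start_ms: float = -2000.0
    epoch_end_ms: float = 1500.0
    n_background_sources: int = 12
    sensor_noise_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.burst_prob <= 1.0):
            raise ValueError("burst_prob must be in [0, 1]")
        if not (13 <= int(self.peak_beta_hz) <= 25):
            raise ValueError("peak_beta_hz must lie in the 13-25 Hz band")
        if self.epoch_start_ms >= self.epoch_end_ms:
            raise ValueError("empty epoch window")


@dataclass(frozen=True)
class TmsEffectParams:
    """Synthetic TMS disruption (Gaussian temporal tuning; a stand-in).

    The real coil elongates the cancellation latency by
    ``delta_ms * exp(-(t_tms - burst_center)^2 / (2 tuning_sd_ms^2))`` where
    the per-trial burst center is approximated as the raw cancellation
    latency minus ``burst_lead_ms``.  Both coils slow EMG onset by
    ``distraction_ms`` on pulse trials (non-specific distraction).
    """

    tms_time_ms: float = 80.0
    delta_ms: float = 20.0
    tuning_sd_ms: float = 60.0
    distraction_ms: float = 15.0
    burst_lead_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.delta_ms < 0:
            raise ValueError("delta_ms must be >= 0")
        if self.tuning_sd_ms <= 0:
            raise ValueError("tuning_sd_ms must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort deterministically."""

    n_subjects: int = 10
    n_go_trials: int = 1440
    n_stop_trials: int = 480
    seed: int = 0
    race: RaceParams = field(default_factory=RaceParams)
    eeg: EegSynthParams = field(default_factory=EegSynthParams)
    tms: TmsEffectParams | None = None
    emg_noise_sd: float = 1.0
    emg_burst_rise_ms: float = 5.0
    emg_burst_fall_ms: float = 100.0
    emg_peak_amp: float = 9.0
    # between-subject variability of the race and carrier frequency
    cancel_mean_sd: float = 25.0
    mu_on_sd: float = 30.0
    peak_beta_sd: float = 2.0
    include_eeg: bool = True

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_go_trials, self.n_stop_trials) <= 0:
            raise ValueError("counts must be > 0")
        if self.emg_noise_sd < 0:
            raise ValueError("emg_noise_sd must be >= 0")


# --------------------------------------------------------------------------
# single trials


@dataclass
class TrialOutcome:
    """One simulated trial with raw latent draws and derived classification.

    Latencies are relative to the go signal unless noted.  Raw draws
    (``t_onset_draw``, ``emd_draw``, ``cancel_draw``) are kept so that a
    TMS transform can re-run the classification.
    """

    trial_index: int
    trial_type: Literal["go", "stop"]
    direction: Literal["left", "right"]
    ssd_ms: float | None
    t_onset_draw: float | None  # EMG-onset latency; None = go omission
    emd_draw: float
    cancel_draw: float | None  # cancellation latency after the stop signal
    classification: str = ""
    keypress_ms: float | None = None
    has_emg: bool = False
    emg_decline_ms: float | None = None  # envelope decline, rel. go signal
    tms: Literal["none", "real", "sham"] = "none"
    tms_abs_ms: float | None = None  # pulse time relative to go signal

    @property
    def cancel_abs_ms(self) -> float | None:
        """Stop-process completion relative to the go signal."""
        if self.ssd_ms is None or self.cancel_draw is None:
            return None
        return self.ssd_ms + self.cancel_draw


def race_outcome(outcome: TrialOutcome) -> TrialOutcome:
    """Fill classification fields from the raw draws (pure rule).

    Stop-trial rule with ``t_on`` = EMG onset, ``t_c`` = SSD + cancellation
    latency, ``EMD`` = electromechanical delay:

    * ``t_c <= t_on``          -> Successful Stop, no EMG
    * ``t_on < t_c < t_on+EMD``-> Successful Stop with a partial EMG burst
                                  truncated at ``t_c``
    * ``t_c >= t_on + EMD``    -> Failed Stop, key press at ``t_on + EMD``
    """
    o = outcome
    o.keypress_ms = None
    o.has_emg = False
    o.emg_decline_ms = None
    if o.trial_type == "go":
        if o.t_onset_draw is None:
            o.classification = "GoOmission"
        else:
            o.classification = "CorrectGo"
            o.has_emg = True
            o.keypress_ms = o.t_onset_draw + o.emd_draw
    else:
        if o.ssd_ms is None or o.cancel_draw is None:
            raise ValueError("stop trial requires ssd_ms and cancel_draw")
        t_c = o.ssd_ms + o.cancel_draw
        if o.t_onset_draw is None or t_c <= o.t_onset_draw:
            o.classification = "SuccessfulStop"
        elif t_c < o.t_onset_draw + o.emd_draw:
            o.classification = "SuccessfulStop"
            o.has_emg = True
            o.emg_decline_ms = t_c
        else:
            o.classification = "FailedStop"
            o.has_emg = True
            o.keypress_ms = o.t_onset_draw + o.emd_draw
    return o


def _sample_cancel(race: RaceParams, rng: np.random.Generator) -> float:
    """Gaussian cancellation latency truncated below at ``cancel_min``."""
    while True:
        c = rng.normal(race.cancel_mean, race.cancel_sd)
        if c >= race.cancel_min:
            return c


def simulate_trial(
    race: RaceParams,
    ssd: float | None,
    rng: np.random.Generator,
    *,
    trial_index: int = 0,
    direction: Literal["left", "right"] = "right",
) -> TrialOutcome:
    """Simulate one trial; ``ssd`` must be given iff it is a stop trial."""
    omitted = rng.random() < race.p_go_omission
    t_on = None if omitted else (
        rng.normal(race.mu_on, race.sigma_on) + rng.exponential(race.tau_on)
    )
    emd = max(1.0, rng.normal(race.emd_mean, race.emd_sd))
    cancel = _sample_cancel(race, rng) if ssd is not None else None
    out = TrialOutcome(
        trial_index=trial_index,
        trial_type="stop" if ssd is not None else "go",
        direction=direction,
        ssd_ms=ssd,
        t_onset_draw=t_on,
        emd_draw=emd,
        cancel_draw=cancel,
    )
    return race_outcome(out)


def apply_tms_effect(
    outcome: TrialOutcome,
    tms: TmsEffectParams,
    coil: Literal["real", "sham"],
    rng: np.random.Generator,
) -> TrialOutcome:
    """Apply the synthetic pulse effect to a trial and re-classify.

    Real coil: cancellation latency grows by a Gaussian function of the
    pulse-to-burst-center distance.  Both coils: EMG onset slowed by
    ``distraction_ms``.  The outcome is modified in place and returned.
    """
    o = outcome
    o.tms = coil
    if o.t_onset_draw is not None:
        o.t_onset_draw = o.t_onset_draw + tms.distraction_ms
    if coil == "real" and o.cancel_draw is not None:
        burst_center = o.cancel_draw - tms.burst_lead_ms
        gain = np.exp(-((tms.tms_time_ms - burst_center) ** 2)
                      / (2.0 * tms.tuning_sd_ms**2))
        o.cancel_draw = o.cancel_draw + tms.delta_ms * float(gain)
    return race_outcome(o)


# --------------------------------------------------------------------------
# sessions


def run_staircase_session(
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    race: RaceParams | None = None,
    coil: Literal["none", "real", "sham"] = "none",
) -> list[TrialOutcome]:
    """Simulate a full session with two independent per-direction staircases.

    Stop trials are ``n_stop_trials`` of ``n_go + n_stop`` total (25% under
    the defaults), randomly interleaved.  The SSD steps up ``ssd_step``
    after a Successful Stop and down after a Failed Stop, clamped at
    ``ssd_floor``.  With ``coil != 'none'`` a pulse is applied on every stop
    trial and half of the go trials (at the most recent stop trial's pulse
    time), per the TMS design.
    """
    race = race or config.race
    n_total = config.n_go_trials + config.n_stop_trials
    is_stop = np.zeros(n_total, dtype=bool)
    is_stop[rng.choice(n_total, size=config.n_stop_trials, replace=False)] = True
    directions = np.where(rng.random(n_total) < 0.5, "left", "right")
    ssd = {"left": race.ssd_start, "right": race.ssd_start}
    tms_time_abs = race.ssd_start + (config.tms.tms_time_ms if config.tms else 0.0)

    outcomes: list[TrialOutcome] = []
    for i in range(n_total):
        d = str(directions[i])
        if is_stop[i]:
            out = simulate_trial(race, ssd[d], rng, trial_index=i, direction=d)
            if coil != "none":
                assert config.tms is not None
                out = apply_tms_effect(out, config.tms, coil, rng)
                out.tms_abs_ms = out.ssd_ms + config.tms.tms_time_ms
                tms_time_abs = out.tms_abs_ms
            if out.classification == "SuccessfulStop":
                ssd[d] = ssd[d] + race.ssd_step
            else:
                ssd[d] = max(race.ssd_floor, ssd[d] - race.ssd_step)
        else:
            out = simulate_trial(race, None, rng, trial_index=i, direction=d)
            if coil != "none" and rng.random() < 0.5:
                assert config.tms is not None
                out = apply_tms_effect(out, config.tms, coil, rng)
                out.tms_abs_ms = tms_time_abs
        outcomes.append(out)
    return outcomes


def trials_to_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    """Tabulate outcomes as a trial table (one row per trial)."""
    rows = []
    for o in outcomes:
        rows.append({
            "trial_index": o.trial_index,
            "trial_type": o.trial_type,
            "direction": o.direction,
            "ssd_ms": np.nan if o.ssd_ms is None else o.ssd_ms,
            "rt_ms": np.nan if o.keypress_ms is None else o.keypress_ms,
            "classification": o.classification,
            "tms": o.tms,
            "tms_time_ms": (np.nan if (o.tms_abs_ms is None or o.ssd_ms is None)
                            else o.tms_abs_ms - o.ssd_ms),
            "tms_abs_ms": np.nan if o.tms_abs_ms is None else o.tms_abs_ms,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# EMG synthesis


def _emg_envelope(
    n: int,
    onset_ms: float,
    truncate_ms: float | None,
    rise_ms: float,
    fall_ms: float,
    fs: float,
    full_dur_ms: float = 135.0,
) -> np.ndarray:
    """Burst amplitude envelope on a trace of ``n`` samples.

    Recruitment: a fast square-root ramp over ``rise_ms`` up to 20% of the
    ballistic peak, then exponential growth reaching the peak at
    ``full_dur_ms`` (the electromechanical delay, when the key press would
    land).  The constant *relative* slope of the exponential keeps the
    post-peak decline crisp at every truncation phase, and makes partial
    bursts systematically smaller than full Go bursts.  When the stop
    process truncates the burst at ``truncate_ms`` the envelope de-recruits
    as the mirror image of its rise (symmetric about the cancellation
    time); a full burst mirrors about ``full_dur_ms``.  ``fall_ms`` caps
    the mirrored decay (the tail is compressed to at most ``fall_ms``).
    """
    t = np.arange(n) / fs * 1000.0 - onset_ms  # ms since burst onset
    floor = 0.25  # envelope level (fraction of ballistic peak) at burst onset
    growth = np.log(1.0 / floor) / max(full_dur_ms - rise_ms, 1.0)

    def recruit(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, None)
        return np.where(
            u < rise_ms,
            floor * np.sqrt(u / rise_ms),
            floor * np.exp(growth * (u - rise_ms)),
        )

    tc = (truncate_ms - onset_ms) if truncate_ms is not None else full_dur_ms
    # mirror around tc; de-recruitment runs ~25% faster than recruitment and
    # the tail is additionally compressed so it lasts at most fall_ms
    scale = min(0.8, fall_ms / max(tc, 1e-9))
    mirrored = recruit(tc - (t - tc) / scale)
    env = np.where(t <= tc, recruit(t), mirrored)
    return np.clip(env, 0.0, None)


def synth_emg_trace(
    outcome: TrialOutcome,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    fs: float = 1000.0,
    muscle: str = "FDI",
) -> EmgTrace:
    """Render one trial's EMG trace at 1000 Hz.

    Baseline Gaussian noise plus, when the trial carries EMG, an
    interference-pattern burst: ``amp * envelope * N(0,1)``.  Partial bursts
    on successful stops are truncated at the cancellation time.  Markers for
    fixation, go and stop are embedded in the returned trace.
    """
    fixation_ms = 100.0
    go_ms = fixation_ms + float(rng.uniform(450.0, 550.0))
    stop_ms = go_ms + outcome.ssd_ms if outcome.ssd_ms is not None else None
    tail = max(1100.0, (outcome.ssd_ms or 0.0) + 700.0)
    n = int(round((go_ms + tail) * fs / 1000.0))
    sig = config.emg_noise_sd * rng.standard_normal(n)
    if outcome.has_emg and outcome.t_onset_draw is not None:
        onset_abs = go_ms + outcome.t_onset_draw
        truncate = (go_ms + outcome.emg_decline_ms
                    if outcome.emg_decline_ms is not None else None)
        # the electrical envelope peaks ~20 ms before the key press lands
        env = _emg_envelope(n, onset_abs, truncate,
                            config.emg_burst_rise_ms, config.emg_burst_fall_ms, fs,
                            full_dur_ms=max(outcome.emd_draw - 20.0, 40.0))
        sig = sig + config.emg_peak_amp * env * rng.standard_normal(n)
    return EmgTrace(
        samples=sig.astype(np.float64),
        fs_hz=fs,
        fixation_ms=fixation_ms,
        go_ms=go_ms,
        stop_ms=stop_ms,
        muscle=muscle,
    )


# --------------------------------------------------------------------------
# EEG synthesis


def _pink_noise(n_series: int, n_samp: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise, one row per series."""
    n_freq = n_samp // 2 + 1
    f = np.arange(n_freq, dtype=float)
    shape = np.zeros(n_freq)
    shape[1:] = 1.0 / np.sqrt(f[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    coef = (rng.standard_normal((n_series, n_freq))
            + 1j * rng.standard_normal((n_series, n_freq))) * shape
    x = np.fft.irfft(coef, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _background(
    n_trials: int,
    n_samp: int,
    mixing_bg: np.ndarray,
    sensor_ratio: float,
    rng: np.random.Generator,
    chunk: int = 64,
) -> np.ndarray:
    """Spatially correlated 1/f background plus white sensor noise (float32)."""
    n_ch, k = mixing_bg.shape
    data = np.empty((n_trials, n_ch, n_samp), dtype=np.float32)
    norm = float(np.linalg.norm(mixing_bg) / np.sqrt(n_ch))  # channel-avg sd
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        latents = _pink_noise((hi - lo) * k, n_samp, rng).reshape(hi - lo, k, n_samp)
        block = np.einsum("ck,tkn->tcn", mixing_bg, latents) / max(norm, 1e-12)
        block += sensor_ratio * rng.standard_normal(block.shape)
        data[lo:hi] = block
    return data


def _burst_waveform(
    times_ms: np.ndarray, peak_ms: float, width_ms: float, freq_hz: float,
    phase: float,
) -> np.ndarray:
    """Hanning-windowed sinusoid, unit peak envelope, centered at ``peak_ms``."""
    half = width_ms / 2.0
    u = (times_ms - peak_ms) / half
    env = np.where(np.abs(u) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return env * np.sin(2 * np.pi * freq_hz * (times_ms - peak_ms) / 1000.0 + phase)


def calibration_amplitude(
    eeg: EegSynthParams,
    montage: Montage,
    mixing_bg: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Median narrowband amplitude of the background at the mixing center.

    Used to put the ``snr`` parameter on the scale 'burst amplitude over
    background narrowband RMS at the source's center channel'.
    """
    n_samp = int(round((eeg.epoch_end_ms - eeg.epoch_start_ms)
                       * eeg.fs_hz / 1000.0))
    bg = _background(4, n_samp, mixing_bg, eeg.sensor_noise_ratio, rng)
    ch = montage.index(eeg.mixing_center)
    nb = gaussian_bandpass(bg[:, ch, :], eeg.fs_hz, float(eeg.peak_beta_hz))
    return float(np.median(analytic_amplitude(nb)))


def synth_eeg_epochs(
    outcomes: list[TrialOutcome],
    eeg: EegSynthParams,
    rng: np.random.Generator,
    montage: Montage | None = None,
) -> tuple[EpochSet, EpochSet, pd.DataFrame]:
    """Synthesize stop-locked and go-locked epochs plus a ground-truth table.

    Stop trials (Successful and Failed) receive, with probability
    ``burst_prob``, a beta burst through the right-frontal mixing vector
    whose peak sits at ``cancel_latency - lead + jitter`` relative to the
    stop signal.  Go trials are background only.  The ground-truth table is
    row-aligned with the emitted stop trials.
    """
    montage = montage or load_montage()
    if montage.n_channels != eeg.n_channels:
        raise ValueError("montage size does not match n_channels")
    fs = eeg.fs_hz
    n_samp = int(round((eeg.epoch_end_ms - eeg.epoch_start_ms) * fs / 1000.0))
    times = eeg.epoch_start_ms + np.arange(n_samp) * 1000.0 / fs

    mixing_bg = rng.standard_normal(
        (eeg.n_channels, eeg.n_background_sources)
    ) / np.sqrt(eeg.n_background_sources)
    mixing = gaussian_mixing(montage, eeg.mixing_center, eeg.mixing_spread)
    amp = eeg.snr * calibration_amplitude(eeg, montage, mixing_bg, rng)

    stop_trials = [o for o in outcomes if o.trial_type == "stop"]
    go_trials = [o for o in outcomes if o.trial_type == "go"]

    stop_data = _background(len(stop_trials), n_samp, mixing_bg,
                            eeg.sensor_noise_ratio, rng)
    gt_rows = []
    for i, o in enumerate(stop_trials):
        present = rng.random() < eeg.burst_prob
        peak = np.nan
        if present:
            lead = rng.normal(eeg.burst_lead_mean, eeg.burst_lead_sd)
            jitter = rng.normal(0.0, eeg.coupling_jitter_sd)
            peak = float(o.cancel_draw - lead + jitter)
            wave = _burst_waveform(times, peak, eeg.burst_width_ms,
                                   float(eeg.peak_beta_hz),
                                   float(rng.uniform(0, 2 * np.pi)))
            stop_data[i] += amp * mixing[:, None] * wave[None, :]
        gt_rows.append({
            "trial_index": o.trial_index,
            "burst_present": present,
            "true_burst_peak_ms": peak,
            "true_cancel_ms": float(o.cancel_draw),
        })
    go_data = _background(len(go_trials), n_samp, mixing_bg,
                          eeg.sensor_noise_ratio, rng)

    window = (eeg.epoch_start_ms, eeg.epoch_end_ms)
    epochs_stop = EpochSet(
        data=stop_data, fs_hz=fs, channel_names=montage.names,
        window_ms=window, lock_event="stop",
        trial_labels=np.array([o.classification for o in stop_trials]),
        trial_index=np.array([o.trial_index for o in stop_trials]),
    )
    epochs_go = EpochSet(
        data=go_data, fs_hz=fs, channel_names=montage.names,
        window_ms=window, lock_event="go",
        trial_labels=np.array([o.classification for o in go_trials]),
        trial_index=np.array([o.trial_index for o in go_trials]),
    )
    return epochs_stop, epochs_go, pd.DataFrame(gt_rows)


# --------------------------------------------------------------------------
# subjects and cohorts


@dataclass
class SubjectData:
    """One simulated subject: trial tables plus raw signal streams.

    ``sessions`` maps a session label ('main', or 'real'/'sham' for TMS
    cohorts) to a dict with keys ``outcomes``, ``trials`` (DataFrame) and
    ``emg`` (trial_index -> EmgTrace).  EEG epochs (non-TMS cohorts only)
    are stop-locked/go-locked EpochSets plus the burst ground-truth table.
    """

    subject_id: int
    race: RaceParams
    eeg_params: EegSynthParams
    sessions: dict
    epochs_stop: EpochSet | None = None
    epochs_go: EpochSet | None = None
    ground_truth: pd.DataFrame | None = None


def _subject_params(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[RaceParams, EegSynthParams]:
    """Draw per-subject race and EEG parameters around the cohort defaults."""
    race = replace(
        config.race,
        mu_on=max(50.0, config.race.mu_on + rng.normal(0, config.mu_on_sd)),
        cancel_mean=max(
            config.race.cancel_min + 20.0,
            config.race.cancel_mean + rng.normal(0, config.cancel_mean_sd),
        ),
    )
    beta = int(np.clip(round(config.eeg.peak_beta_hz
                             + rng.normal(0, config.peak_beta_sd)), 13, 25))
    eeg = replace(config.eeg, peak_beta_hz=beta)
    return race, eeg


def _session(
    config: CohortConfig,
    race: RaceParams,
    rng: np.random.Generator,
    coil: Literal["none", "real", "sham"],
    with_emg: bool = True,
) -> dict:
    outcomes = run_staircase_session(config, rng, race=race, coil=coil)
    emg = {}
    if with_emg:
        for o in outcomes:
            emg[o.trial_index] = synth_emg_trace(o, config, rng)
    return {"outcomes": outcomes, "trials": trials_to_frame(outcomes), "emg": emg}


def simulate_subject(
    config: CohortConfig, subject_id: int, rng: np.random.Generator
) -> SubjectData:
    """Simulate one subject (one session, or a real+sham pair under TMS)."""
    race, eeg = _subject_params(config, rng)
    if config.tms is None:
        sessions = {"main": _session(config, race, rng, "none")}
        data = SubjectData(subject_id, race, eeg, sessions)
        if config.include_eeg:
            ep_s, ep_g, gt = synth_eeg_epochs(
                sessions["main"]["outcomes"], eeg, rng
            )
            data.epochs_stop, data.epochs_go, data.ground_truth = ep_s, ep_g, gt
    else:
        sessions = {
            "sham": _session(config, race, rng, "sham"),
            "real": _session(config, race, rng, "real"),
        }
        data = SubjectData(subject_id, race, eeg, sessions)
    return data


def simulate_cohort(config: CohortConfig) -> Iterator[SubjectData]:
    """Yield subjects one at a time (identical config + seed => identical data)."""
    root = np.random.SeedSequence(config.seed)
    for sid, child in enumerate(root.spawn(config.n_subjects)):
        yield simulate_subject(config, sid, np.random.default_rng(child))
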