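"""Epoch preprocessing, narrowband filtering, analytic amplitude, Morlet TFR.

Containers
----------
:class:`EpochSet` is the in-memory epochs array (trials x channels x
samples) with sampling rate, channel names, the epoch window relative to
the lock event, and per-trial labels.  :class:`TfrMap` is a
frequencies x times power map in dB relative to a pre-go baseline.

Numerical notes
---------------
The narrowband filter is a frequency-domain Gaussian with a 5-Hz full width
at half maximum and unit peak gain; signals are reflection-padded before
filtering so Hilbert/FFT edge artifacts stay out of the analysis windows
(the outer 250 ms are excluded from statistics downstream).  Morlet wavelet
cycles grow from 3 at the lowest frequency by 0.5 per 1-Hz grid step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "EpochSet",
    "TfrMap",
    "preprocess_epochs",
    "gaussian_bandpass",
    "analytic_amplitude",
    "narrowband_amplitude",
    "morlet_tfr",
    "peak_beta_frequency",
]

EDGE_EXCLUDE_MS = 250.0  # filter-edge margin excluded from statistics


@dataclass
class EpochSet:
    """Epoched multichannel data (trials x channels x samples)."""

    data: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    window_ms: tuple[float, float]
    lock_event: str  # 'go' | 'stop'
    trial_labels: np.ndarray
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if len(self.trial_labels) != self.data.shape[0]:
            raise ValueError("trial_labels length mismatch")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to the lock event."""
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs_hz

    def time_slice(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask over samples for ``start_ms <= t < end_ms``."""
        t = self.times
        return (t >= start_ms) & (t < end_ms)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.fs_hz, self.channel_names,
                        self.window_ms, self.lock_event,
                        self.trial_labels[mask], self.trial_index[mask])

    def crop(self, start_ms: float, end_ms: float) -> "EpochSet":
        """Restrict the epoch window (clipped to the available range)."""
        mask = self.time_slice(max(start_ms, self.window_ms[0]),
                               min(end_ms, self.window_ms[1]))
        t = self.times[mask]
        return EpochSet(self.data[:, :, mask], self.fs_hz, self.channel_names,
                        (float(t[0]), float(t[-1] + 1000.0 / self.fs_hz)),
                        self.lock_event, self.trial_labels, self.trial_index)


@dataclass
class TfrMap:
    """Time-frequency power, dB relative to a baseline window."""

    power: np.ndarray  # freqs x times
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    baseline_window_ms: tuple[float, float]


def preprocess_epochs(
    data: np.ndarray,
    fs: float,
    *,
    fs_target: float = 512.0,
    band: tuple[float, float] = (2.0, 100.0),
    notch_hz: tuple[float, ...] = (60.0, 120.0, 180.0),
) -> tuple[np.ndarray, float]:
    """Basic epoch preprocessing: band-pass, line-noise notches, resample, CAR.

    Zero-phase FIR filters (band-pass then notches below Nyquist), polyphase
    resampling to ``fs_target``, then common-average re-referencing.
    Returns the processed array and its sampling rate.
    """
    import mne

    if fs < 2.0 * band[1]:
        raise ValueError("sampling rate violates Nyquist for the band-pass")
    x = np.asarray(data, dtype=np.float64)
    x = mne.filter.filter_data(x, fs, band[0], band[1], verbose="ERROR")
    # zero-phase IIR notches: epochs are too short for sharp FIR notches
    for f0 in notch_hz:
        if f0 < fs / 2.0:
            b, a = sps.iirnotch(f0, Q=35.0, fs=fs)
            x = sps.filtfilt(b, a, x, axis=-1)
    if fs_target != fs:
        x = mne.filter.resample(x, down=fs / fs_target, verbose="ERROR")
    x = x - x.mean(axis=-2, keepdims=True)  # common average reference
    return x, fs_target


def _reflect_pad(x: np.ndarray, n_pad: int) -> np.ndarray:
    pad = [(0, 0)] * (x.ndim - 1) + [(n_pad, n_pad)]
    return np.pad(x, pad, mode="reflect")


def gaussian_bandpass(
    x: np.ndarray, fs: float, center_hz: float, fwhm_hz: float = 5.0,
    *, pad: bool = True,
) -> np.ndarray:
    """Frequency-domain Gaussian narrowband filter (unit peak gain).

    The spectrum is multiplied by ``exp(-4 ln2 (f - center)^2 / fwhm^2)``
    along the last axis; reflection padding suppresses wrap-around edges.
    """
    if center_hz >= fs / 2.0:
        raise ValueError("center frequency at or above Nyquist")
    if center_hz - fwhm_hz <= 0:
        raise ValueError("center - fwhm must be positive")
    from scipy import fft as sfft

    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    n = x.shape[-1]
    n_pad = min(n - 1, int(round(fs))) if pad else 0
    xp = _reflect_pad(x, n_pad) if n_pad else x
    m = xp.shape[-1]
    f = sfft.rfftfreq(m, d=1.0 / fs)
    gain = np.exp(-4.0 * np.log(2.0) * (f - center_hz) ** 2 / fwhm_hz**2)
    y = sfft.irfft(sfft.rfft(xp, axis=-1) * gain.astype(x.dtype), n=m, axis=-1)
    return y[..., n_pad:n_pad + n] if n_pad else y


def analytic_amplitude(x: np.ndarray, *, pad: bool = True) -> np.ndarray:
    """Magnitude of the Hilbert analytic signal of a narrowband series."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_pad = min(n - 1, 256) if pad else 0
    xp = _reflect_pad(x, n_pad) if n_pad else x
    amp = np.abs(sps.hilbert(xp, axis=-1))
    return amp[..., n_pad:n_pad + n] if n_pad else amp


def narrowband_amplitude(x: np.ndarray, fs: float, center_hz: float,
                         fwhm_hz: float = 5.0) -> np.ndarray:
    """Gaussian narrowband filter followed by the analytic amplitude."""
    return analytic_amplitude(gaussian_bandpass(x, fs, center_hz, fwhm_hz))


def _n_cycles(freqs: np.ndarray) -> np.ndarray:
    """3 cycles at the lowest frequency, growing 0.5 per 1-Hz grid step."""
    return 3.0 + 0.5 * np.arange(len(freqs))


def morlet_tfr(
    epochs: EpochSet,
    *,
    freqs: np.ndarray | None = None,
    baseline_ms: tuple[float, float] | None = None,
    db: bool = True,
) -> TfrMap:
    """Trial-averaged Morlet wavelet power map, dB-corrected to baseline.

    ``baseline_ms`` defaults to -500..-200 ms before the lock event for
    go-locked epochs; for stop-locked epochs the caller should pass a pre-go
    window (e.g. ``(-mean_ssd - 500, -mean_ssd - 200)``).  ``db=False``
    skips the baseline correction and returns raw power.
    """
    import mne

    if freqs is None:
        freqs = np.arange(4.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    n_cyc = _n_cycles(freqs)
    longest = n_cyc[0] / freqs[0]
    if longest > epochs.data.shape[2] / epochs.fs_hz:
        raise ValueError("longest wavelet exceeds the epoch duration")
    power = mne.time_frequency.tfr_array_morlet(
        epochs.data, epochs.fs_hz, freqs, n_cycles=n_cyc,
        output="avg_power", verbose="ERROR",
    )  # channels x freqs x times -- caller passes single 'channel' data
    power = power.mean(axis=0) if power.ndim == 3 else power
    if baseline_ms is None:
        baseline_ms = (-500.0, -200.0)
    if db:
        mask = epochs.time_slice(*baseline_ms)
        if not mask.any():
            raise ValueError("baseline window outside the epoch")
        base = power[:, mask].mean(axis=1, keepdims=True)
        power = 10.0 * np.log10(power / base)
    return TfrMap(power=power, freqs_hz=freqs, times_ms=epochs.times,
                  baseline_window_ms=baseline_ms)


def peak_beta_frequency(
    tfr: TfrMap,
    window_ms: tuple[float, float],
    band: tuple[float, float] = (13.0, 25.0),
) -> tuple[float, list[str]]:
    """Beta frequency with the highest mean power in the window.

    Ties resolve to the lowest in-band frequency, flagged.
    """
    fsel = (tfr.freqs_hz >= band[0]) & (tfr.freqs_hz <= band[1])
    if not fsel.any():
        raise ValueError("empty frequency band")
    tsel = (tfr.times_ms >= window_ms[0]) & (tfr.times_ms < window_ms[1])
    if not tsel.any():
        raise ValueError("window outside the epoch")
    mean_pow = tfr.power[np.ix_(fsel, tsel)].mean(axis=1)
    flags: list[str] = []
    best = np.flatnonzero(mean_pow == mean_pow.max())
    if len(best) > 1:
        flags.append("tie")
    return float(tfr.freqs_hz[fsel][best[0]]), flags
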