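"""Beta bursts: thresholds, event extraction, burst%, pairing with EMG."""

import numpy as np
import pandas as pd
import pytest

from betastop.betaburst import (BurstThresholds, burst_fraction,
                                burst_thresholds, detect_bursts,
                                mean_burst_time, pair_bursts_with_emg)
from betastop.emg import EmgBurstEvent
from betastop.spectral import EpochSet

FS = 512.0


def _epochs(n, n_samp=1792, window=(-2000.0, 1500.0), lock="stop",
            labels=None):
    return EpochSet(np.zeros((n, 1, n_samp)), FS, ("comp",), window, lock,
                    np.array(labels or ["SuccessfulStop"] * n), np.arange(n))


def _amp(env, thresholds=None):
    return np.asarray(env, dtype=float)


class TestThresholds:
    def test_constant_amplitude(self):
        ep_s = _epochs(3)
        amp = np.full((3, 1792), 2.0)
        thr = burst_thresholds(amp, ep_s, None, None, 200.0)
        assert thr.baseline_median == 2.0
        assert thr.baseline_sd == 0.0
        assert thr.upper == 2.0 and thr.lower == 2.0

    def test_scale_equivariance(self, rng):
        ep_s = _epochs(5)
        amp = np.abs(rng.standard_normal((5, 1792))) + 0.5
        t1 = burst_thresholds(amp, ep_s, None, None, 200.0)
        t2 = burst_thresholds(2.0 * amp, ep_s, None, None, 200.0)
        assert t2.baseline_median == pytest.approx(2 * t1.baseline_median)
        assert t2.baseline_sd == pytest.approx(2 * t1.baseline_sd)
        assert t2.upper == pytest.approx(2 * t1.upper)

    def test_rayleigh_noise_matches_monte_carlo_oracle(self, rng):
        """Thresholds on Rayleigh amplitude match a direct simulation."""
        ep_s = _epochs(200)
        mask = ep_s.time_slice(-1000.0, -500.0)
        amp = rng.rayleigh(1.0, size=(200, 1792))
        thr = burst_thresholds(amp, ep_s, None, None, 200.0)
        oracle = rng.rayleigh(1.0, size=amp[:, mask].size)
        assert thr.baseline_median == pytest.approx(np.median(oracle), rel=0.02)
        assert thr.baseline_sd == pytest.approx(oracle.std(), rel=0.02)

    def test_pools_across_trial_types(self, rng):
        ep_s, ep_g = _epochs(4), _epochs(4, lock="go",
                                         labels=["CorrectGo"] * 4)
        amp_s = np.full((4, 1792), 1.0)
        amp_g = np.full((4, 1792), 3.0)
        thr = burst_thresholds(amp_s, ep_s, amp_g, ep_g, 200.0)
        assert thr.baseline_median == 2.0  # pooled median of the two levels

    def test_baseline_outside_epoch_errors(self):
        ep = _epochs(2, n_samp=256, window=(0.0, 500.0))
        with pytest.raises(ValueError):
            burst_thresholds(np.ones((2, 256)), ep, None, None, 200.0)


def _hanning_burst(times, peak_ms, width_ms=150.0, height=3.0):
    u = (times - peak_ms) / (width_ms / 2.0)
    return np.where(np.abs(u) <= 1, height * 0.5 * (1 + np.cos(np.pi * u)),
                    0.0)


class TestDetectBursts:
    thr = BurstThresholds(baseline_median=0.5, baseline_sd=0.4)

    def _times(self, n=1792):
        return -2000.0 + np.arange(n) * 1000.0 / FS

    def test_single_burst(self):
        times = self._times()
        amp = 0.5 + _hanning_burst(times, 120.0)
        evs = detect_bursts(amp, times, self.thr)
        assert len(evs) == 1
        assert abs(evs[0].burst_time_ms - 120.0) < 10.0
        assert evs[0].height == pytest.approx(3.5, abs=0.05)
        assert 0 < evs[0].width_ms < 300.0

    def test_two_bursts_with_sub_threshold_gap(self):
        times = self._times()
        amp = (0.5 + _hanning_burst(times, -300.0)
               + _hanning_burst(times, 200.0))
        evs = detect_bursts(amp, times, self.thr)
        assert len(evs) == 2

    def test_all_below_threshold(self):
        times = self._times()
        evs = detect_bursts(np.full_like(times, 0.6), times, self.thr)
        assert evs == []

    def test_width_measured_at_lower_threshold(self):
        times = self._times()
        amp = 0.0 + _hanning_burst(times, 0.0, width_ms=200.0, height=2.0)
        evs = detect_bursts(amp, times, self.thr)
        # lower threshold 0.9 -> crossing where burst envelope = 0.9
        u = np.arccos(2 * 0.9 / 2.0 - 1 + 1e-12) / np.pi  # cos form inverse
        expected = 2 * u * 100.0
        assert evs[0].width_ms == pytest.approx(expected, abs=8.0)
        assert not evs[0].width_truncated

    def test_width_truncated_at_epoch_edge_flagged(self):
        times = self._times()
        amp = np.full_like(times, 2.0)  # never below lower threshold
        evs = detect_bursts(amp, times, self.thr)
        assert evs[0].width_truncated

    def test_threshold_monotonicity(self, rng):
        """Raising the burst threshold never increases the event count."""
        times = self._times()
        amp = rng.rayleigh(1.0, size=times.shape)
        lo = BurstThresholds(baseline_median=1.0, baseline_sd=0.5)
        hi = BurstThresholds(baseline_median=1.0, baseline_sd=1.5)
        assert (len(detect_bursts(amp, times, hi))
                <= len(detect_bursts(amp, times, lo)))

    def test_idempotent_and_order_independent(self, rng):
        times = self._times()
        amps = [0.5 + _hanning_burst(times, p) for p in (-500.0, 100.0)]
        first = [detect_bursts(a, times, self.thr, i)
                 for i, a in enumerate(amps)]
        again = [detect_bursts(a, times, self.thr, i)
                 for i, a in enumerate(amps)]
        assert [[e.burst_time_ms for e in evs] for evs in first] == \
               [[e.burst_time_ms for e in evs] for evs in again]


class TestBurstFraction:
    def test_every_trial_has_burst(self):
        evs = [[_ev(100.0)], [_ev(50.0)], [_ev(120.0)]]
        assert burst_fraction(evs, (0.0, 200.0)) == 100.0

    def test_out_of_window_not_counted(self):
        evs = [[_ev(-300.0)], [_ev(50.0)], []]
        assert burst_fraction(evs, (0.0, 200.0)) == pytest.approx(100 / 3)

    def test_window_is_half_open(self):
        evs = [[_ev(200.0)]]
        assert burst_fraction(evs, (0.0, 200.0)) == 0.0
        assert burst_fraction(evs, (200.0, 300.0)) == 100.0


def _ev(t, height=1.0, width=100.0, trial=0):
    from betastop.betaburst import BetaBurstEvent
    return BetaBurstEvent(trial_index=trial, burst_time_ms=t,
                          width_ms=width, height=height)


class TestMeanBurstTime:
    def test_single_trial(self):
        assert mean_burst_time([[_ev(120.0)]], (0.0, 250.0)) == 120.0

    def test_average_across_trials(self):
        evs = [[_ev(100.0)], [_ev(120.0)], [_ev(140.0)]]
        assert mean_burst_time(evs, (0.0, 250.0)) == pytest.approx(120.0)

    def test_largest_height_wins_within_trial(self):
        evs = [[_ev(100.0, height=1.0), _ev(200.0, height=5.0)]]
        assert mean_burst_time(evs, (0.0, 250.0)) == 200.0

    def test_no_qualifying_trials_returns_none(self):
        assert mean_burst_time([[_ev(-500.0)], []], (0.0, 250.0)) is None


class TestPairing:
    def _trials(self, classes):
        return pd.DataFrame({
            "trial_index": np.arange(len(classes)),
            "classification": classes,
        })

    def test_burst_before_emg_decline_pairs(self):
        beta = {0: [_ev(110.0)]}
        emg = {0: EmgBurstEvent(onset_ms=200.0, peak_ms=300.0,
                                decline_ms=350.0, peak_amp=1.0,
                                cancel_time_ms=150.0)}
        pairs = pair_bursts_with_emg(beta, emg,
                                     self._trials(["SuccessfulStop"]))
        assert len(pairs) == 1
        assert pairs.iloc[0].burst_time_ms == 110.0
        assert pairs.iloc[0].cancel_time_ms == 150.0

    def test_burst_after_decline_excluded(self):
        beta = {0: [_ev(180.0)]}
        emg = {0: EmgBurstEvent(onset_ms=200.0, peak_ms=300.0,
                                decline_ms=350.0, peak_amp=1.0,
                                cancel_time_ms=150.0)}
        pairs = pair_bursts_with_emg(beta, emg,
                                     self._trials(["SuccessfulStop"]))
        assert pairs.empty

    def test_failed_stop_trials_not_paired(self):
        beta = {0: [_ev(110.0)]}
        emg = {0: EmgBurstEvent(onset_ms=200.0, peak_ms=300.0,
                                decline_ms=350.0, peak_amp=1.0,
                                cancel_time_ms=150.0)}
        pairs = pair_bursts_with_emg(beta, emg, self._trials(["FailedStop"]))
        assert pairs.empty

    def test_largest_height_chosen(self):
        beta = {0: [_ev(50.0, height=1.0), _ev(110.0, height=4.0)]}
        emg = {0: EmgBurstEvent(onset_ms=200.0, peak_ms=300.0,
                                decline_ms=350.0, peak_amp=1.0,
                                cancel_time_ms=150.0)}
        pairs = pair_bursts_with_emg(beta, emg,
                                     self._trials(["SuccessfulStop"]))
        assert pairs.iloc[0].burst_time_ms == 110.0
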