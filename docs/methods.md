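# Methods

`betastop` re-implements, as tested library code plus numbered analysis
drivers, a single-trial analysis of human action-stopping: behavioral
stop-signal measures, an EMG-derived per-trial stopping latency
(CancelTime), right-frontal beta-burst extraction from EEG (BurstTime) via
a GED spatial filter, and the statistics linking burst timing to stopping.
Because the original recordings are human data, every stage is exercised
on a synthetic cohort generator that emulates the study's data-generating
structure; the tests are parameter-recovery and contrast checks, not
point reproductions of empirical values.

## The race model and staircase (synthgen)

A trial is a race between a go process and, on stop trials, a stop
process:

* EMG-onset latency from the go signal is ex-Gaussian:
  `t_on ~ N(mu_on, sigma_on) + Exp(tau_on)` with defaults
  `mu_on = 200 ms, sigma_on = 30 ms, tau_on = 60 ms`, chosen so the
  group means approximate typical task values (EMG onset ≈ 256 ms,
  Go RT ≈ 393 ms).
* The key press lags EMG onset by an electromechanical delay
  `EMD ~ N(135, 10) ms`.
* The stop process completes `cancel ~ N(160, 30) ms` (truncated below at
  80 ms) after the stop signal.  With `t_c = SSD + cancel`:
  `t_c ≤ t_on` gives a clean Successful Stop; `t_on < t_c < t_on + EMD`
  gives a Successful Stop with a partial EMG burst truncated at `t_c`;
  otherwise the key press escapes (Failed Stop).
* Go omissions occur with probability 0.01 (Correct Go ≈ 99%).
* The SSD runs on two independent per-direction 1-up/1-down staircases
  (start 200 ms, step 50 ms, floor 0 ms, no ceiling), which converges to
  ~50% stopping success for any continuous latency distributions.
* Stop trials are 25% of the session; the default session is 1440 go /
  480 stop (the full-length trial-level session), with the 12-minute
  (240/80) and TMS (432/144 per coil) sessions available as per-analysis
  configurations.

Between-subject heterogeneity — without which no between-subject
correlation would be defined — is drawn per subject: `cancel_mean`
(SD 25 ms), `mu_on` (SD 30 ms), and the integer beta carrier frequency
(18 ± 2 Hz, clipped to 13–25 Hz).

## Synthetic EMG

Traces are 1000-Hz Gaussian noise (`emg_noise_sd = 1`) plus, on trials
with muscle activity, an interference-pattern burst
`amp * envelope * N(0,1)` with `amp = 9` (×baseline SD).  The envelope is
a recruitment curve: a 5-ms square-root ramp to 25% of the ballistic peak
followed by exponential growth that reaches the peak ~20 ms before the
key press would land (the electrical envelope leads the mechanical
event).  Truncation by the stop process mirrors the curve around the
cancellation time with de-recruitment running ~25% faster than
recruitment.

This shape is the package's calibration of the generator to the fixed
landmarking algorithm: the constant *relative* slope of the exponential
keeps the post-peak decline detectable at every truncation phase under
the 50-ms centered RMS window, and the mild fall asymmetry offsets the
detection delay of the strictly-decreasing-run rule.  Measured recovery
at the defaults: CancelTime bias +4 to +5 ms, error SD ≈ 11 ms,
r(true, detected) ≈ 0.93–0.95.  A by-product matches the direction seen
in real recordings: partial-burst amplitudes are ~55–75% of Go-burst
amplitudes, because truncation interrupts recruitment.

## Synthetic EEG

Epochs (64 channels, 512 Hz, −2000…+1500 ms around the lock event)
contain background plus bursts:

* Background: 12 latent 1/f (power) sources mixed through a random
  per-subject matrix, plus white sensor noise at half the background RMS
  ("spatially correlated 1/f noise + sensor noise").
* Burst: on each stop trial with probability 0.5, a Hanning-windowed
  sinusoid (width 150 ms) at the subject's carrier frequency, injected
  through a Gaussian spatial profile centered on electrode F6 (sigma 0.35
  rad in the azimuthal-equidistant projection; montage coordinates from
  the standard 10-05 set).  The burst peak sits at
  `cancel − lead + jitter` with `lead ~ N(30, 10) ms` and independent
  jitter (SD 25 ms) — the generative counterpart of the
  BurstTime→CancelTime coupling, placing mean BurstTime ~30 ms before
  mean CancelTime.
* Amplitude: `snr = 4` times the median narrowband background amplitude
  at the center channel, measured per subject on a calibration epoch.
  This corresponds to clearly visible single-trial bursts, which the
  scalp-level analysis presumes; at `snr = 2.5` the planted source is no
  longer recoverable from ~240 narrowband successful-stop epochs because
  the narrowband covariance degrees of freedom barely exceed the channel
  count.

What the generator does **not** emulate: eye/muscle artifacts, bad
channels, non-stationary background, volume-conduction forward modeling,
spontaneous (non-stop-related) beta bursts, or continuous recordings.
Passing tests therefore demonstrate that the algorithms recover what this
structure injects — not that they are robust to every pathology of real
EEG.

## EMG landmarking (emg)

Per trial: 4th-order Butterworth band-stop 58–62 Hz (zero-phase) for line
noise; centered 50-ms sliding RMS (edges use the truncated window); burst
threshold = baseline mean + 8 × baseline SD, both computed on the RMS
envelope over the fixation→go window (a zero baseline SD falls back to a
pooled across-trial SD, flagged).  The peak is the suprathreshold
envelope maximum after go ("more than" is strict).  Onset: walking back
from the peak, the sample adjacent to the first run of ≥5 consecutive
samples below 20% of the peak (clamped to go, flagged, if no such run).
Decline: the start of the first run of 5 strictly decreasing consecutive
samples after the peak.  CancelTime = decline − stop signal on successful
stops; negative values are excluded.  Peak amplitudes are normalized to
the mean Go-trial peak per muscle.

The "8 SD" is the per-trial SD of the *envelope* (threshold and signal on
one scale); "decreased for 5 consecutive ms" is read as 5 strictly
decreasing samples at 1 kHz.

## Spectral processing (spectral)

Band-pass 2–100 Hz (zero-phase FIR), line-noise notches at 60/120/180 Hz
(zero-phase IIR notch, Q = 35 — epochs are too short for sharp FIR
notches), polyphase resampling to 512 Hz, common-average reference.
Narrowband filtering is a frequency-domain Gaussian with unit peak gain
and 5-Hz FWHM; the burst envelope is the Hilbert analytic amplitude.
Signals are reflection-padded before filtering and the outer 250 ms never
enter statistics.  Morlet maps run 4–30 Hz with cycles 3 + 0.5 per 1-Hz
grid step (one reading of an ambiguous convention; the alternative —
+0.5 per Hz of frequency — would give the same values on a 1-Hz grid).
dB baseline is −500…−200 ms before the go cue (the pre-go window
translated by the mean SSD for stop-locked epochs).  The subject's peak
beta frequency is the 13–25 Hz argmax of mean baseline-corrected power
between the stop signal and SSRT; ties resolve to the lowest frequency,
flagged.

## GED spatial filter (gedfilter)

For each integer frequency 10–25 Hz, Successful Stop epochs are
narrowband filtered and per-trial covariances averaged in a stop window
(0–250 ms) and baseline window (−1500…−1000 ms).  The generalized
eigenproblem `S w = λ R' w` uses shrinkage
`R' = 0.99 R + 0.01 (tr R / n) I`.  A component qualifies if it ranks in
the top 6 by eigenvalue and its activation pattern `S w` (sign-fixed to a
positive maximal entry) concentrates over the right-frontal ROI
{AF4, F4, F6, F8, FC4, FC6, FT8} at ≥1.2× the all-channel mean |pattern|;
if nothing right-lateralized qualifies anywhere, a frontal-row ROI is
tried (the automated analog of "right frontal, else frontal" visual
selection).

Validation is out-of-sample: candidates are derived from covariances of
half the trials and scored by the beta-power gain (stop→SSRT vs pre-go,
in dB) of the projection of the *held-out* half, with a 1.0-dB floor.
This matters: a GED component fitted on a few narrowband trials always
shows an in-sample stop-window gain (selection bias), so in-sample
validation would "find" a component in pure noise and inflate stop-window
burst rates.  The winning (frequency, component) is refit on all trials,
keeping the top-6 component most similar to the half-data winner; the
reported `beta_gain_db` remains the held-out estimate.  With fewer than
16 trials there is nothing to split and validation is in-sample.  A
cohort without bursts yields "no component" — the analog of participants
excluded for lacking a right-frontal filter.

Measured at the defaults (20 simulation seeds, ~240 successful stops):
median |cos| between selected pattern and true mixing ≈ 0.95, and the
projection's stop-window beta SNR beats the best single channel ~5×.

## Beta bursts (betaburst)

Thresholds come from baseline analytic amplitude pooled across all trial
types (−1000…−500 ms before the stop signal on stop trials; mean
SSD−1000…mean SSD−500 ms after go on go trials): a burst exceeds
`median + 1.5 SD`; its BurstTime is the in-burst amplitude peak; its
width spans the bracketing `median + 1 SD` crossings (flagged truncated
at epoch edges).  burst% is the percentage of trials with ≥1 burst peak
inside a window.  Because a trial-fraction measure grows with window
duration, the baseline window is anchored at the go signal and
duration-matched to the stop window (stop signal → SSRT); the original
go→stop-period baseline would differ from the stop window in length and
could not be compared on burst-free data.  A per-sample suprathreshold
timecourse variant is provided for burst-probability traces.  Multiple
in-window bursts resolve to the largest height.  Pairing keeps Successful
Stop trials with a valid CancelTime and ≥1 beta burst peaking between the
stop signal and the EMG decline.

## Statistics (stats)

Implemented from first principles, with SciPy used only for distribution
CDFs and quadrature:

* Repeated-measures correlation: ANCOVA with subject intercepts and one
  common slope via within-subject centering;
  `r_m = sign(slope)·sqrt(SS_measure/(SS_measure+SS_error))`,
  `df = N − k − 1`, p from F(1, df).
* Paired/one-sample/two-sample t with Cohen's d (`mean(diff)/sd(diff)`
  for paired).  Exactly identical vectors return the defined null result
  (t = 0, p = 1); constant nonzero differences are a zero-variance error.
* JZS Bayes factor: Cauchy prior (scale √2/2) on the standardized effect,
  marginal likelihood by adaptive quadrature over the noncentral-t
  likelihood; equals Rouder's g-integral form.  The scale→0 limit is 1.
* One-way repeated-measures ANOVA with partial eta squared; no sphericity
  correction (reported df are uncorrected).
* Pearson r with t-based p; Bonferroni `min(1, m·p)`.
* Effect-size labels follow the conventional small/medium/large cutoffs
  (d: 0.2/0.5/0.8; BF10: 1/3/10; partial eta²: 0.01/0.06/0.14).

Every estimator is tested against an independently coded oracle
(design-matrix least squares, hand-computed sums of squares, fine-grid
trapezoid quadrature, scipy/pingouin cross-checks).

## TMS condition (synthetic stand-in)

No empirical generative model exists for the pulse effect, so the
generator uses an explicit stand-in: the real coil elongates the
cancellation latency by `delta · exp(−(t_pulse − burst_center)²/(2σ²))`
with `delta = 20 ms`, `σ = 60 ms`, pulse at 80 ms after the stop signal,
and the per-trial burst center approximated as the raw cancellation
latency minus the 30-ms mean burst lead.  Both coils slow EMG onset by
15 ms on pulse trials (non-specific distraction).  These choices make
subjects with shorter cancellation latencies — whose bursts sit closer to
the fixed pulse — experience larger elongations, so the percent change in
CancelTime correlates positively with the relative pulse time
(pulse latency as % of sham CancelTime); with `delta = 0` the real and
sham cohorts are exchangeable and the contrast vanishes.  Note that the
relative-time measure shares its sham-CancelTime denominator with the
percent change, so some positive correlation persists even under the
null; the null check therefore asserts on the contrast itself.

The Failed-Stop latency proxy aggregates, per condition, median Failed
Stop RT − SSD over SSD levels with ≥3 observations in *every* condition,
weighting levels by trial count; pulse trials enter only if the pulse
preceded the response by ≥60 ms.  Count-weighting the per-delay medians
is the package's choice; the procedure it operationalizes fixes only that
the measure aggregates across delays.

## Problem sizes and numerical choices

The recovery analyses run at: 200 partial-EMG trials (CancelTime), one
1440/480 session (SSRT), one study-scale subject (burst detection,
~250 injected bursts), 20 seeds × ~240 successful-stop epochs (GED),
8 subjects × 1440/480 (trial-level coupling), and 12 subjects × 432/144
per coil (TMS contrast) — sizes chosen to give stable estimates while
keeping a full run in minutes on one core.  Seeds flow through
`numpy.random.SeedSequence` children, so identical configuration + seed
reproduces cohorts bit-identically.  Epoch arrays are float32;
covariances accumulate in float64.

## Known limitations

* The GED eigenvalue ranking is used for the "top 6" rule; ranking by
  post-projection variance is an alternative reading of the source
  method.
* The burst% definition (peak-in-window trial fraction) is one of two
  plausible readings; the per-sample timecourse variant is emitted for
  the other.
* The integration-method SSRT mildly underestimates the generator's
  cancellation mean here (≈ −8 ms at the defaults) because staircase
  non-stationarity and go omissions violate the method's independence
  assumptions; the recovery tolerance budgets for this.
* Detector false-alarm rates (~13% of trials) depend on the analysis
  window length and the amplitude distribution of the background; they
  are a property of the thresholding rule, not an estimate of any
  physiological burst rate.
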