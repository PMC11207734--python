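# Methods

This note documents the models behind the simulator and the analysis
pipelines, the parameters that matter, the numerical conventions, and the
limits of what the synthetic validation shows.

## Timing model

All internal times are seconds; milliseconds appear only at the CLI /
reporting level.  Four named clocks are modelled: the control computer
(`ctrl`, command events), the kinetics acquisition (`kin`: force plates,
EMG and the photodiode analog channel at 1000 Hz), the EEG amplifier
(`eeg`, 500 Hz) and the fNIRS device (`nirs`, ~10 Hz).  Each clock is
affine in true time — offset, drift (ppm), optional white timestamp jitter
— which matches crystal-oscillator behaviour over session lengths of
minutes to an hour; higher-order drift is out of scope.  The default
simulated session uses identity clocks (the middleware-synchronized view);
non-trivial clocks are exercised in the alignment tests.  Clock mappings
are fitted by ordinary least squares on shared marker pairs; with exact
affine data the residual RMS is at floating-point level (< 1 ns over a
300 s session), and with 1 ms marker jitter it reproduces the jitter SD.

## Display chain

Stimulus commands are quantized *up* to the next 60 Hz frame boundary (a
command exactly on a boundary displays in that frame) and delayed by a
fixed projector latency (default 50 ms).  In the healthy `single_script`
mode the photodiode blink shares the stimulus frame, so decoded blink time
minus true display time is zero up to one photodiode sample (1 ms).  In the
faulty `two_script` mode the blink is issued by a second, event-chained
script and appears a variable delay after the stimulus.  That delay is
modelled directly as a uniform draw on the configured 12–56 ms envelope:
the envelope is the observed net effect of the event-chaining mechanism
(script scheduling at 300 Hz, chained event dispatch, frame output), and
imposing an additional frame-grid re-quantization on top of it would force
the delays onto 16.7 ms multiples, which the observed envelope does not
show.  The jitter diagnostic flags a delay range exceeding half a frame
period (8.33 ms): a delay constant up to frame quantization is
"synchronous" for this system, anything larger indicates the two-script
fault.  With 120 events the empirical maximum of the uniform envelope lies
within a millisecond of its 56 ms top, so the diagnostic reproduces the
envelope faithfully.

## Photodiode byte codec

Framing is 1 start bit (high) + 8 data bits LSB-first + 1 stop bit (low),
2 display frames per bit (33.3 ms per bit at 60 Hz; one byte = 333 ms).
Start/stop framing makes decoding self-synchronizing and the 2-frame bit
tolerates a dropped frame; both are configurable (`CodecConfig`) since the
encoding is a lab convention, not a standard.  The Schmitt stage uses
0.6/0.4 V thresholds on a 1 V blink: values inside the hysteresis band
never change state, so band-limited noise cannot retrigger edges.  Bits are
sampled at their temporal midpoints (robust to ±1 sample edge jitter)
rather than by edge counting.  The decoded event timestamp is the
rising-edge time of the start bit — what a hardware trigger would latch —
so it carries the full display delay, which is exactly what delay
compensation requires.  At the default 1000 Hz analog rate the noise margin
is large: with Gaussian noise of SD 0.1 V a spurious state change requires
a > 4 SD excursion against the hysteresis, and the round trip over all 256
codes stays exact in practice.

## EEG / VEP

The evoked template is a sum of Gaussian components carrying the N75
(65 ms, −5.39 µV) and P100 (90 ms, +9.15 µV).  Component widths are 7/8 ms
(FWHM ≈ 16/19 ms): narrow enough that the overlap of the two components
biases either recovered peak latency by well under one millisecond (with
~10–12 ms widths the P100 tail pulls the recovered N75 several ms early),
while remaining in the physiological range for transient pattern-reversal
components.  Background activity is 1/f-shaped noise with a 6 µV RMS
default: single trials are visibly noisy, while the 120-trial average
retains ≈ 0.55 µV residual, small against the ±15% amplitude band used in
validation.  (A much lower single-trial SNR would make the amplitude
criterion statistically unattainable at 120 trials — the residual scales as
RMS/√N.)

The acquisition chain of the EEG amplifier delays the recorded data by a
constant (default 10 ms, `acquisition_delay_eeg`); the simulator places the
evoked components at display time + that delay.  Because the hardware
trigger input of an amplifier shares its acquisition path, a trigger fed
into the recording carries the same constant — event-locked latencies are
therefore unbiased in the real setup.  `compensate_display_delay`
reproduces this: it locks analyses to photodiode-decoded times and applies
the known constant acquisition delay of the target modality (default 0).
Command times are never used for locking; doing so would bias latencies by
exactly the projector delay, and the controlled comparison in the tests
shows precisely that shift.

Preprocessing: zero-phase Butterworth high-pass (order 2 at 0.01 Hz) and
low-pass (order 4 at 40 Hz) plus a Q = 30 notch at 50 Hz; common-average
re-reference when ≥ 2 channels (the simulated montage has a single
occipital channel, so the step is skipped with a warning).  An
`artifact_correction` hook (identity by default) stands where an ICA-based
ocular cleanup would run on real data; ocular artifacts are not simulated.
Epoching is resampling-free (nearest-sample anchor, whole-sample offsets);
trials clipped by the recording edge are NaN-padded and flagged, never
dropped.  Averages use per-epoch linear detrend, baseline correction over
−500…−100 ms (the baseline mean of the average is zero to numerical
precision) and a normal-approximation 95% CI (1.96·SEM), adequate at 50–120
trials.  Peak search windows (N75: 50–90 ms, P100: 70–150 ms) follow
standard transient-VEP practice and are configurable; atypical latencies
clip at the window edge and are flagged, not silently truncated.  The
band-pass chain costs the 8 ms-wide P100 a few percent of amplitude
(≈ 8.6 µV recovered from a noise-free 9.15 µV template), well inside the
validation band.

## COP movement onset

Both COP directions are filtered with a zero-phase 2nd-order Butterworth at
5 Hz (reflective padding of 3× the filter order suppresses edge
transients), differenced per sample, and combined as √(dAP² + dML²).  The
first crossing of 0.3 marks the step excursion; among local minima within
±2 s whose height is ≤ 0.05, the one nearest the crossing is the onset
(equidistant ties go to the earlier candidate, since the onset physically
precedes the excursion; a plateau's first sample is its candidate).  The
0.3/0.05 thresholds are treated as mm-per-sample COP displacement at
1000 Hz — the thresholds and the input units must be configured together,
because rescaling the COP rescales the statistic one-for-one.  Whether the
original convention differenced per sample or per second is not
determinable from the method description; per-sample is adopted and
configurable.

The simulator's stance sway is band-limited (0.1–0.8 Hz) COP velocity
integrated to a 3 mm RMS position.  In the ~120 ms before each onset the
sway velocity fades to 3% (anticipatory stillness before a self-initiated
step), and the step itself is a quintic (C²-continuous) anteroposterior
excursion of 150 mm over 0.6 s.  The quintic shape matters: a rise with a
curvature jump at onset has spectral content above 5 Hz which the
zero-phase filter smears ~40 ms *backwards*, so the quiet-minimum rule
would systematically read planted onsets ~40 ms early.  With the C² rise
the combined statistic forms a sharp quiet minimum at the planted onset and
detection lands within 15 ms on ≥ 49 of 50 trials (residual method offset
≈ −10 ms, the onset-precedes-excursion geometry of the rule).  Real step
onsets are less crisp than this construction, so recovery accuracy on real
force-plate data should be expected to be worse, and the thresholds may
need re-calibration against the plant's units.  Baseline QC flags trials
whose pre-onset combined statistic exceeds 0.05 or whose onset is missing;
flags are advisory and an explicit manual exclusion/inclusion list
overrides them in both directions, mirroring the visual-inspection step
this detector is normally paired with.

## EMG

DC removal over the full recording, rectification, and a centered (not
causal) 100-point moving average — centered preserves burst-onset timing
symmetry.  Epochs (−5…+15 s) lock to the *kinetic* onsets from the COP
detector, never to the EMG's own burst times.  The simulated burst
(band-limited 20–150 Hz activity, 8× the baseline amplitude) starts 120 ms
before the kinetic onset; the lead is configurable and recorded in the
session metadata, since only the physiological order (activation precedes
movement) is constrained, not its exact magnitude.

## fNIRS

The canonical hemodynamic response is a three-Gaussian composition: initial
dip at 1.5 s (18% of peak), main peak at 7 s (σ = 2 s), undershoot at
11.5 s (25%), returning to baseline by ~17 s; HbR is generated at −1/3 the
HbO₂ amplitude lagged 1 s (a conventional shape — the component
overlaps shift the composite argmax by < 0.1 s from the nominal peak time).
Default amplitude is 0.5 µM, a typical event-related motor response.
Systemic physiology (Mayer wave 0.1 Hz, respiration 0.25 Hz, cardiac 1 Hz)
enters the short channel fully and the long channels with weight 0.7.
Concentrations are forward-modelled to optical intensities through the same
modified Beer–Lambert relation the analysis inverts — OD = −log10(I/Ī),
2×2 extinction system (Gratzer/Cope tabulated molar coefficients at
760/850 nm), pathlength = source–detector distance × DPF (defaults 3 cm /
1 cm and DPF 6.0, both config-exposed since device-specific).  Noise-free,
the analysis recovers the planted concentrations to < 1e-6 µM up to the
common baseline offset of the mean-referenced OD.

The analysis band-pass (0.02–0.2 Hz, zero-phase order 2) removes cardiac
and respiratory components; the Mayer wave survives it and is removed by
the short-channel regression (per-chromophore OLS of each long channel on
its nearest short channel, residual kept), which cuts 0.1 Hz power by well
over 80% on the default session.  "Nearest short channel" assignment is
montage metadata; the simulated montage is minimal (2 long + 1 short) —
full-head montages are hardware description, not algorithmic content.
Shape metrics on the onset-locked average (baseline −5…−0.1 s): dip =
minimum in 0–3 s, peak = maximum in 3–12 s, return = first time after the
peak with |value| < 10% of the peak.

## Validation scale and limitations

The built-in validation runs at the reference task scale — 120 checkerboard
reversals (310 s session) and 50 step cycles (~28 min of simulated
recording) — which completes in seconds on one core.  What passing shows:
the trigger chain, codec, clock fits and event-locked pipelines are
internally consistent and recover planted ground truth at the stated
tolerances.  What it does not show: robustness to real-world artifacts not
in the generative model (ocular and motion artifacts in EEG, optode
decoupling in fNIRS, treadmill vibration in COP, non-uniform two-script
delay distributions), nor the absolute accuracy of the COP thresholds in a
particular plant's units.  The XDF reader covers the numeric/string-marker
subset of the container needed for session import; there is no write
support and no native support for vendor formats (C3D, SNIRF).
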