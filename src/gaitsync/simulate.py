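"""Acquisition simulator: complete synthetic sessions with ground truth.

Two tasks are generated, mirroring the validation experiments of a
projection-based gait lab:

* ``checkerboard`` — a seated pattern-reversal task: a checkerboard reverses
  contrast at 0.5 Hz (120 reversals over four minutes, 35 s rest before and
  after), evoking a visual potential at the occipital electrode.  The
  display chain quantizes stimulus commands to 60 Hz frames and adds a fixed
  projector delay; a photodiode byte marks every reversal.
* ``start_to_go`` — repeated voluntary step initiation: 50 cycles of quiet
  standing (15 s), a variable 5–10 s wait, then a self-paced forward step.
  Force-plate center of pressure (COP), tibialis-anterior EMG and a minimal
  fNIRS montage (two long channels over sensorimotor cortex, one short
  scalp channel) are generated around the true onsets.

The display chain supports two trigger modes: ``single_script`` (stimulus
and photodiode blink issued in the same frame, so the decoded blink time is
the true display time) and ``two_script`` (the blink issued by a second,
event-chained script, delayed by a variable amount within a configured
envelope — the faulty configuration whose jitter the alignment diagnostics
must expose).

Every generator takes an explicit seed; identical (config, seed) yields a
bit-identical bundle.  All ground truth needed for parameter-recovery
testing (true display times, blink display times, true onsets, clock
parameters) is stored in the bundle metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .codec import CodecConfig, byte_bits
from .evoked import mbll_optical_density
from .streams import MarkerEvent, StreamBundle, TimestampedStream

# Clock names used throughout: the control computer issuing commands, the
# kinetics acquisition (force plates / EMG / photodiode analog channel at
# 1000 Hz), the EEG amplifier and the fNIRS device.
CTRL_CLOCK = "ctrl"
KIN_CLOCK = "kin"
EEG_CLOCK = "eeg"
NIRS_CLOCK = "nirs"


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class ClockModel:
    """Affine local clock: t_local = offset + (1 + drift_ppm*1e-6) * t_true.

    ``jitter_sd`` adds white per-timestamp jitter (seconds); keep it well
    below the sampling interval or the monotonicity invariant breaks.
    """

    clock_id: str
    offset: float = 0.0
    drift_ppm: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.drift_ppm) >= 1000:
            raise ValueError("|drift| must be < 1000 ppm for plausible hardware")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def to_local(self, t_true: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        t = self.offset + (1.0 + self.drift_ppm * 1e-6) * np.asarray(t_true, float)
        if self.jitter_sd > 0 and rng is not None:
            t = t + rng.normal(0.0, self.jitter_sd, size=np.shape(t))
        return t


@dataclass
class DisplayChainConfig:
    """Timing model of the projection chain.

    The control script runs at ``script_rate`` but output is tied to frame
    generation at ``frame_rate``; the projector adds a fixed delay.  In
    ``two_script`` mode the photodiode blink is issued by a second script
    chained off a stimulus event, appearing on screen a variable
    ``two_script_delay`` (uniform envelope, seconds) after the stimulus.
    ``acquisition_delay_eeg`` is the constant delay of the EEG acquisition
    chain relative to the common timeline.
    """

    script_rate: float = 300.0
    frame_rate: float = 60.0
    projector_delay: float = 0.050
    mode: str = "single_script"
    two_script_delay: tuple[float, float] = (0.012, 0.056)
    acquisition_delay_eeg: float = 0.010

    def __post_init__(self) -> None:
        if not self.script_rate >= self.frame_rate > 0:
            raise ValueError("need script_rate >= frame_rate > 0")
        lo, hi = self.two_script_delay
        if not 0 <= lo <= hi:
            raise ValueError("two_script_delay range must be non-negative and ordered")
        if self.mode not in ("single_script", "two_script"):
            raise ValueError(f"unknown display mode {self.mode!r}")

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class VEPTemplate:
    """Sum-of-Gaussians evoked-response template.

    Each component is (latency s, amplitude µV, width s).  Defaults carry
    the N75 negativity (65 ms, −5.39 µV) and the P100 positivity (90 ms,
    9.15 µV).  Widths (7/8 ms Gaussian sigma, FWHM ≈ 16/19 ms) are chosen
    narrow enough that the components' overlap biases either recovered peak
    latency by well under a millisecond.
    """

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.065, -5.39, 0.007), (0.090, 9.15, 0.008)]
    )

    def __post_init__(self) -> None:
        for lat, amp, width in self.components:
            if width <= 0:
                raise ValueError("component widths must be > 0")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Template evaluated at times *t* (seconds after stimulus)."""
        out = np.zeros_like(np.asarray(t, float))
        for lat, amp, width in self.components:
            out += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
        return out


@dataclass
class HRFParams:
    """Canonical hemodynamic response: initial dip, peak, undershoot, return.

    Amplitude is the HbO2 peak height in µM; the dip and undershoot depths
    are expressed as fractions of it.  Deoxygenated hemoglobin is generated
    at −1/3 the HbO2 amplitude, lagged by 1 s (conventional shape).
    """

    peak_time: float = 7.0
    peak_width: float = 2.0
    dip_time: float = 1.5
    dip_frac: float = 0.18
    dip_width: float = 0.6
    undershoot_time: float = 11.5
    undershoot_frac: float = 0.25
    undershoot_width: float = 1.8
    return_time: float = 17.0
    amplitude: float = 0.5  # µM
    hbr_ratio: float = -1.0 / 3.0
    hbr_lag: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.dip_time < self.peak_time < self.return_time:
            raise ValueError("need 0 < dip_time < peak_time < return_time")

    def shape(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak HbO2 response at times *t* (s after onset); 0 for t<0."""
        t = np.asarray(t, float)
        h = (
            np.exp(-0.5 * ((t - self.peak_time) / self.peak_width) ** 2)
            - self.dip_frac * np.exp(-0.5 * ((t - self.dip_time) / self.dip_width) ** 2)
            - self.undershoot_frac
            * np.exp(-0.5 * ((t - self.undershoot_time) / self.undershoot_width) ** 2)
        )
        return np.where(t >= 0, h, 0.0)


@dataclass
class ScheduleConfig:
    """Task schedules.

    Checkerboard: reversals at ``reversal_rate`` during ``stimulation_phase``
    seconds, flanked by rest (0.5 Hz x 240 s = 120 stimulations).
    Start-to-go: ``n_cycles`` cycles of ``stand_duration`` quiet standing
    plus a uniform wait drawn from ``wait_range`` before the true movement
    onset.  ``emg_lead`` is the interval by which the muscle burst precedes
    the kinetic onset (the physiological order: activation drives movement).
    """

    reversal_rate: float = 0.5
    stimulation_phase: float = 240.0
    rest_before: float = 35.0
    rest_after: float = 35.0
    n_cycles: int = 50
    stand_duration: float = 15.0
    wait_range: tuple[float, float] = (5.0, 10.0)
    cycle_tail: float = 12.0  # step execution + return + settle, after onset
    emg_lead: float = 0.120

    def __post_init__(self) -> None:
        lo, hi = self.wait_range
        if not lo <= hi:
            raise ValueError("wait_range must be ordered")
        for v in (self.reversal_rate, self.stimulation_phase, self.rest_before,
                  self.rest_after, self.stand_duration, self.cycle_tail):
            if v <= 0:
                raise ValueError("all durations must be positive")


# ---------------------------------------------------------------------------
# Geometry and schedules
# ---------------------------------------------------------------------------


def visual_angle(extent: float, distance: float) -> float:
    """Visual angle (degrees) subtended by *extent* meters at *distance* meters.

    angle = 2 * atan(extent / (2 * distance)).  A 1.4 cm fixation point at
    2.5 m subtends 0.32 degrees.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if extent < 0:
        raise ValueError("extent must be >= 0")
    return math.degrees(2.0 * math.atan2(extent / 2.0, distance))


def schedule_checkerboard(cfg: ScheduleConfig | None = None) -> list[MarkerEvent]:
    """Command events of the checkerboard task (one per contrast reversal).

    Events occur at rest_before + k / reversal_rate for
    k = 0 .. reversal_rate * stimulation_phase − 1; codes alternate 1/2 for
    the two reversal polarities.
    """
    cfg = cfg or ScheduleConfig()
    n = int(round(cfg.reversal_rate * cfg.stimulation_phase))
    return [
        MarkerEvent(code=1 + (k % 2), time=cfg.rest_before + k / cfg.reversal_rate,
                    clock_id=CTRL_CLOCK, source="command")
        for k in range(n)
    ]


def schedule_start_to_go(
    cfg: ScheduleConfig | None = None, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """True movement-onset times and per-cycle (start, end) windows.

    Within each cycle the onset is cycle_start + stand_duration + U(wait_range);
    the cycle ends ``cycle_tail`` seconds after its onset.  Reproducible for
    a fixed seed.
    """
    cfg = cfg or ScheduleConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = []
    cycles = []
    t = 5.0  # initial settling before the first cycle
    lo, hi = cfg.wait_range
    for _ in range(cfg.n_cycles):
        onset = t + cfg.stand_duration + rng.uniform(lo, hi)
        end = onset + cfg.cycle_tail
        onsets.append(onset)
        cycles.append((t, end))
        t = end
    return np.asarray(onsets), cycles


# ---------------------------------------------------------------------------
# Display chain
# ---------------------------------------------------------------------------


def render_display_chain(
    command_events: list[MarkerEvent],
    chain: DisplayChainConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map command times to (true_display_times, blink_display_times).

    A command is quantized up to the next frame boundary (a command exactly
    on a boundary displays in that frame) and delayed by the projector.  In
    ``single_script`` mode the photodiode blink shares the stimulus frame,
    so blink and stimulus appear simultaneously.  In ``two_script`` mode the
    blink appears a uniform draw from the configured envelope later — the
    observed net effect of the event-chained second script.
    """
    chain = chain or DisplayChainConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_cmd = np.asarray([e.time for e in command_events], float)
    frame = chain.frame_period
    stim_frame = np.ceil(t_cmd / frame - 1e-9) * frame
    display = stim_frame + chain.projector_delay
    if chain.mode == "single_script":
        blink = display.copy()
    else:
        lo, hi = chain.two_script_delay
        blink = display + rng.uniform(lo, hi, size=len(display))
    return display, blink


# ---------------------------------------------------------------------------
# Modality synthesis
# ---------------------------------------------------------------------------


def synth_photodiode(
    blink_events: list[tuple[float, int]],
    codec: CodecConfig | None = None,
    noise_sd: float = 0.02,
    fs: float = 1000.0,
    duration: float | None = None,
    clock: ClockModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TimestampedStream:
    """Analog photodiode trace carrying byte blinks at the given times.

    ``blink_events`` is a list of (display_time, code).  The trace is high
    during encoded high frames, low otherwise, plus Gaussian noise, sampled
    on the kinetics clock.  Events closer together than the byte duration
    collide on the display and raise an error naming them.
    """
    codec = codec or CodecConfig()
    clock = clock or ClockModel(KIN_CLOCK)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = sorted(blink_events, key=lambda e: e[0])
    for (t0, c0), (t1, c1) in zip(times, times[1:]):
        if t1 - t0 < codec.byte_duration:
            raise ValueError(
                f"byte frames collide: events (t={t0:.3f}, code={c0}) and "
                f"(t={t1:.3f}, code={c1}) are closer than {codec.byte_duration:.3f} s"
            )
    if duration is None:
        duration = (times[-1][0] + codec.byte_duration + 1.0) if times else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.full(n, codec.low_level)
    bit = codec.bit_duration
    for t0, code in times:
        bits = byte_bits(code)
        i0 = int(np.ceil(t0 * fs - 1e-9))
        i1 = min(n, int(np.ceil((t0 + codec.byte_duration) * fs - 1e-9)))
        if i0 >= n:
            continue
        idx = np.arange(i0, i1)
        b = np.minimum(((idx / fs - t0) / bit).astype(int), 9)
        x[idx] = np.where(np.asarray(bits)[b] == 1, codec.high_level, codec.low_level)
    x = x + rng.normal(0.0, noise_sd, n)
    return TimestampedStream(
        name="photodiode", modality="photodiode_analog", channel_labels=["pd"],
        units=["V"], nominal_rate=fs, samples=x[:, None],
        timestamps=clock.to_local(t, rng), clock_id=clock.clock_id,
    )


def one_over_f_noise(
    n: int, fs: float, rms: float, rng: np.random.Generator, f_floor: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/max(f, f_floor)."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, f_floor))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def synth_eeg(
    display_times: np.ndarray,
    template: VEPTemplate | None = None,
    fs: float = 500.0,
    noise_rms: float = 6.0,
    chain: DisplayChainConfig | None = None,
    duration: float | None = None,
    clock: ClockModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TimestampedStream:
    """Occipital-channel EEG: 1/f background + evoked template per stimulus.

    The evoked components are placed at display_time + acquisition_delay_eeg
    (the data path of the amplifier); the background is 1/f-shaped noise
    with the given RMS in µV.  Default noise (6 µV RMS against a 9.15 µV
    peak) leaves single trials visibly noisy while a 120-trial average
    recovers the template to a few percent.
    """
    template = template or VEPTemplate()
    chain = chain or DisplayChainConfig()
    clock = clock or ClockModel(EEG_CLOCK)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    display_times = np.asarray(display_times, float)
    if duration is None:
        duration = (display_times.max() + 2.0) if len(display_times) else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = one_over_f_noise(n, fs, noise_rms, rng) if noise_rms > 0 else np.zeros(n)
    span = max(lat + 6 * w for lat, _, w in template.components)
    for t_disp in display_times:
        t0 = t_disp + chain.acquisition_delay_eeg
        i0 = max(0, int((t0 - 0.01) * fs))
        i1 = min(n, int((t0 + span) * fs) + 1)
        x[i0:i1] += template.waveform(t[i0:i1] - t0)
    return TimestampedStream(
        name="eeg", modality="eeg", channel_labels=["Oz"], units=["µV"],
        nominal_rate=fs, samples=x[:, None],
        timestamps=clock.to_local(t, rng), clock_id=clock.clock_id,
    )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smootherstep(u: np.ndarray) -> np.ndarray:
    # quintic step: C2-continuous, so its spectral content stays within the
    # 5 Hz analysis band and zero-phase filtering does not smear the onset
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (6.0 * u * u - 15.0 * u + 10.0)


@dataclass
class SwayParams:
    """Quiet-stance COP sway and step-excursion shape.

    Sway is generated as band-limited (``band`` Hz) COP velocity integrated
    to position with RMS ``amplitude_mm``.  In the ~120 ms before each
    onset the sway velocity is scaled down to ``1 - quiescence`` of its
    amplitude (anticipatory stillness before a self-initiated step); this
    is what gives the planted movement onset a sharp, recoverable
    definition — real onsets are less crisp.  The step itself is a
    C2-smooth (quintic) anteroposterior excursion of ``step_amplitude_mm``
    over ``step_rise`` seconds.
    """

    amplitude_mm: float = 3.0
    band: tuple[float, float] = (0.1, 0.8)
    quiescence: float = 0.97
    quiescence_onset: float = 0.12  # s before onset the velocity fade starts
    step_amplitude_mm: float = 150.0
    step_rise: float = 0.6


def synth_cop(
    onset_times: np.ndarray,
    sway: SwayParams | None = None,
    fs: float = 1000.0,
    duration: float | None = None,
    clock: ClockModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TimestampedStream:
    """COP trace (AP, ML in mm) with step excursions at the true onsets.

    Baseline sway is integrated band-limited velocity; before each onset
    the velocity envelope fades (quiescence), then the AP trace rises
    smoothly (quintic over ``step_rise`` s) into the step excursion and
    returns slowly afterwards.  Scaling puts the combined-derivative
    statistic well above 0.3 mm/sample during the step and below 0.05
    during stance.
    """
    sway = sway or SwayParams()
    clock = clock or ClockModel(KIN_CLOCK)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onset_times = np.asarray(onset_times, float)
    if duration is None:
        duration = (onset_times.max() + 15.0) if len(onset_times) else 10.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    def sway_velocity() -> np.ndarray:
        if sway.amplitude_mm <= 0:
            return np.zeros(n)
        sos = sps.butter(4, sway.band, btype="band", fs=fs, output="sos")
        v = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
        pos = np.cumsum(v) / fs
        return v * (sway.amplitude_mm / pos.std())

    env = np.ones(n)
    step = np.zeros(n)
    for t0 in onset_times:
        # anticipatory quiescence: sway velocity fades just before the onset
        env -= sway.quiescence * (
            _smootherstep((t - (t0 - sway.quiescence_onset)) / (sway.quiescence_onset - 0.01))
            - _smootherstep((t - (t0 + 1.5)) / 1.0)
        )
        step += sway.step_amplitude_mm * (
            _smootherstep((t - t0) / sway.step_rise) - _smootherstep((t - (t0 + 4.0)) / 5.0)
        )
    env = np.clip(env, 1.0 - sway.quiescence, 1.0)
    ap = np.cumsum(sway_velocity() * env) / fs + step
    ml = np.cumsum(sway_velocity() * env) / fs
    samples = np.column_stack([ap, ml])
    return TimestampedStream(
        name="cop", modality="cop", channel_labels=["AP", "ML"], units=["mm", "mm"],
        nominal_rate=fs, samples=samples,
        timestamps=clock.to_local(t, rng), clock_id=clock.clock_id,
    )


def synth_emg(
    onset_times: np.ndarray,
    lead: float = 0.120,
    fs: float = 1000.0,
    duration: float | None = None,
    burst_gain: float = 8.0,
    baseline_sd: float = 0.01,
    clock: ClockModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TimestampedStream:
    """Tibialis-anterior EMG: baseline noise + bursts preceding each onset.

    The burst (band-limited 20–150 Hz activity at ``burst_gain`` times the
    baseline amplitude) starts ``lead`` seconds before the kinetic onset —
    muscle activation drives the movement, so it must lead the force-plate
    onset.
    """
    clock = clock or ClockModel(KIN_CLOCK)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onset_times = np.asarray(onset_times, float)
    if duration is None:
        duration = (onset_times.max() + 15.0) if len(onset_times) else 10.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sos = sps.butter(4, [20.0, 150.0], btype="band", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    carrier /= carrier.std()
    envelope = np.ones(n)
    for t0 in onset_times:
        start = t0 - lead
        envelope += (burst_gain - 1.0) * (
            _smoothstep((t - start) / 0.05) - _smoothstep((t - (t0 + 0.5)) / 0.3)
        )
    x = baseline_sd * carrier * envelope
    return TimestampedStream(
        name="emg", modality="emg", channel_labels=["TA_right"], units=["mV"],
        nominal_rate=fs, samples=x[:, None],
        timestamps=clock.to_local(t, rng), clock_id=clock.clock_id,
    )


#: Minimal fNIRS montage: two long sensorimotor channels + one short scalp
#: channel; distances in meters.
DEFAULT_MONTAGE = {
    "channels": ["long_1", "long_2", "short_1"],
    "distances": {"long_1": 0.03, "long_2": 0.03, "short_1": 0.01},
    "nearest_short": {"long_1": "short_1", "long_2": "short_1"},
}


def synth_fnirs(
    onset_times: np.ndarray,
    hrf: HRFParams | None = None,
    fs: float = 10.0,
    montage: dict | None = None,
    systemic_weight: float = 0.7,
    noise_rel: float = 2e-5,
    dpf: float = 6.0,
    duration: float | None = None,
    clock: ClockModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[TimestampedStream, TimestampedStream, dict]:
    """Two-wavelength fNIRS intensity streams (760 nm, 850 nm) + ground truth.

    Ground-truth hemoglobin changes: the HRF at each onset in the long
    (brain) channels, HbR at −1/3 amplitude lagged 1 s.  Systemic
    oscillations (Mayer wave 0.1 Hz, respiration 0.25 Hz, cardiac 1 Hz) go
    fully into the short channel and with weight ``systemic_weight`` into
    long channels.  Concentrations are forward-modelled to optical
    intensities through the same modified Beer–Lambert relation the analysis
    inverts, with small multiplicative measurement noise.
    """
    hrf = hrf or HRFParams()
    montage = montage or DEFAULT_MONTAGE
    clock = clock or ClockModel(NIRS_CLOCK)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not any(ch.startswith("short") for ch in montage["channels"]):
        raise ValueError("montage must include a short channel (correction stage requires one)")
    onset_times = np.asarray(onset_times, float)
    if duration is None:
        duration = (onset_times.max() + 25.0) if len(onset_times) else 60.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    brain_hbo = np.zeros(n)
    for t0 in onset_times:
        brain_hbo += hrf.amplitude * hrf.shape(t - t0)
    brain_hbr = np.zeros(n)
    for t0 in onset_times:
        brain_hbr += hrf.amplitude * hrf.hbr_ratio * hrf.shape(t - t0 - hrf.hbr_lag)

    phases = rng.uniform(0, 2 * np.pi, 3)
    systemic_hbo = (
        0.30 * np.sin(2 * np.pi * 0.10 * t + phases[0])
        + 0.10 * np.sin(2 * np.pi * 0.25 * t + phases[1])
        + 0.08 * np.sin(2 * np.pi * 1.00 * t + phases[2])
    )
    systemic_hbr = -0.3 * systemic_hbo

    conc = {}  # channel -> (n, 2) µM [HbO2, HbR]
    for ch in montage["channels"]:
        if ch.startswith("short"):
            hbo, hbr = systemic_hbo, systemic_hbr
        else:
            hbo = brain_hbo + systemic_weight * systemic_hbo
            hbr = brain_hbr + systemic_weight * systemic_hbr
        conc[ch] = np.column_stack([hbo, hbr])

    i0 = 1.0  # arbitrary source intensity
    intensities = {760: {}, 850: {}}
    for ch in montage["channels"]:
        od = mbll_optical_density(conc[ch], montage["distances"][ch], dpf)
        for w, col in ((760, 0), (850, 1)):
            noise = 1.0 + rng.normal(0.0, noise_rel, n) if noise_rel > 0 else 1.0
            intensities[w][ch] = i0 * 10.0 ** (-od[:, col]) * noise

    ts = clock.to_local(t, rng)
    streams = []
    for w in (760, 850):
        streams.append(
            TimestampedStream(
                name=f"fnirs_{w}", modality="fnirs_intensity",
                channel_labels=list(montage["channels"]),
                units=["au"] * len(montage["channels"]),
                nominal_rate=fs,
                samples=np.column_stack([intensities[w][ch] for ch in montage["channels"]]),
                timestamps=ts.copy(), clock_id=clock.clock_id,
            )
        )
    truth = {
        "brain_hbo_um": brain_hbo,
        "brain_hbr_um": brain_hbr,
        "systemic_hbo_um": systemic_hbo,
        "dpf": dpf,
        "systemic_weight": systemic_weight,
        "montage": montage,
    }
    return streams[0], streams[1], truth


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def simulate_session(
    task: str,
    seed: int = 0,
    schedule: ScheduleConfig | None = None,
    chain: DisplayChainConfig | None = None,
    codec: CodecConfig | None = None,
    template: VEPTemplate | None = None,
    hrf: HRFParams | None = None,
    sway: SwayParams | None = None,
    eeg_noise_rms: float = 6.0,
    pd_noise_sd: float = 0.02,
    clocks: dict[str, ClockModel] | None = None,
) -> StreamBundle:
    """Generate a complete synthetic session bundle with ground truth.

    ``task`` is ``"checkerboard"`` or ``"start_to_go"``.  The bundle holds
    the modality streams, the command events, the photodiode analog channel,
    and a metadata block with the true display/blink times, true onsets and
    clock parameters.  Bit-identical for identical (configs, seed).
    """
    schedule = schedule or ScheduleConfig()
    chain = chain or DisplayChainConfig()
    codec = codec or CodecConfig(frame_rate=chain.frame_rate)
    clocks = clocks or {
        c: ClockModel(c) for c in (CTRL_CLOCK, KIN_CLOCK, EEG_CLOCK, NIRS_CLOCK)
    }
    ss = np.random.SeedSequence(seed)
    r_chain, r_pd, r_eeg, r_cop, r_emg, r_nirs, r_sched = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    bundle = StreamBundle()
    meta: dict = {
        "task": task,
        "seed": seed,
        "clocks": [CTRL_CLOCK, KIN_CLOCK, EEG_CLOCK, NIRS_CLOCK],
        "clock_params": {c: asdict(m) for c, m in clocks.items()},
        "display_chain": asdict(chain),
        "codec": asdict(codec),
        "acquisition_delay_eeg": chain.acquisition_delay_eeg,
    }

    if task == "checkerboard":
        commands = schedule_checkerboard(schedule)
        display, blink = render_display_chain(commands, chain, r_chain)
        duration = schedule.rest_before + schedule.stimulation_phase + schedule.rest_after
        pd_stream = synth_photodiode(
            [(tb, e.code) for tb, e in zip(blink, commands)], codec,
            noise_sd=pd_noise_sd, duration=duration, clock=clocks[KIN_CLOCK], seed=r_pd,
        )
        eeg_stream = synth_eeg(
            display, template, noise_rms=eeg_noise_rms, chain=chain,
            duration=duration, clock=clocks[EEG_CLOCK], seed=r_eeg,
        )
        bundle.streams = [pd_stream, eeg_stream]
        bundle.events = [
            MarkerEvent(e.code, float(clocks[CTRL_CLOCK].to_local(e.time)), CTRL_CLOCK, "command")
            for e in commands
        ]
        meta["true_display_times"] = display.tolist()
        meta["blink_display_times"] = blink.tolist()
        meta["command_times"] = [e.time for e in commands]
    elif task == "start_to_go":
        onsets, cycles = schedule_start_to_go(schedule, r_sched)
        duration = cycles[-1][1] + 5.0
        # photodiode start/stop byte per cycle, through the display chain
        commands = []
        for (c0, c1) in cycles:
            commands.append(MarkerEvent(3, c0, CTRL_CLOCK, "command"))
            commands.append(MarkerEvent(4, c1 - 1.0, CTRL_CLOCK, "command"))
        commands.sort(key=lambda e: e.time)
        display, blink = render_display_chain(commands, chain, r_chain)
        pd_stream = synth_photodiode(
            [(tb, e.code) for tb, e in zip(blink, commands)], codec,
            noise_sd=pd_noise_sd, duration=duration, clock=clocks[KIN_CLOCK], seed=r_pd,
        )
        cop_stream = synth_cop(onsets, sway, duration=duration,
                               clock=clocks[KIN_CLOCK], seed=r_cop)
        emg_stream = synth_emg(onsets, lead=schedule.emg_lead, duration=duration,
                               clock=clocks[KIN_CLOCK], seed=r_emg)
        nirs760, nirs850, truth = synth_fnirs(
            onsets, hrf, duration=duration, clock=clocks[NIRS_CLOCK], seed=r_nirs,
        )
        bundle.streams = [pd_stream, cop_stream, emg_stream, nirs760, nirs850]
        bundle.events = [
            MarkerEvent(e.code, float(clocks[CTRL_CLOCK].to_local(e.time)), CTRL_CLOCK, "command")
            for e in commands
        ]
        meta["true_onsets"] = onsets.tolist()
        meta["cycles"] = [list(c) for c in cycles]
        meta["emg_lead"] = schedule.emg_lead
        meta["true_display_times"] = display.tolist()
        meta["blink_display_times"] = blink.tolist()
        meta["fnirs_montage"] = truth["montage"]
        meta["fnirs_dpf"] = truth["dpf"]
    else:
        raise ValueError(f"unknown task {task!r}")

    bundle.metadata = meta
    return bundle
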