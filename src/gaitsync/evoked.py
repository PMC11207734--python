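"""Stimulus/onset-locked analyses: VEP, EMG ensemble average, fNIRS.

Three pipelines share the epoching machinery:

* EEG / VEP — band-pass (0.01–40 Hz) + 50 Hz notch, common-average
  re-reference (skipped with a warning on single-channel data), epochs from
  −500 ms to +400 ms around each stimulus, per-epoch linear detrend and
  baseline correction (−500 to −100 ms), trial average with a 95% CI, and
  N75/P100 peak measurement in standard search windows.
* EMG — DC removal over the whole recording, rectification, a centered
  100-point moving average, epochs from −5 to +15 s around the kinetic
  onsets (always the force-plate onsets, never the EMG's own burst times).
* fNIRS — optical densities −log10(I/mean I), modified Beer–Lambert
  conversion to HbO2/HbR concentration changes via the tabulated molar
  extinction coefficients, 0.02–0.2 Hz band-pass, short-channel regression
  (ordinary least squares of each long channel on its nearest short
  channel; the residual is the corrected signal), onset-locked epochs and
  hemodynamic shape metrics (initial dip, peak, return time).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as sps

from .streams import EpochSet, MarkerEvent, StreamBundle, TimestampedStream

logger = logging.getLogger("gaitsync")


# ---------------------------------------------------------------------------
# Modified Beer-Lambert primitives (shared with the simulator's forward model)
# ---------------------------------------------------------------------------

#: Molar extinction coefficients [cm^-1 / (mol/L)], rows = (760 nm, 850 nm),
#: columns = (HbO2, HbR).  Standard tabulated values (Gratzer/Cope
#: compilation) as used throughout the fNIRS literature.
EXTINCTION = np.array(
    [
        [586.0, 1548.52],   # 760 nm
        [1058.0, 691.32],   # 850 nm
    ]
)


def mbll_optical_density(conc_um: np.ndarray, distance_m: float, dpf: float) -> np.ndarray:
    """Forward modified Beer-Lambert: ΔOD per wavelength from Δ[HbO2, HbR].

    ``conc_um``: (n, 2) concentration changes in µM; returns (n, 2) optical
    densities at (760, 850) nm with pathlength = distance * DPF.
    """
    conc_m = np.asarray(conc_um, float) * 1e-6
    path_cm = distance_m * 100.0 * dpf
    return conc_m @ EXTINCTION.T * path_cm


def mbll_concentration(od: np.ndarray, distance_m: float, dpf: float) -> np.ndarray:
    """Inverse modified Beer-Lambert: Δ[HbO2, HbR] in µM from ΔOD."""
    path_cm = distance_m * 100.0 * dpf
    inv = np.linalg.inv(EXTINCTION)
    return (np.asarray(od, float) @ inv.T) / path_cm * 1e6


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class VepConfig:
    bandpass: tuple[float, float] = (0.01, 40.0)
    notch: float = 50.0
    epoch_window: tuple[float, float] = (-0.5, 0.4)
    baseline: tuple[float, float] = (-0.5, -0.1)
    n75_window: tuple[float, float] = (0.05, 0.09)
    p100_window: tuple[float, float] = (0.07, 0.15)
    #: pluggable artifact-correction hook (e.g. an ICA step); identity default
    artifact_correction: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda x: x, repr=False
    )


@dataclass
class EmgConfig:
    moving_average_points: int = 100
    epoch_window: tuple[float, float] = (-5.0, 15.0)

    def __post_init__(self) -> None:
        if self.moving_average_points < 1:
            raise ValueError("moving_average_points must be >= 1")


@dataclass
class HemoConfig:
    bandpass: tuple[float, float] = (0.02, 0.2)
    epoch_window: tuple[float, float] = (-5.0, 15.0)
    baseline: tuple[float, float] = (-5.0, -0.1)
    wavelengths: tuple[int, int] = (760, 850)
    dpf: float = 6.0
    long_distance: float = 0.03
    short_distance: float = 0.01
    dip_window: tuple[float, float] = (0.0, 3.0)
    peak_window: tuple[float, float] = (3.0, 12.0)


@dataclass
class PeakMeasure:
    """A measured peak: label, latency (s), amplitude (µV or µM)."""

    label: str
    latency: float
    amplitude: float
    channel: str
    window: tuple[float, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class Evoked:
    """Trial-averaged event-locked response with a pointwise 95% CI."""

    times: np.ndarray
    data: np.ndarray        # (n_times, n_channels)
    ci: np.ndarray          # half-width of the 95% CI, same shape
    channel_labels: list[str]
    n_trials: int


# ---------------------------------------------------------------------------
# EEG preprocessing
# ---------------------------------------------------------------------------


def preprocess_eeg(stream: TimestampedStream, cfg: VepConfig | None = None) -> TimestampedStream:
    """Zero-phase band-pass + notch, then common-average re-reference.

    Single-channel input skips the re-reference with a warning (a common
    average of one channel would zero the data).
    """
    cfg = cfg or VepConfig()
    fs = stream.nominal_rate
    lo, hi = cfg.bandpass
    if fs < 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz below twice the band-pass edge {hi} Hz")
    x = stream.samples.copy()
    sos_hp = sps.butter(2, lo, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(4, hi, btype="lowpass", fs=fs, output="sos")
    b_n, a_n = sps.iirnotch(cfg.notch, Q=30.0, fs=fs)
    for j in range(x.shape[1]):
        y = sps.sosfiltfilt(sos_hp, x[:, j])
        y = sps.sosfiltfilt(sos_lp, y)
        y = sps.filtfilt(b_n, a_n, y)
        x[:, j] = y
    if x.shape[1] >= 2:
        x = x - x.mean(axis=1, keepdims=True)
    else:
        warnings.warn("single-channel EEG: skipping common-average re-reference")
    x = cfg.artifact_correction(x)
    out = stream.copy()
    out.samples = x
    return out


# ---------------------------------------------------------------------------
# Epoching and averaging
# ---------------------------------------------------------------------------


def epoch(
    stream: TimestampedStream,
    lock_events: list[MarkerEvent] | np.ndarray,
    window: tuple[float, float],
    baseline: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut fixed-length windows around each locking event.

    Events must live on the stream's clock (apply a clock mapping first).
    Locking is resampling-free: the sample nearest the event time anchors
    the window, and offsets are whole samples of the nominal rate.  Events
    whose window exceeds the recording are kept, NaN-padded and flagged —
    exclusion is a flag, never deletion.
    """
    if isinstance(lock_events, np.ndarray) or (
        lock_events and not isinstance(lock_events[0], MarkerEvent)
    ):
        lock_events = [MarkerEvent(0, float(t), stream.clock_id, "command") for t in lock_events]
    for e in lock_events:
        if e.clock_id != stream.clock_id:
            raise ValueError(
                f"event clock {e.clock_id!r} differs from stream clock "
                f"{stream.clock_id!r}; align first"
            )
    fs = stream.nominal_rate
    ts = stream.timestamps
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    offsets = np.arange(lo, hi + 1)
    times = offsets / fs
    n = stream.n_samples
    data = np.full((len(lock_events), len(offsets), stream.n_channels), np.nan)
    flagged = np.zeros(len(lock_events), dtype=bool)
    for k, e in enumerate(lock_events):
        i = int(np.searchsorted(ts, e.time))
        if i > 0 and (i == n or abs(ts[i - 1] - e.time) <= abs(ts[min(i, n - 1)] - e.time)):
            i -= 1
        idx = i + offsets
        valid = (idx >= 0) & (idx < n)
        data[k, valid, :] = stream.samples[idx[valid], :]
        if not valid.all():
            flagged[k] = True
    if baseline is None:
        baseline = (times[0], min(0.0, times[-1]))
    return EpochSet(
        data=data, times=times, channel_labels=list(stream.channel_labels),
        baseline_window=baseline,
        event_codes=np.array([e.code for e in lock_events]),
        qc_excluded=flagged,
    )


def detrend_baseline_average(
    epochs: EpochSet, baseline: tuple[float, float] | None = None, detrend: bool = True
) -> Evoked:
    """Per-epoch linear detrend, baseline correction, and trial average.

    The CI half-width is 1.96 x SEM across non-excluded trials (normal
    approximation; fine at the 50–120 trials these tasks produce).  The
    baseline-window mean of the average is zero by construction.
    """
    baseline = baseline or epochs.baseline_window
    data = epochs.included().copy()
    if data.shape[0] == 0:
        raise ValueError("no non-excluded trials to average")
    t = epochs.times
    if detrend:
        # least-squares line per trial/channel, computed on finite samples
        A = np.column_stack([t, np.ones_like(t)])
        for k in range(data.shape[0]):
            for ch in range(data.shape[2]):
                y = data[k, :, ch]
                m = np.isfinite(y)
                if m.sum() >= 2:
                    coef, *_ = np.linalg.lstsq(A[m], y[m], rcond=None)
                    data[k, :, ch] = y - A @ coef
    bmask = (t >= baseline[0]) & (t <= baseline[1])
    data -= np.nanmean(data[:, bmask, :], axis=1, keepdims=True)
    mean = np.nanmean(data, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(data, axis=0, ddof=1) / np.sqrt(data.shape[0])
    return Evoked(
        times=t, data=mean, ci=1.96 * sem,
        channel_labels=list(epochs.channel_labels), n_trials=data.shape[0],
    )


# ---------------------------------------------------------------------------
# VEP peaks
# ---------------------------------------------------------------------------


def find_vep_peaks(evoked: Evoked, cfg: VepConfig | None = None, channel: int = 0) -> dict[str, PeakMeasure]:
    """N75 (most negative in its window) and P100 (most positive in its window).

    A flat trace yields zero amplitudes at the window starts with a
    ``degenerate`` flag; an N75 found later than the P100 flags both with
    ``window_conflict``.
    """
    cfg = cfg or VepConfig()
    t = evoked.times
    y = evoked.data[:, channel]
    out: dict[str, PeakMeasure] = {}
    for label, window, picker in (
        ("N75", cfg.n75_window, np.argmin),
        ("P100", cfg.p100_window, np.argmax),
    ):
        m = (t >= window[0]) & (t <= window[1])
        if not m.any():
            raise ValueError(f"evoked trace does not cover the {label} window {window}")
        seg, tseg = y[m], t[m]
        flags = []
        if np.allclose(seg, seg[0]):
            out[label] = PeakMeasure(label, float(tseg[0]), 0.0,
                                     evoked.channel_labels[channel], window, ["degenerate"])
            continue
        i = picker(seg)
        out[label] = PeakMeasure(label, float(tseg[i]), float(seg[i]),
                                 evoked.channel_labels[channel], window, flags)
    if out["N75"].latency >= out["P100"].latency and not (
        "degenerate" in out["N75"].flags or "degenerate" in out["P100"].flags
    ):
        for p in out.values():
            p.flags.append("window_conflict")
    return out


def vep_pipeline(
    bundle: StreamBundle,
    lock_events: list[MarkerEvent],
    cfg: VepConfig | None = None,
    stream_name: str = "eeg",
) -> tuple[Evoked, dict[str, PeakMeasure], EpochSet]:
    """Full VEP chain: preprocess, epoch, detrend/baseline/average, peaks."""
    cfg = cfg or VepConfig()
    clean = preprocess_eeg(bundle.stream(stream_name), cfg)
    epochs = epoch(clean, lock_events, cfg.epoch_window, cfg.baseline)
    evoked = detrend_baseline_average(epochs)
    peaks = find_vep_peaks(evoked, cfg)
    return evoked, peaks, epochs


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def emg_pipeline(
    stream: TimestampedStream,
    onsets: list[MarkerEvent],
    cfg: EmgConfig | None = None,
) -> tuple[EpochSet, Evoked]:
    """DC removal, rectification, centered moving average, onset-locked average.

    ``onsets`` are the kinetic (force-plate) movement onsets; the EMG's own
    burst times are never used for locking.
    """
    cfg = cfg or EmgConfig()
    x = stream.samples[:, 0]
    x = np.abs(x - x.mean())
    kernel = np.ones(cfg.moving_average_points) / cfg.moving_average_points
    smooth = np.convolve(x, kernel, mode="same")
    proc = stream.copy()
    proc.samples = smooth[:, None]
    epochs = epoch(proc, onsets, cfg.epoch_window, baseline=(cfg.epoch_window[0], -0.5))
    evoked = detrend_baseline_average(epochs, detrend=False)
    return epochs, evoked


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------


def intensities_to_hemoglobin(
    stream_lo: TimestampedStream,
    stream_hi: TimestampedStream,
    distances: dict[str, float],
    cfg: HemoConfig | None = None,
) -> TimestampedStream:
    """Modified Beer-Lambert conversion of two wavelength streams to ΔHbO2/ΔHbR.

    Optical density is −log10(I / mean(I)) per channel; the 2x2 extinction
    system is solved with pathlength = source-detector distance x DPF.
    Non-positive intensity samples are flagged and linearly interpolated
    with a log entry before the conversion.
    """
    cfg = cfg or HemoConfig()
    if not np.array_equal(stream_lo.timestamps, stream_hi.timestamps):
        raise ValueError("wavelength streams must share timestamps")
    labels_out: list[str] = []
    cols: list[np.ndarray] = []
    for ch in stream_lo.channel_labels:
        od = np.empty((stream_lo.n_samples, 2))
        for col, s in enumerate((stream_lo, stream_hi)):
            inten = s.channel(ch).copy()
            bad = inten <= 0
            if bad.any():
                logger.warning(
                    "channel %s: %d non-positive intensity sample(s) interpolated",
                    ch, int(bad.sum()),
                )
                good = ~bad
                inten[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), inten[good])
            od[:, col] = -np.log10(inten / inten.mean())
        conc = mbll_concentration(od, distances[ch], cfg.dpf)
        labels_out += [f"{ch}_HbO2", f"{ch}_HbR"]
        cols += [conc[:, 0], conc[:, 1]]
    return TimestampedStream(
        name="hemoglobin", modality="fnirs_hemo", channel_labels=labels_out,
        units=["µM"] * len(labels_out), nominal_rate=stream_lo.nominal_rate,
        samples=np.column_stack(cols), timestamps=stream_lo.timestamps.copy(),
        clock_id=stream_lo.clock_id,
    )


def bandpass_hemo(stream: TimestampedStream, cfg: HemoConfig | None = None) -> TimestampedStream:
    """Zero-phase band-pass of hemoglobin streams (0.02–0.2 Hz default)."""
    cfg = cfg or HemoConfig()
    fs = stream.nominal_rate
    sos = sps.butter(2, cfg.bandpass, btype="bandpass", fs=fs, output="sos")
    out = stream.copy()
    out.samples = sps.sosfiltfilt(sos, stream.samples, axis=0)
    return out


def short_channel_correct(
    hemo: TimestampedStream, nearest_short: dict[str, str]
) -> TimestampedStream:
    """Regress each long channel on its nearest short channel; keep residuals.

    The short channel (~1 cm separation) sees mainly extracerebral systemic
    signal, so its OLS projection out of a long channel removes shared
    systemic fluctuations and leaves the cortical component.  Applied per
    chromophore.  Short channels are passed through unchanged.
    """
    out = hemo.copy()
    for long_ch, short_ch in nearest_short.items():
        for chromo in ("HbO2", "HbR"):
            li = hemo.channel_labels.index(f"{long_ch}_{chromo}")
            s = hemo.channel(f"{short_ch}_{chromo}")
            y = hemo.samples[:, li]
            A = np.column_stack([s, np.ones_like(s)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            out.samples[:, li] = y - A @ coef
    return out


def hemo_response_metrics(
    evoked: Evoked, channel: str, cfg: HemoConfig | None = None
) -> dict[str, PeakMeasure]:
    """Shape metrics of an onset-locked ΔHbO2 average.

    Initial dip = minimum in (0, 3) s; peak = maximum in (3, 12) s; return
    time = first time after the peak with |value| < 10% of the peak.  A flat
    trace is flagged degenerate.
    """
    cfg = cfg or HemoConfig()
    t = evoked.times
    y = evoked.data[:, evoked.channel_labels.index(channel)]
    out: dict[str, PeakMeasure] = {}
    if np.allclose(y, y[0]):
        for label, window in (("HbO2_dip", cfg.dip_window), ("HbO2_peak", cfg.peak_window)):
            out[label] = PeakMeasure(label, window[0], 0.0, channel, window, ["degenerate"])
        return out
    dm = (t >= cfg.dip_window[0]) & (t <= cfg.dip_window[1])
    pm = (t >= cfg.peak_window[0]) & (t <= cfg.peak_window[1])
    i_dip = np.argmin(y[dm])
    i_peak = np.argmax(y[pm])
    out["HbO2_dip"] = PeakMeasure("HbO2_dip", float(t[dm][i_dip]), float(y[dm][i_dip]),
                                  channel, cfg.dip_window)
    peak_lat = float(t[pm][i_peak])
    peak_amp = float(y[pm][i_peak])
    out["HbO2_peak"] = PeakMeasure("HbO2_peak", peak_lat, peak_amp, channel, cfg.peak_window)
    after = t > peak_lat
    below = after & (np.abs(y) < 0.1 * abs(peak_amp))
    ret = float(t[below][0]) if below.any() else float("nan")
    out["HbO2_return"] = PeakMeasure(
        "HbO2_return", ret, 0.0, channel, (peak_lat, float(t[-1])),
        [] if np.isfinite(ret) else ["no_return"],
    )
    return out


def hemo_pipeline(
    bundle: StreamBundle,
    onsets: list[MarkerEvent],
    cfg: HemoConfig | None = None,
) -> tuple[Evoked, dict[str, PeakMeasure], TimestampedStream]:
    """Full fNIRS chain on a session bundle.

    mBLL conversion, band-pass, short-channel correction, onset-locked
    epoching with the configured baseline, and shape metrics on the average
    of the long channels' ΔHbO2.
    """
    cfg = cfg or HemoConfig()
    montage = bundle.metadata.get("fnirs_montage", {})
    distances = montage.get(
        "distances",
        {ch: (cfg.short_distance if ch.startswith("short") else cfg.long_distance)
         for ch in bundle.stream("fnirs_760").channel_labels},
    )
    nearest_short = montage.get("nearest_short", {})
    hemo = intensities_to_hemoglobin(
        bundle.stream("fnirs_760"), bundle.stream("fnirs_850"), distances, cfg
    )
    hemo = bandpass_hemo(hemo, cfg)
    if nearest_short:
        hemo = short_channel_correct(hemo, nearest_short)
    epochs = epoch(hemo, onsets, cfg.epoch_window, cfg.baseline)
    evoked = detrend_baseline_average(epochs, detrend=False)
    # average the long channels' HbO2 into a region trace for the metrics
    long_hbo = [
        i for i, lab in enumerate(evoked.channel_labels)
        if lab.endswith("_HbO2") and not lab.startswith("short")
    ]
    region = Evoked(
        times=evoked.times,
        data=evoked.data[:, long_hbo].mean(axis=1, keepdims=True),
        ci=evoked.ci[:, long_hbo].mean(axis=1, keepdims=True),
        channel_labels=["long_HbO2"], n_trials=evoked.n_trials,
    )
    metrics = hemo_response_metrics(region, "long_HbO2", cfg)
    return region, metrics, hemo
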