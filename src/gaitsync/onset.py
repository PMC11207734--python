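"""Kinetic movement-onset detection from center-of-pressure traces.

The onset of a voluntary step is read off the force-plate COP: both
directions (anteroposterior and mediolateral) are low-pass filtered with a
zero-phase second-order Butterworth at 5 Hz, differentiated per sample, and
combined as the root of the sum of squares.  The first crossing of a 0.3
(arbitrary unit) threshold marks the excursion; the movement onset is the
local minimum of the combined series nearest to that crossing whose height
does not exceed 0.05 — the last quiet point between normal stance sway and
the step.

Unit convention: the 0.3/0.05 thresholds are interpreted as mm-per-sample
COP displacement at the kinetics rate (first difference of mm-scaled COP at
1000 Hz).  The thresholds and the input units must be configured together:
rescaling the COP rescales the combined statistic one-for-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .streams import MarkerEvent, StreamBundle, TimestampedStream


@dataclass
class CopOnsetConfig:
    """Parameters of the COP onset detector.

    ``crossing_threshold`` and ``local_min_max_height`` are in the
    mm-per-sample units of the combined derivative (see module docstring).
    ``search_radius`` bounds, in seconds, how far from the threshold
    crossing a qualifying local minimum may lie.
    """

    lowpass_cutoff: float = 5.0
    filter_order: int = 2
    crossing_threshold: float = 0.3
    local_min_max_height: float = 0.05
    search_radius: float = 2.0
    baseline_qc_limit: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.local_min_max_height < self.crossing_threshold:
            raise ValueError("need 0 < local_min_max_height < crossing_threshold")


@dataclass
class OnsetDetection:
    """Outcome of onset detection on one combined series."""

    found: bool
    index: int | None = None
    time: float | None = None
    crossing_index: int | None = None
    reason: str | None = None  # "no_crossing" | "no_local_min" when absent


def lowpass_zero_phase(x: np.ndarray, fs: float, cfg: CopOnsetConfig | None = None) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase by construction).

    Reflective padding of 3x the filter order suppresses edge transients.
    """
    cfg = cfg or CopOnsetConfig()
    if cfg.lowpass_cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = np.asarray(x, float)
    sos = sps.butter(cfg.filter_order, cfg.lowpass_cutoff, fs=fs, output="sos")
    padlen = 3 * max(len(sos) * 2, cfg.filter_order)
    if len(x) <= padlen:
        raise ValueError(f"series too short for zero-phase filtering (need > {padlen} samples)")
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def combined_derivative(ap: np.ndarray, ml: np.ndarray) -> np.ndarray:
    """Per-sample first differences of both directions, combined as
    sqrt(dAP^2 + dML^2).  Length is n - 1; non-negative everywhere."""
    ap = np.asarray(ap, float)
    ml = np.asarray(ml, float)
    if ap.shape != ml.shape:
        raise ValueError("AP and ML series must have equal length")
    return np.hypot(np.diff(ap), np.diff(ml))


def _local_minima(c: np.ndarray) -> np.ndarray:
    """Interior local minima (c[j] <= both neighbors); for a plateau of
    equal values, the first sample of the plateau is the candidate."""
    j = np.arange(1, len(c) - 1)
    is_min = (c[j] <= c[j - 1]) & (c[j] <= c[j + 1])
    # collapse plateaus: drop a candidate whose left neighbor has equal value
    # and is itself a candidate (keep the first of the run)
    keep = is_min.copy()
    for k in range(1, len(j)):
        if keep[k] and is_min[k - 1] and c[j[k]] == c[j[k] - 1]:
            keep[k] = False
    return j[keep]


def detect_onset(
    c: np.ndarray,
    cfg: CopOnsetConfig | None = None,
    times: np.ndarray | None = None,
    fs: float = 1000.0,
) -> OnsetDetection:
    """Movement onset from a combined-derivative series.

    Finds the first index crossing ``crossing_threshold``; among local
    minima within ``search_radius`` whose height does not exceed
    ``local_min_max_height``, returns the one nearest in time to the
    crossing (an equidistant tie goes to the earlier one: the onset
    physically precedes the excursion).
    """
    cfg = cfg or CopOnsetConfig()
    c = np.asarray(c, float)
    if times is None:
        times = np.arange(len(c)) / fs
    above = np.flatnonzero(c > cfg.crossing_threshold)
    if len(above) == 0:
        return OnsetDetection(found=False, reason="no_crossing")
    ci = int(above[0])
    minima = _local_minima(c)
    minima = minima[c[minima] <= cfg.local_min_max_height]
    minima = minima[np.abs(times[minima] - times[ci]) <= cfg.search_radius]
    if len(minima) == 0:
        return OnsetDetection(found=False, crossing_index=ci, reason="no_local_min")
    dist = np.abs(times[minima] - times[ci])
    best = np.flatnonzero(dist == dist.min())
    onset = int(minima[best[0]])  # candidates sorted ascending: tie -> earlier
    return OnsetDetection(found=True, index=onset, time=float(times[onset]), crossing_index=ci)


@dataclass
class TrialQC:
    """Advisory per-trial quality flags; exclusion requires an explicit list."""

    flagged: bool
    reasons: list[str]


def qc_trials(
    trial_combined: list[np.ndarray],
    trial_onsets: list[OnsetDetection],
    baseline_slices: list[slice],
    cfg: CopOnsetConfig | None = None,
    manual_exclude: set[int] | None = None,
    manual_include: set[int] | None = None,
) -> list[TrialQC]:
    """Flag trials whose pre-onset baseline is disturbed or whose onset is
    missing.  Flags are advisory; a manual exclusion/inclusion list
    overrides them in both directions (mirroring the visual-inspection step
    such detection is normally paired with)."""
    cfg = cfg or CopOnsetConfig()
    manual_exclude = manual_exclude or set()
    manual_include = manual_include or set()
    out = []
    for k, (c, det, bsl) in enumerate(zip(trial_combined, trial_onsets, baseline_slices)):
        reasons = []
        if not det.found:
            reasons.append(det.reason or "no_onset")
        elif len(c[bsl]) and np.any(c[bsl] > cfg.baseline_qc_limit):
            reasons.append("baseline_disturbed")
        flagged = bool(reasons)
        if k in manual_exclude:
            flagged, reasons = True, reasons + ["manual_exclude"]
        elif k in manual_include:
            flagged = False
        out.append(TrialQC(flagged=flagged, reasons=reasons))
    return out


def detect_onsets_bundle(
    bundle: StreamBundle,
    cfg: CopOnsetConfig | None = None,
    windows: list[tuple[float, float]] | None = None,
    stream_name: str = "cop",
) -> tuple[list[MarkerEvent], list[OnsetDetection], list[TrialQC]]:
    """Detect one movement onset per trial window of a session bundle.

    ``windows`` defaults to the per-cycle windows recorded in the bundle
    metadata (simulator sessions) and are given on the COP stream's clock.
    Returns derived-onset marker events (absent detections skipped), the raw
    per-trial detections, and advisory QC flags.
    """
    cfg = cfg or CopOnsetConfig()
    cop = bundle.stream(stream_name)
    if windows is None:
        windows = [tuple(w) for w in bundle.metadata.get("cycles", [])]
        if not windows:
            windows = [(float(cop.timestamps[0]), float(cop.timestamps[-1]))]
    fs = cop.nominal_rate
    ap = lowpass_zero_phase(cop.channel("AP"), fs, cfg)
    ml = lowpass_zero_phase(cop.channel("ML"), fs, cfg)
    c_all = combined_derivative(ap, ml)
    t_all = cop.timestamps[1:]  # c[i] sits at the step's completion sample

    events: list[MarkerEvent] = []
    detections: list[OnsetDetection] = []
    trial_c: list[np.ndarray] = []
    baseline_slices: list[slice] = []
    for (w0, w1) in windows:
        i0, i1 = np.searchsorted(t_all, [w0, w1])
        c = c_all[i0:i1]
        t = t_all[i0:i1]
        det = detect_onset(c, cfg, times=t)
        detections.append(det)
        trial_c.append(c)
        if det.found:
            end = np.searchsorted(t, det.time - 0.5)
            baseline_slices.append(slice(np.searchsorted(t, w0 + 1.0), end))
            events.append(
                MarkerEvent(code=0, time=det.time, clock_id=cop.clock_id, source="derived_onset")
            )
        else:
            baseline_slices.append(slice(0, 0))
    qc = qc_trials(trial_c, detections, baseline_slices, cfg)
    return events, detections, qc
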