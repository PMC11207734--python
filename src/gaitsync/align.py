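"""Clock alignment and trigger-delay diagnostics.

Independently clocked acquisition devices are mapped onto a common timeline
with a first-order (affine) clock model fitted by least squares from shared
marker events: t_to = offset + rate * t_from.  Hardware crystal drift is
near-linear over session length, so the affine model is sufficient; the fit
residuals quantify marker-timestamp jitter.

The delay diagnostic compares a reference event sequence (issued commands,
or the true stimulus display times when available) against the photodiode-
decoded events: a display chain that is healthy produces a delay that is
constant up to frame quantization, while the faulty event-chained
("two-script") configuration produces a variable delay whose range exceeds
a frame period.  The default jitter threshold is half a frame period
(8.33 ms at 60 Hz): constant-to-within-frame-quantization is "synchronous"
in this system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .streams import MarkerEvent, TimestampedStream

logger = logging.getLogger("gaitsync")


@dataclass
class ClockMapping:
    """Affine map t_to = offset_a + rate_b * t_from with fit diagnostics."""

    from_clock: str
    to_clock: str
    offset_a: float
    rate_b: float
    residual_rms: float = 0.0
    residual_min: float = 0.0
    residual_max: float = 0.0
    n_pairs: int = 0

    def apply_times(self, t: np.ndarray) -> np.ndarray:
        return self.offset_a + self.rate_b * np.asarray(t, float)

    def inverse(self) -> "ClockMapping":
        return ClockMapping(
            from_clock=self.to_clock, to_clock=self.from_clock,
            offset_a=-self.offset_a / self.rate_b, rate_b=1.0 / self.rate_b,
            residual_rms=self.residual_rms, residual_min=self.residual_min,
            residual_max=self.residual_max, n_pairs=self.n_pairs,
        )

    @classmethod
    def identity(cls, clock: str) -> "ClockMapping":
        return cls(from_clock=clock, to_clock=clock, offset_a=0.0, rate_b=1.0)


@dataclass
class DelayReport:
    """Per-event delays of decoded blinks against a reference sequence."""

    delays: np.ndarray
    min: float
    max: float
    range: float
    mean: float
    sd: float
    is_jittered: bool
    jitter_threshold: float


def match_marker_sequences(
    events_a: list[MarkerEvent], events_b: list[MarkerEvent]
) -> list[tuple[int, int]]:
    """Pair events of both lists with identical codes in identical order.

    Uses longest-common-subsequence on the code sequences when counts
    differ; among equally long matchings the one whose time differences are
    closest to the coarse offset (median time difference) is preferred.
    Raises if fewer than 2 pairs result (a clock mapping would be unfittable).
    """
    if not events_a or not events_b:
        raise ValueError("cannot match empty event sequences")
    a_codes = [e.code for e in events_a]
    b_codes = [e.code for e in events_b]
    a_times = np.array([e.time for e in events_a])
    b_times = np.array([e.time for e in events_b])
    coarse = float(np.median(b_times) - np.median(a_times))

    n, m = len(a_codes), len(b_codes)
    # DP over (LCS length, -time penalty); penalty breaks ties toward pairs
    # whose offset agrees with the coarse estimate.
    length = np.zeros((n + 1, m + 1))
    penalty = np.zeros((n + 1, m + 1))
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a_codes[i] == b_codes[j]:
                length[i, j] = 1 + length[i + 1, j + 1]
                penalty[i, j] = abs(b_times[j] - a_times[i] - coarse) + penalty[i + 1, j + 1]
            if length[i + 1, j] > length[i, j] or (
                length[i + 1, j] == length[i, j] and penalty[i + 1, j] < penalty[i, j]
            ):
                length[i, j] = length[i + 1, j]
                penalty[i, j] = penalty[i + 1, j]
            if length[i, j + 1] > length[i, j] or (
                length[i, j + 1] == length[i, j] and penalty[i, j + 1] < penalty[i, j]
            ):
                length[i, j] = length[i, j + 1]
                penalty[i, j] = penalty[i, j + 1]

    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if (
            a_codes[i] == b_codes[j]
            and length[i, j] == 1 + length[i + 1, j + 1]
            and np.isclose(penalty[i, j],
                           abs(b_times[j] - a_times[i] - coarse) + penalty[i + 1, j + 1])
        ):
            pairs.append((i, j))
            i += 1
            j += 1
        elif length[i + 1, j] >= length[i, j + 1]:
            i += 1
        else:
            j += 1
    if len(pairs) < 2:
        raise ValueError(f"only {len(pairs)} matching event pair(s); need >= 2")
    return pairs


def fit_clock_mapping(
    t_from: np.ndarray,
    t_to: np.ndarray,
    from_clock: str = "from",
    to_clock: str = "to",
) -> ClockMapping:
    """Least-squares affine fit t_to = offset + rate * t_from.

    Residual statistics are stored on the mapping.  Raises on fewer than
    2 pairs or a degenerate design (all t_from equal).
    """
    t_from = np.asarray(t_from, float)
    t_to = np.asarray(t_to, float)
    if len(t_from) != len(t_to):
        raise ValueError("time arrays must have equal length")
    if len(t_from) < 2:
        raise ValueError("need at least 2 event pairs to fit a clock mapping")
    if np.ptp(t_from) == 0:
        raise ValueError("degenerate fit: all source times identical")
    # center for numerical conditioning
    mu = t_from.mean()
    rate, off_c = np.polyfit(t_from - mu, t_to, 1)
    offset = off_c - rate * mu
    resid = t_to - (offset + rate * t_from)
    return ClockMapping(
        from_clock=from_clock, to_clock=to_clock,
        offset_a=float(offset), rate_b=float(rate),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        residual_min=float(resid.min()), residual_max=float(resid.max()),
        n_pairs=len(t_from),
    )


def fit_clock_mapping_from_events(
    events_a: list[MarkerEvent], events_b: list[MarkerEvent]
) -> ClockMapping:
    """Match two marker sequences by code and fit the affine clock model."""
    pairs = match_marker_sequences(events_a, events_b)
    ta = np.array([events_a[i].time for i, _ in pairs])
    tb = np.array([events_b[j].time for _, j in pairs])
    return fit_clock_mapping(
        ta, tb,
        from_clock=events_a[0].clock_id, to_clock=events_b[0].clock_id,
    )


def apply_mapping(obj, mapping: ClockMapping):
    """Return a retimed copy of a stream or event list on the target clock."""
    if isinstance(obj, TimestampedStream):
        out = obj.copy()
        out.timestamps = mapping.apply_times(obj.timestamps)
        out.clock_id = mapping.to_clock
        return out
    if isinstance(obj, MarkerEvent):
        return replace(obj, time=float(mapping.apply_times(obj.time)), clock_id=mapping.to_clock)
    return [apply_mapping(e, mapping) for e in obj]


def delay_report(
    reference_events: list[MarkerEvent],
    decoded_events: list[MarkerEvent],
    jitter_threshold: float | None = None,
    frame_rate: float = 60.0,
) -> DelayReport:
    """Per-event delay (decoded − reference) and jitter diagnosis.

    Both sequences must live on a common clock (apply clock mappings first).
    ``is_jittered`` is true when the delay range exceeds the threshold
    (default: half a frame period).
    """
    if jitter_threshold is None:
        jitter_threshold = 0.5 / frame_rate
    pairs = match_marker_sequences(reference_events, decoded_events)
    d = np.array([decoded_events[j].time - reference_events[i].time for i, j in pairs])
    rng = float(d.max() - d.min())
    return DelayReport(
        delays=d, min=float(d.min()), max=float(d.max()), range=rng,
        mean=float(d.mean()), sd=float(d.std()),
        is_jittered=bool(rng > jitter_threshold),
        jitter_threshold=float(jitter_threshold),
    )


def compensate_display_delay(
    analysis_events: list[MarkerEvent], acquisition_delay: float = 0.0
) -> list[MarkerEvent]:
    """Select the events downstream epoching must lock to.

    The locking events are the photodiode-decoded times — the blink traverses
    the projection chain, so its decoded time carries the full display delay
    and is projection-true; command times must never be used for locking.
    ``acquisition_delay`` optionally adds a known constant recording-chain
    delay of the target modality (the hardware trigger input of an amplifier
    shares its acquisition path, so event-locked latencies stay unbiased
    when the same constant is applied to software-decoded events).
    """
    decoded = [e for e in analysis_events if e.source == "photodiode_decoded"]
    if not decoded:
        decoded = list(analysis_events)
        logger.warning("no photodiode-decoded events supplied; locking to given events as-is")
    logger.info(
        "locking to %d photodiode-decoded events (acquisition delay %.4f s applied)",
        len(decoded), acquisition_delay,
    )
    return [e.shifted(acquisition_delay) for e in decoded]
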