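"""Photodiode byte codec: encode event bytes as blink frame patterns and
decode analog/digital photodiode traces back into timestamped byte events.

Each event is transmitted as one byte over the display: a white dot at the
screen edge blinks a serial pattern, one bit per ``bit_frames`` display
frames — 1 start bit (high), 8 data bits LSB-first, 1 stop bit (low).  The
photodiode output is digitized by a Schmitt trigger (a comparator with
hysteresis: rising threshold above falling threshold, so levels inside the
band never toggle the state), then the decoder detects start bits on rising
edges, samples each bit at its temporal midpoint, and validates the stop
bit.  The decoded event timestamp is the rising edge of the start bit: that
is what a hardware trigger latches, and since the blink traverses the same
projection chain as the stimulus it carries the full display delay, which is
exactly what delay compensation needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .streams import MarkerEvent, TimestampedStream

logger = logging.getLogger("gaitsync")


@dataclass
class CodecConfig:
    """Framing and digitization parameters of the blink codec.

    ``bit_frames = 2`` (the default, 33.3 ms per bit at 60 Hz) tolerates a
    single dropped display frame per bit.  A byte then lasts
    ``10 * bit_frames / frame_rate`` = 333 ms.
    """

    frame_rate: float = 60.0
    bit_frames: int = 2
    high_level: float = 1.0
    low_level: float = 0.0
    schmitt_high: float = 0.6
    schmitt_low: float = 0.4

    def __post_init__(self) -> None:
        if self.bit_frames < 1:
            raise ValueError("bit_frames must be >= 1")
        if not self.schmitt_low < self.schmitt_high:
            raise ValueError("schmitt_low must be below schmitt_high")

    @property
    def bit_duration(self) -> float:
        return self.bit_frames / self.frame_rate

    @property
    def byte_duration(self) -> float:
        """Duration of one framed byte (start + 8 data + stop bits)."""
        return 10 * self.bit_duration


def byte_bits(code: int) -> list[int]:
    """Framed bit sequence of *code*: start(1) + 8 data bits LSB-first + stop(0)."""
    if not 0 <= code <= 255:
        raise ValueError(f"code {code} out of byte range 0..255")
    return [1] + [(code >> i) & 1 for i in range(8)] + [0]


def encode_byte(code: int, t_start: float, cfg: CodecConfig | None = None) -> list[tuple[float, int]]:
    """Encode *code* as per-frame blink states starting at *t_start*.

    Returns ``10 * bit_frames`` pairs ``(frame_time, state)``; frame k is
    high iff its bit of the framed sequence is 1.
    """
    cfg = cfg or CodecConfig()
    bits = byte_bits(code)
    frames: list[tuple[float, int]] = []
    frame_dt = 1.0 / cfg.frame_rate
    for b, bit in enumerate(bits):
        for f in range(cfg.bit_frames):
            frames.append((t_start + (b * cfg.bit_frames + f) * frame_dt, bit))
    return frames


def digitize_schmitt(analog: TimestampedStream, cfg: CodecConfig | None = None) -> TimestampedStream:
    """Digitize a single-channel analog photodiode trace with hysteresis.

    Output is 1 from the first sample exceeding ``schmitt_high`` until the
    signal falls below ``schmitt_low``; samples inside the hysteresis band
    never change the state.  Timestamps are carried over unchanged.
    """
    cfg = cfg or CodecConfig()
    if analog.n_channels != 1:
        raise ValueError("digitize_schmitt expects a single-channel stream")
    x = analog.samples[:, 0]
    if len(x) and (x.max() < cfg.schmitt_high or x.min() > cfg.schmitt_low):
        logger.warning(
            "Schmitt thresholds (%.3g/%.3g) outside observed signal range "
            "[%.3g, %.3g]; output will not toggle",
            cfg.schmitt_low, cfg.schmitt_high, x.min(), x.max(),
        )
    digital = schmitt_states(x, cfg.schmitt_high, cfg.schmitt_low)
    out = analog.copy()
    out.name = analog.name + "_digital"
    out.modality = "photodiode_digital"
    out.units = ["binary"]
    out.samples = digital[:, None].astype(float)
    return out


def schmitt_states(x: np.ndarray, high: float, low: float) -> np.ndarray:
    """Vectorized hysteresis comparator on *x* (initial state low).

    Samples > *high* force state 1, samples < *low* force state 0, samples
    in between hold the previous state.
    """
    force = np.zeros(len(x), dtype=np.int8)
    force[x > high] = 1
    force[x < low] = -1
    idx = np.nonzero(force)[0]
    out = np.zeros(len(x), dtype=np.int8)
    if len(idx) == 0:
        return out
    # state between forcing samples equals the most recent forcing decision
    decided = np.maximum(force[idx], 0)
    pos = np.zeros(len(x), dtype=np.int64)
    pos[idx] = np.arange(1, len(idx) + 1)
    pos = np.maximum.accumulate(pos)
    have = pos > 0
    out[have] = decided[pos[have] - 1]
    return out


def decode_events(digital: TimestampedStream, cfg: CodecConfig | None = None) -> list[MarkerEvent]:
    """Decode a binary photodiode stream into byte events.

    For each rising edge that stays high for at least half a bit (a start
    bit), every bit is sampled at its temporal midpoint and the stop bit is
    validated.  Stop-bit violations drop the event with a log entry; a byte
    truncated by the end of the recording is logged as well.  Event time is
    the rising-edge timestamp of the start bit.
    """
    cfg = cfg or CodecConfig()
    x = digital.samples[:, 0] > 0.5
    ts = digital.timestamps
    events: list[MarkerEvent] = []
    n = len(x)
    rising = np.flatnonzero(~x[:-1] & x[1:]) + 1
    if len(x) and x[0]:
        rising = np.concatenate([[0], rising])
    bit = cfg.bit_duration
    consumed_until = -np.inf
    for i in rising:
        t0 = ts[i]
        if t0 < consumed_until:
            continue  # edge inside a byte already decoded
        if t0 + 10 * bit > ts[-1] + 0.5 / digital.nominal_rate:
            logger.warning("truncated byte at t=%.4f s: recording ends mid-frame", t0)
            continue
        # start-bit check: high for at least half the bit duration
        half = np.searchsorted(ts, t0 + 0.5 * bit)
        if half >= n or not x[i:half + 1].all():
            continue
        bits = []
        for b in range(10):
            mid = np.searchsorted(ts, t0 + (b + 0.5) * bit)
            bits.append(bool(x[min(mid, n - 1)]))
        if not bits[0]:
            continue
        if bits[9]:
            logger.warning("stop-bit violation at t=%.4f s; event dropped", t0)
            consumed_until = t0 + 10 * bit
            continue
        code = sum((1 << k) for k in range(8) if bits[1 + k])
        events.append(
            MarkerEvent(code=code, time=float(t0), clock_id=digital.clock_id,
                        source="photodiode_decoded")
        )
        consumed_until = t0 + 10 * bit
    return events
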