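"""Virtual data-acquisition device.

Models the per-channel configuration of a DAQ control panel — measurement
mode, range, gain, offset, enable flag — and the scaling applied to analog
input (AI) and analog output (AO) samples each cycle.  Digital I/O lines are
modeled as 0/5 V analog levels so that every port in the system carries plain
scalar samples.

Also provides the *external sampler* harness: an independent observer that
samples the analog lines on a fast (default 250 kHz) grid and measures
input-to-output latency by matching half-amplitude rising edges, the same
way a second DAQ box on the bench would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ChannelConfig",
    "scale_ai",
    "emit_ao",
    "quantize_dio",
    "FunctionTrace",
    "SampledTrace",
    "detect_rising_edges",
    "measure_latency",
    "LatencyReport",
]

_DIRECTIONS = ("AI", "AO", "DIO")
_MODES = ("ground_referenced", "differential")


@dataclass
class ChannelConfig:
    """Configuration of one DAQ channel.

    AI samples are transformed as ``clip(gain * raw + offset, lo, hi)``;
    AO samples are clipped to the range before emission.
    """

    index: int
    direction: str  # AI | AO | DIO
    mode: str = "ground_referenced"
    range: tuple[float, float] = (-10.0, 10.0)
    gain: float = 1.0
    offset: float = 0.0
    enabled: bool = True

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValidationError(f"unknown channel direction {self.direction!r}")
        if self.mode not in _MODES:
            raise ValidationError(f"unknown channel mode {self.mode!r}")
        lo, hi = self.range
        if not lo < hi:
            raise ValidationError(f"channel range must satisfy lo < hi, got {self.range}")
        self.range = (float(lo), float(hi))

    @property
    def name(self) -> str:
        return f"{self.direction}{self.index}"


def scale_ai(raw, config: ChannelConfig):
    """Scale a raw AI sample (scalar or array): clip(gain*raw + offset, lo, hi).

    NaN passes through un-clipped so that a blown-up source is visible
    downstream instead of being silently saturated.
    """
    if config.direction == "AO":
        raise ValidationError(f"{config.name} is not an input channel")
    if not config.enabled:
        raise ValidationError(f"read from disabled channel {config.name}")
    lo, hi = config.range
    return np.clip(config.gain * np.asarray(raw, dtype=float) + config.offset, lo, hi)[()]


def emit_ao(value, config: ChannelConfig):
    """Clip an AO sample (scalar or array) to the channel range.

    NaN is returned as NaN (flagged by the engine, never clamped).
    """
    if config.direction == "AI":
        raise ValidationError(f"{config.name} is not an output channel")
    if not config.enabled:
        raise ValidationError(f"write to disabled channel {config.name}")
    lo, hi = config.range
    return np.clip(np.asarray(value, dtype=float), lo, hi)[()]


def quantize_dio(value):
    """Digital line emission: >= 2.5 V reads as logic high (5 V), else 0 V."""
    return np.where(np.asarray(value, dtype=float) >= 2.5, 5.0, 0.0)[()]


# ---------------------------------------------------------------------------
# Traces and the external latency sampler
# ---------------------------------------------------------------------------


class FunctionTrace:
    """Continuous-time signal defined by a vectorized function of t (seconds)."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self._fn = fn

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(np.asarray(t, dtype=float)), dtype=float)


class SampledTrace:
    """Zero-order-hold reconstruction of a regularly sampled signal.

    ``values[k]`` is taken to hold on ``[t0 + k/rate, t0 + (k+1)/rate)``,
    matching a DAQ output line that is updated once per engine cycle.
    """

    def __init__(self, rate: float, values: Sequence[float], t0: float = 0.0):
        self.rate = float(rate)
        self.values = np.asarray(values, dtype=float)
        self.t0 = float(t0)

    def sample(self, t: np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(t, dtype=float) - self.t0) * self.rate).astype(np.int64)
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]


def detect_rising_edges(
    trace,
    duration: float,
    threshold: float,
    rate: float = 250_000.0,
    chunk: int = 2_500_000,
) -> np.ndarray:
    """Times (s) at which ``trace`` first reaches ``threshold`` from below.

    The trace is evaluated on the sampler grid ``k / rate`` in chunks so that
    arbitrarily long runs never materialize the full grid.  Rising edges are
    half-amplitude-style crossings: sample >= threshold with the previous
    sample < threshold.
    """
    n = int(round(duration * rate))
    edges: list[np.ndarray] = []
    prev_above = True  # suppress a spurious edge if the trace starts high
    for k0 in range(0, n, chunk):
        k1 = min(k0 + chunk, n)
        t = np.arange(k0, k1, dtype=np.int64) / rate
        above = trace.sample(t) >= threshold
        prior = np.concatenate(([prev_above], above[:-1]))
        hit = above & ~prior
        if hit.any():
            edges.append(t[hit])
        prev_above = bool(above[-1]) if len(above) else prev_above
    if not edges:
        return np.empty(0)
    return np.concatenate(edges)


@dataclass
class LatencyReport:
    """Result of an external-sampler latency measurement."""

    latencies_s: np.ndarray
    latencies_periods: np.ndarray  # ceil(latency / engine period)
    n_input_edges: int
    n_output_edges: int
    missed_events: int
    period: float

    @property
    def max_latency_s(self) -> float:
        return float(self.latencies_s.max()) if len(self.latencies_s) else 0.0

    @property
    def max_latency_periods(self) -> int:
        return int(self.latencies_periods.max()) if len(self.latencies_periods) else 0

    def hard_rt_ok(self) -> bool:
        """Hard-RT check on I/O latency: nothing missed, delay <= 2 periods."""
        return self.missed_events == 0 and (
            len(self.latencies_s) == 0 or self.max_latency_s <= 2.0 * self.period
        )


def measure_latency(
    input_trace,
    output_trace,
    duration: float,
    period: float,
    threshold_in: float,
    threshold_out: float,
    sampler_rate: float = 250_000.0,
    max_latency: float | None = None,
) -> LatencyReport:
    """Per-event input→output latency as an external DAQ would measure it.

    Both traces are sampled on the sampler grid; each input rising edge is
    matched to the first subsequent output rising edge, consuming output
    edges monotonically.  An input edge with no output edge before the next
    input edge (or before ``max_latency``, default 10 periods) counts as a
    missed event.  Latencies are reported in seconds and in whole engine
    periods (ceil).
    """
    if max_latency is None:
        max_latency = 10.0 * period
    in_edges = detect_rising_edges(input_trace, duration, threshold_in, sampler_rate)
    out_edges = detect_rising_edges(output_trace, duration, threshold_out, sampler_rate)

    lat = []
    missed = 0
    j = 0
    n_out = len(out_edges)
    for i, te in enumerate(in_edges):
        limit = te + max_latency
        if i + 1 < len(in_edges):
            limit = min(limit, in_edges[i + 1])
        # an output edge on the same sampler tick as the input edge is a
        # legitimate (sub-tick) match, hence >= not >
        while j < n_out and out_edges[j] < te:
            j += 1
        if j < n_out and out_edges[j] <= limit:
            lat.append(out_edges[j] - te)
            j += 1
        else:
            missed += 1
    lat_arr = np.asarray(lat, dtype=float)
    # tolerate one sampler tick of grid rounding when converting to periods
    tick = 1.0 / sampler_rate
    periods = np.ceil((lat_arr - tick) / period).astype(np.int64) if len(lat_arr) else np.empty(0, np.int64)
    return LatencyReport(
        latencies_s=lat_arr,
        latencies_periods=np.maximum(periods, 1) if len(lat_arr) else periods,
        n_input_edges=len(in_edges),
        n_output_edges=n_out,
        missed_events=missed,
        period=period,
    )
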