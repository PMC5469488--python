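"""Real-time benchmark statistics.

Collects, per cycle, the realized RT period p_k, its jitter j_k = p_k −
nominal, and the computation time c_k spent in the cycle body, and applies
the hard-RT acceptance rule: the realized period must never exceed twice the
nominal period, otherwise deadlines are being missed and hard real-time
behavior is compromised.

In simulated mode the engine feeds exact nominal periods, so p_k ≡ nominal
and j_k ≡ 0 by construction; the computation times are then informational
wall-clock measurements only and carry no determinism guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["BenchmarkStats", "summarize_series"]


def summarize_series(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return {"mean": 0.0, "sd": 0.0, "min": 0.0, "max": 0.0, "n": 0}
    return {
        "mean": float(x.mean()),
        "sd": float(x.std()),  # population SD; a singleton series has sd 0
        "min": float(x.min()),
        "max": float(x.max()),
        "n": int(len(x)),
    }


@dataclass
class HardRTResult:
    ok: bool
    first_violation: int | None  # cycle index of the first period > 2x nominal
    max_period: float


class BenchmarkStats:
    """Per-cycle period / jitter / computation-time collector."""

    def __init__(self, nominal_period: float):
        if nominal_period <= 0:
            raise ValidationError("nominal period must be positive")
        self.nominal = float(nominal_period)
        self._t_start: list[float] = []
        self._p: list[float] = []
        self._c: list[float] = []

    # -- recording ---------------------------------------------------------

    def record_cycle_timing(self, t_start: float, t_end: float) -> None:
        """Record one cycle from clock timestamps.

        c_k = t_end − t_start; the realized period is the difference of
        successive cycle-start timestamps (defined from the second cycle on).
        """
        if t_end < t_start:
            raise ValidationError("t_end precedes t_start")
        if self._t_start and t_start < self._t_start[-1]:
            raise ValidationError("non-monotone cycle start timestamps")
        if self._t_start:
            self._p.append(t_start - self._t_start[-1])
        self._t_start.append(t_start)
        self._c.append(t_end - t_start)

    def record_period(self, period: float, comp_time: float = 0.0) -> None:
        """Record one cycle with a known realized period (the engine's
        simulated-mode entry point: period == nominal exactly)."""
        if period < 0 or comp_time < 0:
            raise ValidationError("negative timing sample")
        self._p.append(float(period))
        self._c.append(float(comp_time))

    # -- series ------------------------------------------------------------

    @property
    def periods(self) -> np.ndarray:
        return np.asarray(self._p, dtype=float)

    @property
    def jitter(self) -> np.ndarray:
        """Signed deviation of each realized period from nominal."""
        return self.periods - self.nominal

    @property
    def comp_times(self) -> np.ndarray:
        return np.asarray(self._c, dtype=float)

    @property
    def n_cycles(self) -> int:
        return len(self._c)

    # -- analysis ----------------------------------------------------------

    def check_hard_rt(self) -> HardRTResult:
        """Pass iff max_k p_k <= 2 × nominal (boundary inclusive)."""
        p = self.periods
        if len(p) < 1 or self.n_cycles < 2:
            raise ValidationError("need at least 2 recorded cycles")
        bad = np.nonzero(p > 2.0 * self.nominal)[0]
        if len(bad):
            return HardRTResult(False, int(bad[0]), float(p.max()))
        return HardRTResult(True, None, float(p.max()))

    def summarize(self, hist_bins: int | np.ndarray | None = None) -> dict:
        """Mean/sd/min/max for period, jitter, and computation time.

        Jitter is reported as the signed deviation, plus its absolute
        maximum.  Pass ``hist_bins`` to also get a period histogram.
        """
        if self.n_cycles < 1:
            raise ValidationError("no cycles recorded")
        out = {
            "nominal_period": self.nominal,
            "period": summarize_series(self.periods),
            "jitter": summarize_series(self.jitter),
            "comp_time": summarize_series(self.comp_times),
        }
        j = self.jitter
        out["jitter"]["abs_max"] = float(np.abs(j).max()) if len(j) else 0.0
        if hist_bins is not None:
            counts, edges = np.histogram(self.periods, bins=hist_bins)
            out["period_histogram"] = {"counts": counts, "edges": edges}
        return out

    def as_signals(self) -> dict[str, np.ndarray]:
        """Benchmark series in recordable form (one value per cycle), so
        they can be streamed into the data recorder like any other signal."""
        n = self.n_cycles
        p = self.periods
        if len(p) < n:  # timestamp-derived periods start one cycle late
            p = np.concatenate([[self.nominal] * (n - len(p)), p])
        return {
            "rt_period": p,
            "rt_jitter": p - self.nominal,
            "comp_time": self.comp_times,
        }
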