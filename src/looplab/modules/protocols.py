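"""Standard experiment modules.

These four blocks cover the classic closed-loop electrophysiology bench:
a signal generator, a Hodgkin–Huxley point neuron, a threshold-crossing
spike detector with TTL output, and a dynamic-clamp virtual leak
conductance.  Chained as

    trigger → neuron → spike detector → AO

they form the loaded-processing characterization case; neuron + dynamic
clamp in a loop is the excitability-modulation protocol.

Units at the ports: generator and clamp outputs are volts (command-signal
convention), the neuron's membrane potential port carries mV, and the
neuron's stimulus port converts volts to current density via its
``stim_scale`` parameter (default 1 V ↦ 10 µA/cm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ..errors import ValidationError
from .base import Module, register_module

__all__ = [
    "signal_generator",
    "SignalGenerator",
    "HHParams",
    "HHState",
    "hh_step",
    "hh_rhs",
    "HHNeuron",
    "SpikeDetector",
    "spike_detect_step",
    "dynamic_clamp_current",
    "DynamicClamp",
]


# ---------------------------------------------------------------------------
# Signal generator
# ---------------------------------------------------------------------------

_SIG_KINDS = ("dc", "sine", "square", "pulse_train", "file_waveform")


def signal_generator(kind: str, params: dict, t):
    """Deterministic waveform value(s) at time t (vectorized).

    kinds: ``dc`` (constant ``amplitude``); ``sine`` (amplitude × sin(2πft+φ));
    ``square`` (peak-to-peak ``amplitude``, ``duty`` fraction high, levels
    ±amplitude/2); ``pulse_train`` (rectangular ``amplitude``-high pulses of
    ``width`` s every 1/frequency s); ``file_waveform`` (samples from a
    one-column ASCII file, played at ``rate``, zero after the end).
    """
    t = np.asarray(t, dtype=float)
    if kind == "dc":
        out = np.full_like(t, float(params.get("amplitude", 0.0)))
    elif kind == "sine":
        a = float(params.get("amplitude", 1.0))
        f = float(params.get("frequency", 1.0))
        phase = float(params.get("phase", 0.0))
        out = a * np.sin(2.0 * np.pi * f * t + phase)
    elif kind == "square":
        vpp = float(params.get("amplitude", 1.0))
        f = float(params.get("frequency", 1.0))
        duty = float(params.get("duty", 0.5))
        frac = np.mod(t * f, 1.0)
        out = np.where(frac < duty, vpp / 2.0, -vpp / 2.0)
    elif kind == "pulse_train":
        a = float(params.get("amplitude", 5.0))
        f = float(params.get("frequency", 1.0))
        width = float(params.get("width", 0.5 / f))
        frac = np.mod(t, 1.0 / f)
        out = np.where(frac < width, a, 0.0)
    elif kind == "file_waveform":
        samples = params["_samples"]
        rate = float(params.get("rate", 1000.0))
        idx = np.floor(t * rate).astype(np.int64)
        valid = (idx >= 0) & (idx < len(samples))
        out = np.where(valid, samples[np.clip(idx, 0, len(samples) - 1)], 0.0)
    else:
        raise ValidationError(f"unknown signal kind {kind!r}")
    return out[()]


@register_module
class SignalGenerator(Module):
    """Stimulus waveform source; one output port ``out`` (volts).

    ``file_waveform`` reads one float per line from the ASCII file named by
    the ``path`` parameter and plays it at ``rate`` Hz.
    """

    type_name = "signal_generator"
    OUTPUTS = ("out",)
    PARAMS = {
        "kind": "dc",
        "amplitude": 0.0,
        "frequency": 1.0,
        "duty": 0.5,
        "width": 0.0,
        "phase": 0.0,
        "rate": 1000.0,
        "path": "",
    }

    def update(self, state, event=None):
        from .base import LifecycleState

        if state in (LifecycleState.INIT, LifecycleState.MODIFY):
            kind = self.params["kind"]
            if kind not in _SIG_KINDS:
                raise ValidationError(f"unknown signal kind {kind!r}")
            if kind == "file_waveform":
                self._samples = np.loadtxt(self.params["path"], ndmin=1)
            else:
                self._samples = None

    def execute(self, t, dt, inputs):
        p = dict(self.params)
        if p["kind"] == "pulse_train" and not p["width"]:
            p["width"] = 0.5 / p["frequency"]
        if self._samples is not None:
            p["_samples"] = self._samples
        return {"out": float(signal_generator(p["kind"], p, t))}


# ---------------------------------------------------------------------------
# Hodgkin–Huxley point neuron
# ---------------------------------------------------------------------------


@dataclass
class HHParams:
    """Classic squid-axon constants (resting potential ≈ −65 mV).

    Units: Cm µF/cm²; conductances mS/cm²; reversal potentials mV.
    """

    cm: float = 1.0
    gna: float = 120.0
    gk: float = 36.0
    gl: float = 0.3
    ena: float = 50.0
    ek: float = -77.0
    el: float = -54.4

    def __post_init__(self):
        if self.cm <= 0:
            raise ValidationError("Cm must be positive")
        if min(self.gna, self.gk, self.gl) < 0:
            raise ValidationError("conductances must be non-negative")


@dataclass
class HHState:
    """Membrane potential (mV) and the three gating variables."""

    v: float = -65.0
    m: float = 0.0529
    h: float = 0.5961
    n: float = 0.3177


def _safe_exp_ratio(u: float) -> float:
    """u / (1 - exp(-u)), with the u→0 limit and float overflow handled."""
    if abs(u) < 1e-7:
        return 1.0 + u / 2.0
    if u < -700.0:  # denominator overflows; the ratio tends to 0
        return 0.0
    if u > 700.0:
        return u
    return -u / math.expm1(-u)


def hh_rhs(v, m, h, n, i_ext, p: HHParams):
    """Right-hand side of the membrane + gate ODEs (rates in /ms, V in mV,
    I in µA/cm²; time unit ms)."""
    # alpha_m = 0.1(v+40)/(1-e^{-(v+40)/10}) = ratio((v+40)/10), and similarly alpha_n
    am = _safe_exp_ratio((v + 40.0) / 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _safe_exp_ratio((v + 55.0) / 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    ina = p.gna * m ** 3 * h * (v - p.ena)
    ik = p.gk * n ** 4 * (v - p.ek)
    il = p.gl * (v - p.el)
    dv = (i_ext - ina - ik - il) / p.cm
    return (
        dv,
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    )


def hh_step(state: HHState, i_ext: float, dt: float, params: HHParams | None = None,
            max_substep: float = 25e-6) -> HHState:
    """Advance the neuron by one engine period with classical RK4.

    ``dt`` is in seconds; the integration runs in ms internally.  When the
    period exceeds ``max_substep`` (stiffness bound for the spike upstroke)
    the step is split into equal RK4 substeps, so a 50 µs engine period
    integrates at 25 µs without changing engine semantics.  Gates are
    clamped to [0, 1] after every substep.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    p = params or HHParams()
    v, m, h, n = state.v, state.m, state.h, state.n
    if not all(map(math.isfinite, (v, m, h, n))):
        raise ValidationError("non-finite neuron state")
    nsub = max(1, math.ceil(dt / max_substep))
    hms = dt * 1e3 / nsub  # substep in ms
    for _ in range(nsub):
        k1 = hh_rhs(v, m, h, n, i_ext, p)
        k2 = hh_rhs(v + 0.5 * hms * k1[0], m + 0.5 * hms * k1[1],
                    h + 0.5 * hms * k1[2], n + 0.5 * hms * k1[3], i_ext, p)
        k3 = hh_rhs(v + 0.5 * hms * k2[0], m + 0.5 * hms * k2[1],
                    h + 0.5 * hms * k2[2], n + 0.5 * hms * k2[3], i_ext, p)
        k4 = hh_rhs(v + hms * k3[0], m + hms * k3[1],
                    h + hms * k3[2], n + hms * k3[3], i_ext, p)
        v += hms / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m += hms / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        h += hms / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n += hms / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        m = min(1.0, max(0.0, m))
        h = min(1.0, max(0.0, h))
        n = min(1.0, max(0.0, n))
    return HHState(v=v, m=m, h=h, n=n)


@register_module
class HHNeuron(Module):
    """Hodgkin–Huxley point neuron.

    Input port ``stim`` (volts, scaled to µA/cm² by ``stim_scale``); output
    port ``Vm`` (mV).  All model constants are parameters.
    """

    type_name = "hh_neuron"
    INPUTS = ("stim",)
    OUTPUTS = ("Vm",)
    PARAMS = {
        "cm": 1.0, "gna": 120.0, "gk": 36.0, "gl": 0.3,
        "ena": 50.0, "ek": -77.0, "el": -54.4,
        "stim_scale": 10.0,  # (µA/cm²) per port volt
        "v0": -65.0, "m0": 0.0529, "h0": 0.5961, "n0": 0.3177,
    }
    STATES = ("v", "m", "h", "n")

    def update(self, state, event=None):
        from .base import LifecycleState

        if state == LifecycleState.INIT:
            self.v = self.params["v0"]
            self.m = self.params["m0"]
            self.h = self.params["h0"]
            self.n = self.params["n0"]
        self._hh = HHParams(
            cm=self.params["cm"], gna=self.params["gna"], gk=self.params["gk"],
            gl=self.params["gl"], ena=self.params["ena"], ek=self.params["ek"],
            el=self.params["el"],
        )

    def execute(self, t, dt, inputs):
        i_ext = self.params["stim_scale"] * inputs["stim"]
        s = hh_step(HHState(self.v, self.m, self.h, self.n), i_ext, dt, self._hh)
        self.v, self.m, self.h, self.n = s.v, s.m, s.h, s.n
        return {"Vm": self.v}


# ---------------------------------------------------------------------------
# Spike detector
# ---------------------------------------------------------------------------


def spike_detect_step(v, t, dt, cfg, st):
    """One detector step; ``cfg``/``st`` are plain dicts (see SpikeDetector).

    Fires on an upward threshold crossing while armed and out of refractory;
    emits the pulse level for the pulse width; re-arms only after the
    potential falls back below threshold and the refractory period elapses.
    """
    thr = cfg["threshold"]
    fired = False
    if (
        st["armed"]
        and st["prev_v"] < thr <= v
        and t >= st["refractory_until"]
    ):
        st["pulse_until"] = t + cfg["pulse_width"]
        st["refractory_until"] = t + cfg["refractory"]
        st["armed"] = False
        fired = True
    if not st["armed"] and v < thr and t >= st["refractory_until"]:
        st["armed"] = True
    st["prev_v"] = v
    out = cfg["pulse_level"] if t < st["pulse_until"] else 0.0
    return out, fired


@register_module
class SpikeDetector(Module):
    """Threshold-crossing action-potential detector with TTL output.

    Input ``Vm`` (mV); output ``ttl`` (volts, 5 V pulses).  The pulse width
    must span at least one engine period so the pulse is visible on the
    output trace.
    """

    type_name = "spike_detector"
    INPUTS = ("Vm",)
    OUTPUTS = ("ttl",)
    PARAMS = {
        "threshold": -20.0,   # mV
        "refractory": 0.002,  # s
        "pulse_width": 0.001,  # s
        "pulse_level": 5.0,   # V
    }
    STATES = ("spike_count",)

    def update(self, state, event=None):
        from .base import LifecycleState

        if state == LifecycleState.INIT:
            self.spike_count = 0.0
            self._st = {
                "armed": True,
                "prev_v": -1e9,
                "pulse_until": -1.0,
                "refractory_until": -1.0,
            }
        if self.params["refractory"] < 0:
            raise ValidationError("refractory must be non-negative")

    def execute(self, t, dt, inputs):
        if self.params["pulse_width"] < dt:
            raise ValidationError("pulse width must span at least one engine period")
        cfg = self.params
        out, fired = spike_detect_step(inputs["Vm"], t, dt, cfg, self._st)
        if fired:
            self.spike_count += 1.0
        return {"ttl": out}


# ---------------------------------------------------------------------------
# Dynamic clamp
# ---------------------------------------------------------------------------


def dynamic_clamp_current(v_mv: float, g_leak_ns: float, e_leak_mv: float) -> float:
    """Virtual leak-conductance current, I = −G_leak (V − E_leak), in pA.

    Injected current is positive-depolarizing, so a *negative* G_leak
    produces depolarizing current above E_leak — it cancels part of the
    cell's natural leak and increases excitability.
    """
    return -g_leak_ns * (v_mv - e_leak_mv)


@register_module
class DynamicClamp(Module):
    """Leak-conductance dynamic clamp.

    Input ``Vm`` (mV, the latest sampled membrane potential); output
    ``command`` (volts).  The command scale is ``volts_per_na`` (default
    1 V per nA of computed current); I is recomputed from the fresh V every
    cycle.  No sign restriction on ``g_leak`` — negative values are the
    excitability-raising case.
    """

    type_name = "dynamic_clamp"
    INPUTS = ("Vm",)
    OUTPUTS = ("command",)
    PARAMS = {
        "g_leak": 0.0,       # nS
        "e_leak": -65.0,     # mV; default = the model neuron's resting potential
        "volts_per_na": 1.0,
    }

    def execute(self, t, dt, inputs):
        i_pa = dynamic_clamp_current(inputs["Vm"], self.params["g_leak"],
                                     self.params["e_leak"])
        return {"command": i_pa / 1000.0 * self.params["volts_per_na"]}


# ---------------------------------------------------------------------------
# Closed-loop excitability measurement
# ---------------------------------------------------------------------------


def closed_loop_rheobase(
    g_leak_ns: float,
    e_leak_mv: float = -65.0,
    frequency: float = 20_000.0,
    duration: float = 0.3,
    i_lo: float = 0.0,
    i_hi: float = 12.0,
    tol: float = 0.05,
    volts_per_na: float = 0.3,
    stim_scale: float = 10.0,
) -> float:
    """Minimal sustained DC current density (µA/cm²) that elicits a spike
    from the model neuron with the dynamic clamp in the loop.

    Builds the workspace DC source + clamp → neuron → spike detector and
    bisects the current to ``tol``.  The composite clamp coupling
    (``volts_per_na`` × ``stim_scale`` / 1000) maps G_leak in nS to a
    conductance density of 0.003·|G_leak| mS/cm² at the defaults — a
    ~3×10⁻⁴ cm² membrane equivalent, strong enough that ±60 nS visibly
    shifts excitability while keeping the total leak positive.
    """
    from ..dataflow import Workspace
    from ..engine import Engine, EngineConfig

    def spikes(i_ua: float) -> bool:
        ws = Workspace(EngineConfig(frequency=frequency))
        ws.load_module(
            "signal_generator", "stim", {"kind": "dc", "amplitude": i_ua / stim_scale}
        )
        ws.load_module("hh_neuron", "neuron", {"stim_scale": stim_scale})
        ws.load_module(
            "dynamic_clamp",
            "clamp",
            {"g_leak": g_leak_ns, "e_leak": e_leak_mv, "volts_per_na": volts_per_na},
        )
        ws.load_module("spike_detector", "det", {})
        ws.connect("stim.out", "neuron.stim")
        ws.connect("clamp.command", "neuron.stim")
        ws.connect("neuron.Vm", "clamp.Vm")
        ws.connect("neuron.Vm", "det.Vm")
        Engine(ws).run(duration)
        return ws.modules["det"].spike_count > 0

    if spikes(i_lo):
        return i_lo
    if not spikes(i_hi):
        raise ValidationError(f"no spike up to {i_hi} µA/cm²; widen the bracket")
    lo, hi = i_lo, i_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi
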