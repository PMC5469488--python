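"""Shared fixtures: instrumented test modules, workspace builders, and
hypothesis strategies for randomized workspaces."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

import looplab as ll
from looplab.modules.base import Module, register_module
from looplab.fixtures import PulseTrainSpec, make_pulse_train

settings.register_profile(
    "looplab",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("looplab")


# ---------------------------------------------------------------------------
# Instrumented test modules
# ---------------------------------------------------------------------------


@register_module
class Gain(Module):
    """y = gain * x; simplest possible dataflow probe."""

    type_name = "test_gain"
    INPUTS = ("in",)
    OUTPUTS = ("out",)
    PARAMS = {"gain": 1.0}

    def execute(self, t, dt, inputs):
        return {"out": self.params["gain"] * inputs["in"]}


@register_module
class TraceProbe(Module):
    """Records every execute and update call with its cycle phase, for
    asserting intra-cycle ordering."""

    type_name = "test_probe"
    INPUTS = ("in",)
    OUTPUTS = ("out",)
    PARAMS = {"post_kind": "", "post_at_cycle": -1.0}

    def update(self, state, event=None):
        from looplab.modules.base import LifecycleState

        if state == LifecycleState.INIT:
            self.calls = []
            self.seen_inputs = []
        else:
            getattr(self, "calls", []).append(("update", state.value, event))

    def execute(self, t, dt, inputs):
        self.calls.append(("execute", t, None))
        self.seen_inputs.append(inputs["in"])
        if self.params["post_kind"] and len(self.seen_inputs) - 1 == int(
            self.params["post_at_cycle"]
        ):
            self.post_event(self.params["post_kind"], {"from": self.id})
        return {"out": float(len(self.seen_inputs))}


# ---------------------------------------------------------------------------
# Workspace builders
# ---------------------------------------------------------------------------


@pytest.fixture
def loopback_ws():
    """SISO loopback: AI0 → AO0, no modules, with a pulse-train source."""

    def build(frequency=2000.0, duration=2.0, n_events=2, seed=1):
        ws = ll.Workspace(ll.EngineConfig(frequency=frequency))
        ws.add_channel(ll.ChannelConfig(0, "AI"))
        ws.add_channel(ll.ChannelConfig(0, "AO"))
        ws.connect("AI0", "AO0")
        sig, events = make_pulse_train(
            PulseTrainSpec(
                duration=duration,
                n_events=n_events,
                pulse_width=0.3,
                min_gap=0.2,
                seed=seed,
            )
        )
        ws.set_ai_source(0, sig)
        return ws, sig, events

    return build


@pytest.fixture
def case3_ws():
    """Loaded-processing characterization loop:
    trigger (AI0) → HH neuron → spike detector → AO0, plus an AI1→AO1 leg."""

    def build(frequency=5000.0, duration=2.0, n_events=3, seed=11):
        ws = ll.Workspace(ll.EngineConfig(frequency=frequency))
        for i in (0, 1):
            ws.add_channel(ll.ChannelConfig(i, "AI"))
            ws.add_channel(ll.ChannelConfig(i, "AO"))
        ws.load_module("hh_neuron", "neuron", {})
        ws.load_module("spike_detector", "det", {})
        ws.connect("AI0", "neuron.stim")
        ws.connect("neuron.Vm", "det.Vm")
        ws.connect("det.ttl", "AO0")
        ws.connect("AI1", "AO1")
        sig, events = make_pulse_train(
            PulseTrainSpec(
                duration=duration,
                n_events=n_events,
                pulse_width=0.2,
                min_gap=0.15,
                seed=seed,
            )
        )
        ws.set_ai_source(0, lambda t: np.asarray(sig(t)) / 10.0)  # 5 V -> 5 µA/cm²
        ws.set_ai_source(1, sig)
        return ws, sig, events

    return build


# ---------------------------------------------------------------------------
# Randomized-workspace strategy (persistence round-trips)
# ---------------------------------------------------------------------------

_param_float = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
_pos_float = st.floats(min_value=1e-3, max_value=1e3)


def _module_entries():
    sig = st.fixed_dictionaries(
        {
            "kind": st.sampled_from(["dc", "sine", "square"]),
            "amplitude": _param_float,
            "frequency": _pos_float,
        }
    ).map(lambda p: ("signal_generator", p))
    neuron = st.fixed_dictionaries(
        {"gna": _pos_float, "stim_scale": _param_float, "el": _param_float}
    ).map(lambda p: ("hh_neuron", p))
    det = st.fixed_dictionaries(
        {"threshold": _param_float, "refractory": _pos_float}
    ).map(lambda p: ("spike_detector", p))
    clamp = st.fixed_dictionaries(
        {"g_leak": _param_float, "e_leak": _param_float}
    ).map(lambda p: ("dynamic_clamp", p))
    return st.lists(st.one_of(sig, neuron, det, clamp), min_size=0, max_size=5)


@st.composite
def workspaces(draw):
    ws = ll.Workspace(
        ll.EngineConfig(
            frequency=draw(st.sampled_from([1000.0, 2000.0, 20000.0, 30000.0])),
            mode=draw(st.sampled_from(["simulated", "wallclock"])),
            seed=draw(st.integers(min_value=0, max_value=2**31 - 1)),
        )
    )
    for i in range(draw(st.integers(min_value=0, max_value=3))):
        ws.add_channel(
            ll.ChannelConfig(
                index=i,
                direction=draw(st.sampled_from(["AI", "AO", "DIO"])),
                mode=draw(st.sampled_from(["ground_referenced", "differential"])),
                range=(-10.0, draw(st.floats(min_value=1.0, max_value=100.0))),
                gain=draw(_param_float),
                offset=draw(_param_float),
                enabled=draw(st.booleans()),
            )
        )
    for j, (type_name, params) in enumerate(draw(_module_entries())):
        ws.load_module(type_name, f"m{j}", params)
    # random valid connections among existing ports
    outputs = [c.name for c in ws.channels.values() if c.direction == "AI"]
    inputs = [c.name for c in ws.channels.values() if c.direction != "AI"]
    for m in ws.modules.values():
        outputs.extend(f"{m.id}.{p}" for p in m.OUTPUTS)
        inputs.extend(f"{m.id}.{p}" for p in m.INPUTS)
    if outputs and inputs:
        pairs = draw(
            st.lists(
                st.tuples(st.sampled_from(outputs), st.sampled_from(inputs)),
                max_size=6,
                unique=True,
            )
        )
        for src, dst in pairs:
            ws.connect(src, dst)
    return ws
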