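"""Cycle scheduler semantics: acquire/execute/drain/emit ordering, events,
pause, period changes, load/unload, and the chunked fast path."""

import numpy as np
import pytest

import looplab as ll
from looplab.engine import RTEvent
from looplab.errors import ModuleExecutionError, ValidationError, WorkspaceError
from looplab.modules.base import LifecycleState


def probe_ws(frequency=1000.0, n_probes=2, **probe_params):
    ws = ll.Workspace(ll.EngineConfig(frequency=frequency))
    for i in range(n_probes):
        ws.load_module("test_probe", f"p{i}", probe_params if i == 0 else {})
    return ws


class TestCycleSemantics:
    def test_siso_loopback_is_identity(self, loopback_ws):
        ws, sig, _ = loopback_ws(frequency=1000.0)
        engine = ll.Engine(ws)
        log = engine.run(1.0)
        t = np.arange(log.n_cycles) / 1000.0
        assert np.array_equal(engine.ao_trace("AO0"), sig(t))

    def test_event_observed_same_cycle_after_all_executes(self):
        """A module posting during execute is seen by every update hook in
        the same cycle, once all module computations are complete."""
        ws = probe_ws(post_kind="custom", post_at_cycle=1)
        engine = ll.Engine(ws)
        engine.run(3 / 1000.0)
        for pid in ("p0", "p1"):
            calls = ws.modules[pid].calls
            kinds = [
                (c[0], c[2].kind if c[0] == "update" and c[2] else None) for c in calls
            ]
            # cycle 0: execute, execute; cycle 1: executes then the custom event
            idx_exec = [i for i, c in enumerate(calls) if c[0] == "execute"]
            idx_event = [
                i for i, k in enumerate(kinds) if k == ("update", "custom")
            ]
            assert len(idx_event) == 1
            # the event lands after the second execute (cycle 1) and before
            # the third (cycle 2)
            assert idx_exec[1] < idx_event[0] < idx_exec[2]

    def test_paused_module_retains_last_output(self):
        ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
        ws.load_module("signal_generator", "gen", {"kind": "dc", "amplitude": 4.2})
        engine = ll.Engine(ws)
        engine.run(2 / 1000.0)
        assert ws.read("gen.out") == 4.2
        engine.set_pause("gen", True)
        ws.modules["gen"].params["amplitude"] = -1.0  # would change output if run
        engine.run(2 / 1000.0)
        assert ws.read("gen.out") == 4.2  # port kept its last-written value
        engine.set_pause("gen", False)
        engine.run(1 / 1000.0)
        assert ws.read("gen.out") == -1.0

    def test_nan_output_propagates_and_is_flagged(self):
        ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
        ws.add_channel(ll.ChannelConfig(0, "AO"))
        ws.load_module("signal_generator", "gen", {"kind": "dc", "amplitude": np.nan})
        ws.connect("gen.out", "AO0")
        engine = ll.Engine(ws)
        log = engine.run(2 / 1000.0)
        assert log.nan_cycles == 2
        assert np.isnan(engine.ao_trace("AO0")).all()

    def test_module_error_aborts_with_context(self):
        ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
        ws.load_module("signal_generator", "gen", {"kind": "dc"})
        # break the module after INIT so the failure happens mid-run
        ws.modules["gen"].params["kind"] = "bogus"
        engine = ll.Engine(ws)
        with pytest.raises(ModuleExecutionError) as exc_info:
            engine.run(1.0)
        assert exc_info.value.module_id == "gen"
        assert exc_info.value.cycle == 0
        assert exc_info.value.partial_log.n_cycles == 0


class TestEvents:
    def test_fifo_drain_order(self):
        ws = probe_ws(n_probes=2)
        engine = ll.Engine(ws)
        engine.post_event(RTEvent("custom", "p0", {"n": 1}))
        engine.post_event(RTEvent("custom", "p1", {"n": 2}))
        engine.run(1 / 1000.0)
        observed = [
            c[2].payload["n"]
            for c in ws.modules["p0"].calls
            if c[0] == "update" and c[2] is not None and c[2].kind == "custom"
        ]
        assert observed == [1, 2]

    def test_unknown_source_rejected(self):
        engine = ll.Engine(probe_ws())
        with pytest.raises(ValidationError):
            engine.post_event(RTEvent("custom", "ghost", {}))

    def test_event_posted_during_drain_deferred_to_next_cycle(self):
        class Reposter(ll.Module):
            type_name = "test_reposter"
            PARAMS = {}

            def execute(self, t, dt, inputs):
                return {}

            def update(self, state, event=None):
                if state == LifecycleState.INIT:
                    self.custom_seen_at = []
                    self.reposted = False
                    return
                if event is not None and event.kind == "custom":
                    # engine.cycle during the drain is the running cycle index
                    self.custom_seen_at.append(self.engine.cycle)
                    if not self.reposted:
                        self.reposted = True
                        self.post_event("custom", {"echo": True})

        ll.register_module(Reposter)
        ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
        ws.load_module("test_reposter", "r", {})
        engine = ll.Engine(ws)
        engine.post_event(RTEvent("custom", "r", {}))
        engine.run(3 / 1000.0)
        # first event drained in cycle 0; the echo posted during that drain
        # must be deferred to cycle 1
        assert ws.modules["r"].custom_seen_at == [0, 1]


class TestPeriodChange:
    def test_20khz_gives_50us_budget(self):
        assert ll.EngineConfig(frequency=20_000.0).period == pytest.approx(50e-6)

    def test_period_hook_runs_before_next_executes(self):
        ws = probe_ws(n_probes=1)
        engine = ll.Engine(ws)
        engine.run(1 / 1000.0)
        engine.set_period(2000.0)
        engine.run(1 / 2000.0)
        calls = ws.modules["p0"].calls
        kinds = [(c[0], getattr(c[2], "kind", None) if c[0] == "update" else None)
                 for c in calls]
        i_period = kinds.index(("update", "period_changed"))
        i_exec2 = [i for i, c in enumerate(calls) if c[0] == "execute"][1]
        assert i_period < i_exec2
        assert engine.config.frequency == 2000.0

    def test_unchanged_frequency_emits_no_event(self):
        ws = probe_ws(n_probes=1)
        engine = ll.Engine(ws)
        engine.set_period(1000.0)  # already the configured rate
        engine.run(1 / 1000.0)
        assert not any(
            c[0] == "update" and getattr(c[2], "kind", None) == "period_changed"
            for c in ws.modules["p0"].calls
        )

    def test_nonpositive_frequency_rejected(self):
        engine = ll.Engine(probe_ws())
        with pytest.raises(ValidationError):
            engine.set_period(0.0)

    def test_simulated_time_continuous_across_change(self):
        ws = probe_ws(n_probes=1)
        engine = ll.Engine(ws)
        engine.run(2 / 1000.0)
        engine.set_period(4000.0)
        engine.run(4 / 4000.0)
        assert engine.sim_time == pytest.approx(2 / 1000.0 + 4 / 4000.0)


class TestLoadUnload:
    def test_load_mid_run_first_execute_next_cycle(self):
        ws = probe_ws(n_probes=1)
        engine = ll.Engine(ws)
        engine.run(2 / 1000.0)
        engine.load_module("test_probe", "late", {})
        engine.run(3 / 1000.0)
        assert len(ws.modules["late"].seen_inputs) == 3

    def test_unload_keeps_remaining_fan_in(self):
        ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
        ws.load_module("signal_generator", "a", {"kind": "dc", "amplitude": 1.0})
        ws.load_module("signal_generator", "b", {"kind": "dc", "amplitude": 2.0})
        ws.load_module("test_gain", "sink", {})
        ws.connect("a.out", "sink.in")
        ws.connect("b.out", "sink.in")
        engine = ll.Engine(ws)
        engine.run(1 / 1000.0)
        assert ws.gather("sink.in") == 3.0
        engine.unload_module("a")
        engine.run(1 / 1000.0)
        assert ws.gather("sink.in") == 2.0  # remaining source still summed
        assert all("a." not in c.src for c in ws.connections)

    def test_unload_unknown_and_invalid_params_rejected(self):
        engine = ll.Engine(probe_ws())
        with pytest.raises(WorkspaceError):
            engine.unload_module("ghost")
        with pytest.raises(ValidationError):
            engine.load_module("test_gain", "g", {"not_a_param": 1.0})

    def test_parameter_edit_applies_via_modify_hook(self):
        ws = probe_ws(n_probes=1)
        ws.load_module("test_gain", "g", {"gain": 1.0})
        engine = ll.Engine(ws)
        engine.set_parameter("g", "gain", 3.0)
        engine.run(1 / 1000.0)
        assert ws.modules["g"].params["gain"] == 3.0
        # other modules observe the param_modified event
        assert any(
            getattr(c[2], "kind", None) == "param_modified"
            for c in ws.modules["p0"].calls
            if c[0] == "update"
        )


class TestRunArithmetic:
    @pytest.mark.parametrize(
        "duration,frequency,n",
        [
            (1.0, 20_000.0, 20_000),
            (0.0005, 2_000.0, 1),  # rounding edge: half a millisecond
            (0.25, 1_000.0, 250),
        ],
    )
    def test_cycle_count(self, duration, frequency, n):
        ws = ll.Workspace(ll.EngineConfig(frequency=frequency))
        log = ll.Engine(ws).run(duration)
        assert log.n_cycles == n

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            ll.Engine(ll.Workspace()).run(0.0)


class TestLoadOrderSkew:
    def test_permuting_order_shifts_by_one_cycle_only(self):
        """Downstream-after-upstream sees same-cycle values; the reversed
        load order sees the previous cycle's — a pure one-cycle skew."""

        def build(order):
            ws = ll.Workspace(ll.EngineConfig(frequency=1000.0))
            if order == "upstream_first":
                ws.load_module("signal_generator", "gen",
                               {"kind": "sine", "amplitude": 1.0, "frequency": 50.0})
                ws.load_module("test_gain", "g", {"gain": 1.0})
            else:
                ws.load_module("test_gain", "g", {"gain": 1.0})
                ws.load_module("signal_generator", "gen",
                               {"kind": "sine", "amplitude": 1.0, "frequency": 50.0})
            ws.connect("gen.out", "g.in")
            out = []

            class Tap:
                pass

            engine = ll.Engine(ws)
            for _ in range(20):
                engine.run_cycle()
                out.append(ws.read("g.out"))
            return np.array(out)

        a = build("upstream_first")
        b = build("downstream_first")
        assert np.allclose(b[1:], a[:-1])  # identical values, one-cycle skew
        assert b[0] == 0.0  # nothing yet published at the first cycle


class TestChunkedFastPath:
    def test_chunked_equals_generic_bitwise(self, loopback_ws):
        ws, _, _ = loopback_ws(frequency=2000.0)
        fast = ll.Engine(ws)
        assert fast.run(2.0).chunked

        ws2, _, _ = loopback_ws(frequency=2000.0)
        slow = ll.Engine(ws2)
        slow.attach_benchmarks(ll.BenchmarkStats(ws2.engine.period))  # forces per-cycle
        assert not slow.run(2.0).chunked
        assert np.array_equal(fast.ao_trace("AO0"), slow.ao_trace("AO0"))

    def test_modules_disable_fast_path(self, case3_ws):
        ws, _, _ = case3_ws(frequency=2000.0)
        log = ll.Engine(ws).run(0.5)
        assert not log.chunked
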