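"""Deterministic cycle scheduler emulating a hard real-time thread.

On every cycle of the real-time period the scheduler (1) acquires new data —
each enabled AI channel samples its analog source and publishes the scaled
value; (2) runs the execute step of every loaded, unpaused module once, in
load order, feeding each input port the summed value of its connected
sources; (3) drains the event queue in FIFO order, invoking every module's
update hook once all module computations for the cycle are complete; and
(4) emits the gathered value of every enabled AO/DIO channel, clipped to the
channel range and timestamped with the cycle's simulated time.

The primary mode is *simulated* time: the clock is the cycle counter times
the period, no sleeping occurs, and a run is a pure function of (workspace,
duration, seed) — two identical runs produce identical products, byte for
byte.  A *wallclock* mode sleeps to each deadline for demonstrations; it
carries no hard-RT guarantee, which on a stock kernel would require a
real-time scheduling framework and is out of scope here.

Structural changes — pause/unpause, parameter edits, frequency changes,
loading and unloading modules — are requested at any time and applied at the
next cycle boundary, so acquisition never halts.

For workspaces with no modules and pure AI→AO routing (the loopback and
MIMO characterization cases), :meth:`Engine.run` transparently switches to a
chunked vectorized evaluator that computes many cycles per numpy operation.
It is value-identical to the per-cycle path (the per-sample arithmetic is
the same) and makes half-hour characterization runs cheap.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .daq import emit_ao, quantize_dio, scale_ai
from .dataflow import Workspace
from .errors import ModuleExecutionError, ValidationError, WorkspaceError
from .modules.base import LifecycleState, create_module

__all__ = ["EngineConfig", "RTEvent", "CycleSummary", "RunLog", "Engine", "EVENT_KINDS"]

EVENT_KINDS = (
    "param_modified",
    "period_changed",
    "module_loaded",
    "module_unloaded",
    "pause_changed",
    "custom",
)

# which lifecycle state an event kind is delivered under
_EVENT_STATE = {
    "param_modified": LifecycleState.MODIFY,
    "period_changed": LifecycleState.PERIOD,
    "module_loaded": LifecycleState.MODIFY,
    "module_unloaded": LifecycleState.MODIFY,
    "pause_changed": LifecycleState.MODIFY,
    "custom": LifecycleState.MODIFY,
}


@dataclass
class EngineConfig:
    """Real-time system configuration.

    frequency — cycle rate in Hz (default 20 kHz, i.e. a 50 µs budget per
    cycle); mode — "simulated" or "wallclock"; seed — integer seeding all
    engine-owned randomness.
    """

    frequency: float = 20_000.0
    mode: str = "simulated"
    seed: int = 0

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValidationError(f"frequency must be positive, got {self.frequency}")
        if self.mode not in ("simulated", "wallclock"):
            raise ValidationError(f"unknown engine mode {self.mode!r}")

    @property
    def period(self) -> float:
        """Cycle period in seconds (1/frequency)."""
        return 1.0 / self.frequency


@dataclass
class RTEvent:
    """A deferred notification posted during module execution.

    Events posted in cycle k are drained in cycle k, after every execute of
    that cycle; events posted while the queue is being drained are deferred
    to the next cycle (this bounds same-cycle cascades).
    """

    kind: str
    source: str
    payload: dict[str, Any] = field(default_factory=dict)
    cycle: int = -1

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass
class CycleSummary:
    cycle: int
    t: float
    nan_ports: list[str]
    events_drained: int


@dataclass
class RunLog:
    """Summary of one run() invocation."""

    n_cycles: int
    start_time: float
    end_time: float
    frequency: float
    termination: str = "completed"
    nan_cycles: int = 0
    events_drained: int = 0
    chunked: bool = False


class Engine:
    """Cycle scheduler bound to one workspace.

    Recorder trial handles and benchmark collectors are attached as
    observers; they receive every cycle synchronously.
    """

    def __init__(self, workspace: Workspace):
        workspace.validate()
        self.workspace = workspace
        self.cycle = 0  # index of the next cycle to run
        self._t_base = 0.0  # simulated time at the last frequency change
        self._k_base = 0  # cycle index at the last frequency change
        self._events: list[RTEvent] = []
        self._draining = False
        self._deferred: list[RTEvent] = []
        self._boundary_ops: list = []
        self.ao_traces: dict[str, list[np.ndarray]] = {}
        self._recorder = None
        self._record_signals: list[str] = []
        self._record_base_cycle = 0
        self.benchmarks = None
        self.rng = np.random.default_rng(workspace.engine.seed)
        for mod in workspace.modules.values():
            mod.engine = self

    # -- clock -------------------------------------------------------------

    @property
    def config(self) -> EngineConfig:
        return self.workspace.engine

    @property
    def period(self) -> float:
        return self.config.period

    @property
    def sim_time(self) -> float:
        """Simulated time of the next cycle's acquire step."""
        return self._t_base + (self.cycle - self._k_base) / self.config.frequency

    # -- observers ---------------------------------------------------------

    def attach_recorder(self, trial_handle, signals: Sequence[str]) -> None:
        """Stream ``signals`` (port endpoints) into an active recorder trial."""
        for s in signals:
            if not (s in self.workspace.channels or self._endpoint_exists(s)):
                raise ValidationError(f"cannot record unknown signal {s!r}")
        self._recorder = trial_handle
        self._record_signals = list(signals)
        self._record_base_cycle = self.cycle

    def detach_recorder(self) -> None:
        self._recorder = None
        self._record_signals = []

    def attach_benchmarks(self, stats) -> None:
        self.benchmarks = stats

    def _endpoint_exists(self, endpoint: str) -> bool:
        if "." not in endpoint:
            return False
        owner, name = endpoint.split(".", 1)
        mod = self.workspace.modules.get(owner)
        return mod is not None and (name in mod.OUTPUTS or name in mod.INPUTS)

    # -- events ------------------------------------------------------------

    def post_event(self, event: RTEvent) -> None:
        """Append an event FIFO; it is drained after the executes of the
        current cycle, or of the next cycle if posted during a drain or
        between cycles."""
        if event.source not in self.workspace.modules and event.source not in (
            "engine",
            "system",
        ):
            raise ValidationError(f"event from unknown source {event.source!r}")
        event.cycle = self.cycle
        if self._draining:
            self._deferred.append(event)
        else:
            self._events.append(event)

    def _drain_events(self) -> int:
        drained = 0
        self._draining = True
        try:
            queue, self._events = self._events, []
            for ev in queue:
                state = _EVENT_STATE[ev.kind]
                for mod in list(self.workspace.modules.values()):
                    mod.update(state, ev)
                drained += 1
        finally:
            self._draining = False
        self._events.extend(self._deferred)
        self._deferred = []
        return drained

    # -- boundary requests ---------------------------------------------------

    def set_period(self, frequency: float) -> None:
        """Request a frequency change; takes effect at the next cycle
        boundary, with every module's PERIOD hook invoked before the next
        executes.  Setting the current frequency is a no-op."""
        if frequency <= 0:
            raise ValidationError(f"frequency must be positive, got {frequency}")
        self._boundary_ops.append(("period", float(frequency)))

    def load_module(self, type_name: str, module_id: str, params=None) -> None:
        """Request loading a module between cycles; INIT runs on load and
        the first execute is in the following cycle."""
        create_module(type_name, module_id, params)  # validate type + params now
        self._boundary_ops.append(("load", type_name, module_id, dict(params or {})))

    def unload_module(self, module_id: str) -> None:
        if module_id not in self.workspace.modules:
            raise WorkspaceError(f"no module {module_id!r} to unload")
        self._boundary_ops.append(("unload", module_id))

    def set_pause(self, module_id: str, paused: bool) -> None:
        if module_id not in self.workspace.modules:
            raise WorkspaceError(f"no module {module_id!r}")
        self._boundary_ops.append(("pause", module_id, bool(paused)))

    def set_parameter(self, module_id: str, name: str, value) -> None:
        """Request a live parameter edit: applied at the next boundary via
        the module's MODIFY hook, broadcast as a param_modified event, and
        logged to the recorder (with timestamp) if a trial is active."""
        mod = self.workspace.modules.get(module_id)
        if mod is None:
            raise WorkspaceError(f"no module {module_id!r}")
        if name not in mod.PARAMS:
            raise ValidationError(f"module {module_id!r}: unknown parameter {name!r}")
        self._boundary_ops.append(("param", module_id, name, value))

    def _apply_boundary_ops(self) -> None:
        ops, self._boundary_ops = self._boundary_ops, []
        for op in ops:
            kind = op[0]
            if kind == "period":
                self._do_set_period(op[1])
            elif kind == "load":
                _, type_name, module_id, params = op
                mod = self.workspace.load_module(type_name, module_id, params)
                mod.engine = self
                self.post_event(RTEvent("module_loaded", "engine", {"id": module_id}))
            elif kind == "unload":
                self.workspace.remove_module(op[1])
                self.post_event(RTEvent("module_unloaded", "engine", {"id": op[1]}))
            elif kind == "pause":
                _, module_id, paused = op
                mod = self.workspace.modules[module_id]
                if mod.paused != paused:
                    mod.paused = paused
                    mod.update(
                        LifecycleState.PAUSED if paused else LifecycleState.UNPAUSED
                    )
                    self.post_event(
                        RTEvent("pause_changed", "engine",
                                {"id": module_id, "paused": paused})
                    )
            elif kind == "param":
                _, module_id, name, value = op
                mod = self.workspace.modules[module_id]
                mod.set_param(name, value)  # MODIFY hook runs here
                self.post_event(
                    RTEvent("param_modified", module_id, {"name": name, "value": value})
                )
                if self._recorder is not None and self._recorder.active:
                    self._recorder.log_param_change(self.sim_time, module_id, name, value)

    def _do_set_period(self, frequency: float) -> None:
        if frequency == self.config.frequency:
            return  # idempotent: no PERIOD event
        self._t_base = self.sim_time
        self._k_base = self.cycle
        self.config.frequency = frequency
        ev = RTEvent(
            "period_changed",
            "engine",
            {"frequency": frequency, "period": 1.0 / frequency},
            cycle=self.cycle,
        )
        # PERIOD hooks run before the next cycle's executes
        for mod in list(self.workspace.modules.values()):
            mod.update(LifecycleState.PERIOD, ev)

    # -- the cycle ----------------------------------------------------------

    def run_cycle(self) -> CycleSummary:
        """Run the next cycle (acquire → execute → drain events → emit)."""
        ws = self.workspace
        k = self.cycle
        t = self.sim_time
        dt = self.period
        nan_ports: list[str] = []

        # (1) acquire: enabled AI channels publish their scaled samples
        for ch in ws.channels.values():
            if ch.direction != "AI" or not ch.enabled:
                continue
            src = ws.ai_sources.get(ch.index)
            raw = float(src(t)) if src is not None else 0.0
            ws.set_value(ch.name, float(scale_ai(raw, ch)))

        # (2) execute every loaded, unpaused module in load order
        for mod in list(ws.modules.values()):
            if mod.paused:
                continue
            inputs = {name: ws.gather(f"{mod.id}.{name}") for name in mod.INPUTS}
            try:
                outputs = mod.execute(t, dt, inputs)
            except Exception as exc:
                raise ModuleExecutionError(mod.id, k, exc) from exc
            for name, value in (outputs or {}).items():
                endpoint = f"{mod.id}.{name}"
                value = float(value)
                if math.isnan(value):
                    nan_ports.append(endpoint)
                ws.set_value(endpoint, value)

        # (3) drain the event queue once all module computations are complete
        drained = self._drain_events()

        # (4) emit: enabled AO/DIO channels output their gathered values
        for ch in ws.channels.values():
            if ch.direction == "AI" or not ch.enabled:
                continue
            value = ws.gather(ch.name)
            if math.isnan(value):
                nan_ports.append(ch.name)
                out = value
            else:
                out = float(emit_ao(value, ch))
                if ch.direction == "DIO":
                    out = float(quantize_dio(out))
            ws.set_value(ch.name, out)
            self.ao_traces.setdefault(ch.name, []).append(out)

        # observers
        if self._recorder is not None and self._recorder.active:
            values = [ws.read(s) for s in self._record_signals]
            self._recorder.record_cycle(k - self._record_base_cycle, values)

        self.cycle += 1
        return CycleSummary(cycle=k, t=t, nan_ports=nan_ports, events_drained=drained)

    # -- runs ----------------------------------------------------------------

    def run(self, duration: float) -> RunLog:
        """Run for ``duration`` simulated seconds (round(duration*frequency)
        cycles).  In simulated mode no wall-clock sleeping occurs."""
        if duration <= 0:
            raise ValidationError(f"duration must be positive, got {duration}")
        # pending boundary requests (e.g. a frequency change) apply first so
        # the cycle count uses the effective rate
        self._apply_boundary_ops()
        n = int(round(duration * self.config.frequency))
        start = self.sim_time
        if self._fast_path_ok():
            return self._run_chunked(n, start)

        wallclock = self.config.mode == "wallclock"
        nan_cycles = 0
        drained_total = 0
        deadline = time.perf_counter()
        for i in range(n):
            if wallclock:
                deadline += self.period
                lag = deadline - time.perf_counter()
                if lag > 0:
                    time.sleep(lag)
            c0 = time.perf_counter()
            try:
                summary = self.run_cycle()
            except ModuleExecutionError as exc:
                exc.partial_log = RunLog(
                    n_cycles=i,
                    start_time=start,
                    end_time=self.sim_time,
                    frequency=self.config.frequency,
                    termination=f"error in module {exc.module_id!r} at cycle {exc.cycle}",
                )
                raise
            c1 = time.perf_counter()
            if self.benchmarks is not None:
                if wallclock:
                    self.benchmarks.record_cycle_timing(c0, c1)
                else:
                    self.benchmarks.record_period(self.period, c1 - c0)
            if summary.nan_ports:
                nan_cycles += 1
            drained_total += summary.events_drained
            self._apply_boundary_ops()
        return RunLog(
            n_cycles=n,
            start_time=start,
            end_time=self.sim_time,
            frequency=self.config.frequency,
            nan_cycles=nan_cycles,
            events_drained=drained_total,
        )

    # -- chunked fast path ---------------------------------------------------

    def _fast_path_ok(self) -> bool:
        ws = self.workspace
        if ws.modules or self.config.mode != "simulated":
            return False
        if self.benchmarks is not None or self._events or self._boundary_ops:
            return False
        for c in ws.connections:
            if "." in c.src or "." in c.dst:
                return False
        return True

    def _run_chunked(self, n: int, start: float, chunk: int = 250_000) -> RunLog:
        """Vectorized evaluation of a module-free AI→AO workspace.

        Value-identical to the per-cycle path: the same scale/sum/clip
        arithmetic is applied elementwise over blocks of cycles.
        """
        ws = self.workspace
        f = self.config.frequency
        ai = [
            ch for ch in ws.channels.values() if ch.direction == "AI" and ch.enabled
        ]
        outs = [
            ch for ch in ws.channels.values() if ch.direction != "AI" and ch.enabled
        ]
        nan_cycles = 0
        for k0 in range(0, n, chunk):
            k1 = min(k0 + chunk, n)
            kk = np.arange(self.cycle + k0, self.cycle + k1, dtype=np.int64)
            t = self._t_base + (kk - self._k_base) / f
            ai_vals: dict[str, np.ndarray] = {}
            for ch in ai:
                src = ws.ai_sources.get(ch.index)
                raw = src(t) if src is not None else np.zeros(len(t))
                ai_vals[ch.name] = np.asarray(scale_ai(raw, ch), dtype=float)
            out_vals: dict[str, np.ndarray] = {}
            for ch in outs:
                total = np.zeros(len(t))
                for conn in ws.sources_into(ch.name):
                    total = total + ai_vals[conn.src]
                emitted = np.asarray(emit_ao(total, ch), dtype=float)
                if ch.direction == "DIO":
                    emitted = np.asarray(quantize_dio(emitted), dtype=float)
                bad = np.isnan(total)
                if bad.any():
                    emitted = np.where(bad, np.nan, emitted)
                    nan_cycles += int(bad.sum())
                out_vals[ch.name] = emitted
                self.ao_traces.setdefault(ch.name, []).append(emitted)
            if self._recorder is not None and self._recorder.active:
                cols = []
                for s in self._record_signals:
                    cols.append(ai_vals.get(s, out_vals.get(s, np.zeros(len(t)))))
                self._recorder.record_chunk(
                    self.cycle + k0 - self._record_base_cycle,
                    np.column_stack(cols),
                )
            # publish the last sample of the chunk to the value store
            for name, vals in (*ai_vals.items(), *out_vals.items()):
                ws.set_value(name, float(vals[-1]))
        self.cycle += n
        return RunLog(
            n_cycles=n,
            start_time=start,
            end_time=self.sim_time,
            frequency=f,
            nan_cycles=nan_cycles,
            chunked=True,
        )

    # -- trace access ---------------------------------------------------------

    def ao_trace(self, channel_name: str) -> np.ndarray:
        """Concatenated per-cycle output samples of an AO/DIO channel."""
        chunks = self.ao_traces.get(channel_name, [])
        if not chunks:
            return np.empty(0)
        return np.concatenate([np.atleast_1d(np.asarray(c, dtype=float)) for c in chunks])
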