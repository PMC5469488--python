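"""Ports, connections, and the workspace.

A workspace is the complete description of an experiment setup: the engine
configuration, the DAQ channel configurations, the ordered list of loaded
modules with their parameter and state values, and the connections between
ports.  It round-trips losslessly through a small versioned XML dialect so
that a protocol built on one machine can be restored on another.

Endpoints are written as strings: ``"AI0"`` / ``"AO1"`` / ``"DIO0"`` for DAQ
channels, ``"module_id.port"`` for module ports.  Fan-in is allowed — when
several outputs feed one input, the samples are summed before the input sees
them; summation runs in ascending connection-id order so floating-point
results are reproducible.  An unconnected input reads 0.0 (the empty sum).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Any, Callable, Iterable
from xml.etree import ElementTree as ET

from .daq import ChannelConfig
from .errors import ValidationError, WorkspaceError
from .modules.base import Module, create_module

__all__ = ["Port", "Connection", "Workspace"]

_CHANNEL_RE = re.compile(r"^(AI|AO|DIO)(\d+)$")


@dataclass(frozen=True)
class Port:
    """A resolved endpoint: (owner, name, direction)."""

    owner: str  # module id, or "daq" for channels
    name: str
    direction: str  # "input" | "output"

    @property
    def endpoint(self) -> str:
        return self.name if self.owner == "daq" else f"{self.owner}.{self.name}"


@dataclass(frozen=True)
class Connection:
    """A directed edge from an output port to an input port."""

    id: int
    src: str
    dst: str


class Workspace:
    """Engine config + channels + ordered modules + connections.

    Module insertion order is load order; the engine executes modules in
    this order within each cycle.
    """

    def __init__(self, engine_config=None):
        if engine_config is None:
            from .engine import EngineConfig

            engine_config = EngineConfig()
        self.engine = engine_config
        self.channels: dict[str, ChannelConfig] = {}
        self.modules: dict[str, Module] = {}
        self.connections: list[Connection] = []
        self._next_conn_id = 1
        # runtime-only signal store; not part of persistence
        self.values: dict[str, float] = {}
        self.ai_sources: dict[int, Callable] = {}

    # -- construction -----------------------------------------------------

    def add_channel(self, config: ChannelConfig) -> ChannelConfig:
        if config.name in self.channels:
            raise WorkspaceError(f"channel {config.name} already configured")
        self.channels[config.name] = config
        return config

    def add_module(self, module: Module) -> Module:
        if module.id in self.modules:
            raise WorkspaceError(f"module id {module.id!r} already loaded")
        if _CHANNEL_RE.match(module.id) or "." in module.id:
            raise WorkspaceError(f"module id {module.id!r} collides with endpoint syntax")
        self.modules[module.id] = module
        return module

    def load_module(self, type_name: str, module_id: str, params=None) -> Module:
        """Instantiate a registered type (its INIT hook runs) and add it."""
        return self.add_module(create_module(type_name, module_id, params))

    def remove_module(self, module_id: str) -> list[Connection]:
        """Unload a module; connections touching it are removed with it."""
        if module_id not in self.modules:
            raise WorkspaceError(f"no module {module_id!r} to unload")
        mod = self.modules.pop(module_id)
        prefix = f"{module_id}."
        dropped = [
            c for c in self.connections
            if c.src.startswith(prefix) or c.dst.startswith(prefix)
        ]
        self.connections = [c for c in self.connections if c not in dropped]
        for name in mod.OUTPUTS:
            self.values.pop(f"{module_id}.{name}", None)
        return dropped

    def set_ai_source(self, index: int, fn: Callable) -> None:
        """Attach the analog signal feeding AI channel ``index``.

        ``fn`` maps time (scalar or array, seconds) to volts and must be
        vectorized; fixture generators return suitable callables.
        """
        self.ai_sources[index] = fn

    # -- endpoint resolution ----------------------------------------------

    def resolve(self, endpoint: str, expect: str) -> Port:
        """Resolve an endpoint string; ``expect`` is "output" (for a
        connection source) or "input" (for a destination)."""
        m = _CHANNEL_RE.match(endpoint)
        if m:
            if endpoint not in self.channels:
                raise ValidationError(f"no such channel {endpoint}")
            direction = "output" if m.group(1) == "AI" else "input"
            if direction != expect:
                raise ValidationError(
                    f"channel {endpoint} cannot be used as a connection {expect}"
                )
            return Port("daq", endpoint, direction)
        if "." not in endpoint:
            raise ValidationError(f"malformed endpoint {endpoint!r}")
        owner, name = endpoint.split(".", 1)
        if owner not in self.modules:
            raise ValidationError(f"no module {owner!r} for endpoint {endpoint!r}")
        mod = self.modules[owner]
        if expect == "output":
            if name not in mod.OUTPUTS:
                raise ValidationError(
                    f"{endpoint!r} is not an output port of {owner!r} "
                    f"(outputs: {list(mod.OUTPUTS)})"
                )
        else:
            if name not in mod.INPUTS:
                raise ValidationError(
                    f"{endpoint!r} is not an input port of {owner!r} "
                    f"(inputs: {list(mod.INPUTS)})"
                )
        return Port(owner, name, expect)

    # -- connections ------------------------------------------------------

    def connect(self, src: str, dst: str) -> int:
        """Create a connection; returns its id.  Duplicates are rejected."""
        self.resolve(src, "output")
        self.resolve(dst, "input")
        for c in self.connections:
            if c.src == src and c.dst == dst:
                raise ValidationError(f"duplicate connection {src} -> {dst}")
        conn = Connection(self._next_conn_id, src, dst)
        self._next_conn_id += 1
        self.connections.append(conn)
        return conn.id

    def disconnect(self, conn_id: int) -> None:
        for i, c in enumerate(self.connections):
            if c.id == conn_id:
                del self.connections[i]
                return
        raise ValidationError(f"no connection with id {conn_id}")

    def sources_into(self, dst: str) -> list[Connection]:
        """Connections feeding ``dst``, in ascending id (= summation) order."""
        conns = [c for c in self.connections if c.dst == dst]
        conns.sort(key=lambda c: c.id)
        return conns

    # -- the sample store -------------------------------------------------

    def set_value(self, endpoint: str, value: float) -> None:
        self.values[endpoint] = value

    def read(self, endpoint: str) -> float:
        return self.values.get(endpoint, 0.0)

    def gather(self, dst: str) -> float:
        """Fan-in rule: the sum of the latest values on all sources feeding
        ``dst`` (0.0 when nothing is connected)."""
        total = 0.0
        for c in self.sources_into(dst):
            total += self.values.get(c.src, 0.0)
        return total

    def validate(self) -> None:
        """Check that every connection endpoint resolves."""
        for c in self.connections:
            self.resolve(c.src, "output")
            self.resolve(c.dst, "input")

    # -- equality / description -------------------------------------------

    def describe(self) -> dict[str, Any]:
        """Plain-data description of everything persistence covers."""
        return {
            "engine": {
                "frequency": self.engine.frequency,
                "mode": self.engine.mode,
                "seed": self.engine.seed,
            },
            "channels": {
                name: (c.index, c.direction, c.mode, c.range, c.gain, c.offset, c.enabled)
                for name, c in self.channels.items()
            },
            "modules": [
                (m.id, m.type_name, dict(m.params), m.state_dict())
                for m in self.modules.values()
            ],
            "connections": [(c.src, c.dst) for c in self.connections],
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, Workspace):
            return NotImplemented
        return self.describe() == other.describe()

    # -- XML persistence ---------------------------------------------------

    def to_xml_string(self) -> str:
        root = ET.Element("workspace", version="1")
        ET.SubElement(
            root,
            "engine",
            frequency=repr(float(self.engine.frequency)),
            mode=self.engine.mode,
            seed=str(int(self.engine.seed)),
        )
        daq = ET.SubElement(root, "daq")
        for ch in self.channels.values():
            ET.SubElement(
                daq,
                "channel",
                index=str(ch.index),
                direction=ch.direction,
                mode=ch.mode,
                range_lo=repr(ch.range[0]),
                range_hi=repr(ch.range[1]),
                gain=repr(float(ch.gain)),
                offset=repr(float(ch.offset)),
                enabled="true" if ch.enabled else "false",
            )
        mods = ET.SubElement(root, "modules")
        for m in self.modules.values():
            el = ET.SubElement(mods, "module", id=m.id, type=m.type_name)
            for name, value in m.params.items():
                ET.SubElement(el, "param", name=name, value=_fmt(value))
            for name, value in m.state_dict().items():
                ET.SubElement(el, "state", name=name, value=_fmt(value))
        conns = ET.SubElement(root, "connections")
        for c in self.connections:
            ET.SubElement(conns, "connection", src=c.src, dst=c.dst)
        ET.indent(root)
        buf = io.BytesIO()
        ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
        return buf.getvalue().decode("utf-8") + "\n"

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_xml_string())

    @classmethod
    def from_xml_string(cls, text: str) -> "Workspace":
        from .engine import EngineConfig

        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise WorkspaceError(f"malformed workspace XML: {exc}") from exc
        if root.tag != "workspace":
            raise WorkspaceError(f"root element must be <workspace>, got <{root.tag}>")
        if root.get("version") != "1":
            raise WorkspaceError(f"unsupported workspace version {root.get('version')!r}")

        eng = root.find("engine")
        if eng is None:
            raise WorkspaceError("missing <engine> element")
        config = EngineConfig(
            frequency=float(eng.get("frequency", "20000.0")),
            mode=eng.get("mode", "simulated"),
            seed=int(eng.get("seed", "0")),
        )
        ws = cls(config)
        daq = root.find("daq")
        if daq is not None:
            for el in daq.findall("channel"):
                ws.add_channel(
                    ChannelConfig(
                        index=int(_require(el, "index")),
                        direction=_require(el, "direction"),
                        mode=el.get("mode", "ground_referenced"),
                        range=(
                            float(el.get("range_lo", "-10")),
                            float(el.get("range_hi", "10")),
                        ),
                        gain=float(el.get("gain", "1.0")),
                        offset=float(el.get("offset", "0.0")),
                        enabled=el.get("enabled", "true") == "true",
                    )
                )
        mods = root.find("modules")
        if mods is not None:
            for el in mods.findall("module"):
                params = {
                    p.get("name"): _parse(_require(p, "value"))
                    for p in el.findall("param")
                }
                mod = create_module(_require(el, "type"), _require(el, "id"), params)
                states = {
                    s.get("name"): _parse(_require(s, "value"))
                    for s in el.findall("state")
                }
                if states:
                    mod.load_state(states)
                ws.add_module(mod)
        conns = root.find("connections")
        if conns is not None:
            for el in conns.findall("connection"):
                ws.connect(_require(el, "src"), _require(el, "dst"))
        ws.validate()
        return ws

    @classmethod
    def load(cls, path) -> "Workspace":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_xml_string(fh.read())


def _fmt(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (int, bool)):
        return repr(float(value)) if isinstance(value, bool) else str(value)
    return str(value)


def _parse(text: str) -> Any:
    try:
        return float(text)
    except ValueError:
        return text


def _require(el: ET.Element, attr: str) -> str:
    value = el.get(attr)
    if value is None:
        raise WorkspaceError(f"<{el.tag}> element missing required attribute {attr!r}")
    return value
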