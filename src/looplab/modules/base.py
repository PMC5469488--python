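"""Base module class and lifecycle.

Every processing block — core or user-written — derives from :class:`Module`
and declares its I/O ports, parameters, and exported state variables as class
attributes (the analogue of a plugin's variable table).  Real-time work goes
in :meth:`Module.execute`, which the engine calls once per cycle while the
module is unpaused; reactions to system notifications (parameter edits,
period changes, load/unload, pause toggles) go in :meth:`Module.update`,
keyed by one of five lifecycle states.
"""

from __future__ import annotations

import enum
from typing import Any, Mapping

from ..errors import ValidationError

__all__ = ["LifecycleState", "Module", "MODULE_TYPES", "register_module", "create_module"]


class LifecycleState(enum.Enum):
    """The five module lifecycle states.

    INIT      — module elements are being initialized (on load)
    MODIFY    — a parameter or workspace change was applied
    PERIOD    — the system frequency/period changed
    PAUSED    — execution of this module was suspended
    UNPAUSED  — execution of this module resumed
    """

    INIT = "INIT"
    MODIFY = "MODIFY"
    PERIOD = "PERIOD"
    PAUSED = "PAUSED"
    UNPAUSED = "UNPAUSED"


#: Registry of loadable module types: type name -> class.
MODULE_TYPES: dict[str, type["Module"]] = {}


def register_module(cls: type["Module"]) -> type["Module"]:
    """Class decorator adding a module type to the registry."""
    if not cls.type_name:
        raise ValidationError(f"{cls.__name__} has no type_name")
    MODULE_TYPES[cls.type_name] = cls
    return cls


def create_module(type_name: str, module_id: str, params: Mapping[str, Any] | None = None) -> "Module":
    """Instantiate a registered module type; unknown types list what exists."""
    try:
        cls = MODULE_TYPES[type_name]
    except KeyError:
        known = ", ".join(sorted(MODULE_TYPES))
        raise ValidationError(
            f"unknown module type {type_name!r}; registered types: {known}"
        ) from None
    return cls(module_id, **(params or {}))


class Module:
    """A processing block with scalar input/output ports.

    Subclasses set:

    ``type_name``
        registry name used in workspace files;
    ``INPUTS`` / ``OUTPUTS``
        tuples of port names (one scalar sample per cycle each);
    ``PARAMS``
        mapping of parameter name -> default value (floats or strings);
    ``STATES``
        names of attributes exported as state (recorded / persisted).
    """

    type_name: str = ""
    INPUTS: tuple[str, ...] = ()
    OUTPUTS: tuple[str, ...] = ()
    PARAMS: dict[str, Any] = {}
    STATES: tuple[str, ...] = ()

    #: set by the engine when the module runs under one; enables post_event
    engine = None

    def __init__(self, module_id: str, **params: Any):
        self.id = module_id
        unknown = set(params) - set(self.PARAMS)
        if unknown:
            raise ValidationError(
                f"module {module_id!r} ({self.type_name}): unknown parameter(s) "
                f"{sorted(unknown)}; valid: {sorted(self.PARAMS)}"
            )
        merged = {**self.PARAMS, **params}
        # numeric parameters are normalized to float so persistence round-trips
        self.params: dict[str, Any] = {
            k: float(v) if isinstance(v, (int, float)) else v for k, v in merged.items()
        }
        self.paused = False
        self.update(LifecycleState.INIT)

    # -- hooks ------------------------------------------------------------

    def execute(self, t: float, dt: float, inputs: Mapping[str, float]) -> dict[str, float]:
        """One hard-RT step at simulated time ``t`` with cycle period ``dt``.

        ``inputs`` maps each declared input port to its gathered (summed)
        value.  Returns a mapping of output port name -> sample.
        """
        raise NotImplementedError

    def update(self, state: LifecycleState, event: Any = None) -> None:
        """Lifecycle hook; default does nothing.  ``event`` is the posted
        notification (an :class:`~looplab.engine.RTEvent`) when one exists."""

    def post_event(self, kind: str, payload: Mapping[str, Any] | None = None) -> None:
        """Post a notification to the engine's event queue (drained after
        all executes of the current cycle)."""
        if self.engine is None:
            raise ValidationError(
                f"module {self.id!r} is not attached to a running engine"
            )
        from ..engine import RTEvent

        self.engine.post_event(RTEvent(kind, self.id, dict(payload or {})))

    # -- parameters & state ----------------------------------------------

    def set_param(self, name: str, value: Any) -> None:
        if name not in self.PARAMS:
            raise ValidationError(
                f"module {self.id!r}: unknown parameter {name!r}"
            )
        self.params[name] = float(value) if isinstance(value, (int, float)) else value
        self.update(LifecycleState.MODIFY)

    def state_dict(self) -> dict[str, float]:
        """Exported state values, by declared name."""
        return {name: getattr(self, name) for name in self.STATES}

    def load_state(self, state: Mapping[str, float]) -> None:
        for name, value in state.items():
            if name not in self.STATES:
                raise ValidationError(
                    f"module {self.id!r}: unknown state {name!r}"
                )
            setattr(self, name, value)

    def port_names(self, direction: str) -> tuple[str, ...]:
        return self.INPUTS if direction == "input" else self.OUTPUTS

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} id={self.id!r}>"
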