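"""Exception hierarchy."""


class LoopLabError(Exception):
    """Base class for all looplab errors."""


class ValidationError(LoopLabError):
    """A workspace, channel, or module configuration is invalid."""


class WorkspaceError(LoopLabError):
    """Workspace structure or persistence problem."""


class RecorderError(LoopLabError):
    """Data-recorder misuse (double stop, value-count mismatch, ...)."""


class ModuleExecutionError(LoopLabError):
    """A module's execute step raised; carries the module id and cycle index."""

    def __init__(self, module_id: str, cycle: int, cause: BaseException):
        super().__init__(
            f"module {module_id!r} failed at cycle {cycle}: {cause!r}"
        )
        self.module_id = module_id
        self.cycle = cycle
        self.cause = cause
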