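"""HDF5 data recorder.

Each recording trial becomes one ``/Trial N`` group in the file, holding:

``Synchronous Data``
    a 2-D float64 dataset (rows = kept cycles, columns = recorded signals,
    column names in the ``columns`` attribute);
``Parameters``
    one sub-group per module, one dataset per parameter: the initial value
    (snapshot taken when recording starts) as an ``initial`` attribute and
    the timestamped change table as rows of (time, value);
``System Settings``
    the configuration of every enabled AI channel at trial start;
``Tags``
    timestamped free-text annotations.

Trial-level attributes carry the engine period, the downsample factor k, and
the simulated start/stop times (float64 seconds — no wall-clock timestamps,
so identical runs give identical files).  Global downsampling keeps cycles
congruent to 0 mod k (plain decimation, no anti-alias filter): a trial of
``n`` cycles stores ``ceil(n / k)`` rows.  Files use no custom filters and
are readable by any standard HDF5 tool.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

from .daq import ChannelConfig
from .errors import RecorderError, ValidationError

__all__ = [
    "Recorder",
    "TrialHandle",
    "TrialData",
    "read_trial",
    "list_trials",
    "snapshot_from_workspace",
    "export_trace",
]

_STR = h5py.string_dtype(encoding="utf-8")
_CHANGE_DTYPE = np.dtype([("time", "f8"), ("value", _STR)])
_TAG_DTYPE = np.dtype([("time", "f8"), ("text", _STR)])
_FLUSH_ROWS = 65536


def snapshot_from_workspace(workspace) -> tuple[dict, list[ChannelConfig]]:
    """Parameter snapshot of all loaded modules plus enabled AI channels."""
    params = {
        (mod.id, name): value
        for mod in workspace.modules.values()
        for name, value in mod.params.items()
    }
    channels = [
        ch
        for ch in workspace.channels.values()
        if ch.direction == "AI" and ch.enabled
    ]
    return params, channels


class Recorder:
    """A writable HDF5 experiment file holding numbered trials.

    Pointing at an existing file requires an explicit choice: ``mode="append"``
    continues with the next trial number, ``mode="overwrite"`` truncates.
    """

    def __init__(self, path, mode: str | None = None):
        self.path = os.fspath(path)
        exists = os.path.exists(self.path)
        if mode is None:
            if exists:
                raise RecorderError(
                    f"{self.path} exists; choose mode='append' or mode='overwrite'"
                )
            mode = "append"
        if mode not in ("append", "overwrite"):
            raise RecorderError(f"unknown recorder mode {mode!r}")
        self._file = h5py.File(self.path, "w" if mode == "overwrite" else "a")
        self._active: TrialHandle | None = None

    @property
    def n_trials(self) -> int:
        return sum(1 for k in self._file.keys() if k.startswith("Trial "))

    def start_trial(
        self,
        signals: Sequence[str],
        period: float,
        downsample: int = 1,
        parameters: Mapping[tuple[str, str], Any] | None = None,
        channels: Sequence[ChannelConfig] = (),
        start_time: float = 0.0,
    ) -> "TrialHandle":
        """Open ``/Trial N`` (N = trials present + 1) and begin buffering.

        ``signals`` fixes the column order of the synchronous dataset;
        ``parameters`` is the full snapshot keyed (module id, name).
        """
        if self._active is not None and self._active.active:
            raise RecorderError("a trial is already active")
        if int(downsample) < 1 or downsample != int(downsample):
            raise ValidationError(f"downsample factor must be a positive integer, got {downsample}")
        if not signals:
            raise ValidationError("at least one signal must be recorded")
        n = self.n_trials + 1
        group = self._file.create_group(f"Trial {n}")
        handle = TrialHandle(
            group=group,
            trial=n,
            signals=list(signals),
            period=float(period),
            downsample=int(downsample),
            parameters=dict(parameters or {}),
            channels=list(channels),
            start_time=float(start_time),
        )
        self._active = handle
        return handle

    def close(self) -> None:
        if self._active is not None and self._active.active:
            self._active.stop()
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class TrialHandle:
    """One active recording trial (returned by :meth:`Recorder.start_trial`)."""

    def __init__(self, group, trial, signals, period, downsample, parameters,
                 channels, start_time):
        self.group = group
        self.trial = trial
        self.signals = signals
        self.period = period
        self.downsample = downsample
        self.parameters = parameters
        self.channels = channels
        self.start_time = start_time
        self.active = True
        self.rows = 0
        self._buffer: list[np.ndarray] = []
        self._changes: list[tuple[float, str, str, Any]] = []
        self._tags: list[tuple[float, str]] = []
        self._last_change_time = start_time
        ncols = len(signals)
        self._data = group.create_dataset(
            "Synchronous Data",
            shape=(0, ncols),
            maxshape=(None, ncols),
            chunks=(4096, ncols),
            dtype="f8",
        )
        self._data.attrs["columns"] = np.asarray(signals, dtype=_STR)
        group.attrs["period"] = float(period)
        group.attrs["downsample"] = int(downsample)
        group.attrs["start_time"] = float(start_time)

    # -- streaming ---------------------------------------------------------

    def record_cycle(self, cycle_index: int, values: Sequence[float]) -> None:
        """Store one cycle's samples iff cycle_index ≡ 0 (mod k)."""
        if not self.active:
            raise RecorderError("trial is stopped")
        if len(values) != len(self.signals):
            raise RecorderError(
                f"got {len(values)} values for {len(self.signals)} signals"
            )
        if cycle_index % self.downsample == 0:
            self._buffer.append(np.asarray(values, dtype=float))
            if len(self._buffer) >= _FLUSH_ROWS:
                self._flush()

    def record_chunk(self, cycle0: int, matrix: np.ndarray) -> None:
        """Vectorized equivalent of record_cycle for cycles
        cycle0 .. cycle0+len(matrix)-1."""
        if not self.active:
            raise RecorderError("trial is stopped")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != len(self.signals):
            raise RecorderError("chunk shape does not match the signal list")
        k = self.downsample
        first = (-cycle0) % k
        rows = matrix[first::k]
        if len(rows):
            self._buffer.append(rows)
            if sum(len(np.atleast_2d(b)) for b in self._buffer) >= _FLUSH_ROWS:
                self._flush()

    def log_param_change(self, time: float, module: str, name: str, value) -> None:
        """Timestamped record of a live parameter edit."""
        if not self.active:
            raise RecorderError("trial is stopped")
        if (module, name) not in self.parameters:
            raise ValidationError(
                f"parameter {module}.{name} is not in the trial snapshot"
            )
        if time < self._last_change_time:
            raise ValidationError("parameter change times must be non-decreasing")
        self._last_change_time = time
        self._changes.append((float(time), module, name, value))

    def add_tag(self, time: float, text: str) -> None:
        if not self.active:
            raise RecorderError("trial is stopped")
        self._tags.append((float(time), str(text)))

    # -- finalization ------------------------------------------------------

    def _flush(self) -> None:
        if not self._buffer:
            return
        block = np.vstack([np.atleast_2d(b) for b in self._buffer])
        self._buffer = []
        n0 = self._data.shape[0]
        self._data.resize(n0 + len(block), axis=0)
        self._data[n0:] = block
        self.rows = n0 + len(block)

    def stop(self, stop_time: float | None = None) -> dict:
        """Flush buffers, write metadata groups, and close the trial.

        Returns row count and trial duration.
        """
        if not self.active:
            raise RecorderError("trial already stopped")
        self._flush()
        self.active = False
        if stop_time is None:
            # infer from rows actually seen at the engine rate
            stop_time = self.start_time + self.rows * self.downsample * self.period
        self.group.attrs["stop_time"] = float(stop_time)

        pgroup = self.group.create_group("Parameters")
        by_module: dict[str, dict[str, Any]] = {}
        for (module, name), value in self.parameters.items():
            by_module.setdefault(module, {})[name] = value
        changes_by_param: dict[tuple[str, str], list] = {}
        for t, module, name, value in self._changes:
            changes_by_param.setdefault((module, name), []).append((t, _encode(value)))
        for module in sorted(by_module):
            mgroup = pgroup.create_group(module)
            for name in sorted(by_module[module]):
                table = np.array(
                    changes_by_param.get((module, name), []), dtype=_CHANGE_DTYPE
                )
                ds = mgroup.create_dataset(name, data=table)
                ds.attrs["initial"] = _encode(by_module[module][name])

        sgroup = self.group.create_group("System Settings")
        for ch in self.channels:
            cg = sgroup.create_group(ch.name)
            cg.attrs["index"] = int(ch.index)
            cg.attrs["direction"] = ch.direction
            cg.attrs["mode"] = ch.mode
            cg.attrs["range_lo"] = float(ch.range[0])
            cg.attrs["range_hi"] = float(ch.range[1])
            cg.attrs["gain"] = float(ch.gain)
            cg.attrs["offset"] = float(ch.offset)
            cg.attrs["enabled"] = bool(ch.enabled)

        self.group.create_dataset(
            "Tags", data=np.array(self._tags, dtype=_TAG_DTYPE)
        )
        self.group.file.flush()
        return {
            "trial": self.trial,
            "rows": self.rows,
            "duration": float(stop_time) - self.start_time,
        }


def _encode(value) -> str:
    # repr round-trips floats exactly; strings pass through
    return repr(float(value)) if isinstance(value, (int, float)) else str(value)


def _decode(text: str):
    try:
        return float(text)
    except (TypeError, ValueError):
        return text


# ---------------------------------------------------------------------------
# Read-back
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    trial: int
    data: np.ndarray
    columns: list[str]
    period: float
    downsample: int
    start_time: float
    stop_time: float
    parameters: dict[tuple[str, str], Any] = field(default_factory=dict)
    changes: dict[tuple[str, str], list[tuple[float, Any]]] = field(default_factory=dict)
    channels: list[ChannelConfig] = field(default_factory=list)
    tags: list[tuple[float, str]] = field(default_factory=list)


def list_trials(path) -> list[int]:
    with h5py.File(path, "r") as f:
        return sorted(
            int(k.split(" ", 1)[1]) for k in f.keys() if k.startswith("Trial ")
        )


def read_trial(path, trial: int) -> TrialData:
    """Load one trial group back into memory (exact values, no conversion)."""
    with h5py.File(path, "r") as f:
        name = f"Trial {trial}"
        if name not in f:
            raise RecorderError(f"{path} has no {name}")
        g = f[name]
        ds = g["Synchronous Data"]
        columns = [c.decode() if isinstance(c, bytes) else str(c) for c in ds.attrs["columns"]]
        params: dict[tuple[str, str], Any] = {}
        changes: dict[tuple[str, str], list[tuple[float, Any]]] = {}
        if "Parameters" in g:
            for module in g["Parameters"]:
                for pname, pds in g["Parameters"][module].items():
                    key = (module, pname)
                    params[key] = _decode(_asstr(pds.attrs["initial"]))
                    rows = pds[()]
                    changes[key] = [
                        (float(r["time"]), _decode(_asstr(r["value"]))) for r in rows
                    ]
        channels = []
        if "System Settings" in g:
            for cname in g["System Settings"]:
                a = g["System Settings"][cname].attrs
                channels.append(
                    ChannelConfig(
                        index=int(a["index"]),
                        direction=_asstr(a["direction"]),
                        mode=_asstr(a["mode"]),
                        range=(float(a["range_lo"]), float(a["range_hi"])),
                        gain=float(a["gain"]),
                        offset=float(a["offset"]),
                        enabled=bool(a["enabled"]),
                    )
                )
        tags = []
        if "Tags" in g:
            tags = [(float(r["time"]), _asstr(r["text"])) for r in g["Tags"][()]]
        return TrialData(
            trial=trial,
            data=ds[()],
            columns=columns,
            period=float(g.attrs["period"]),
            downsample=int(g.attrs["downsample"]),
            start_time=float(g.attrs["start_time"]),
            stop_time=float(g.attrs["stop_time"]),
            parameters=params,
            changes=changes,
            channels=channels,
            tags=tags,
        )


def _asstr(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def export_trace(path, trial: int, signals: Sequence[str] | None = None,
                 csv_path=None, png_path=None) -> np.ndarray:
    """Offline rendering of recorded columns to CSV and/or PNG — the
    non-interactive stand-in for a live oscilloscope view."""
    td = read_trial(path, trial)
    if signals is None:
        signals = td.columns
    missing = [s for s in signals if s not in td.columns]
    if missing:
        raise ValidationError(f"signals not in trial {trial}: {missing}")
    idx = [td.columns.index(s) for s in signals]
    t = td.start_time + np.arange(len(td.data)) * td.downsample * td.period
    table = np.column_stack([t] + [td.data[:, i] for i in idx])
    if csv_path:
        header = ",".join(["time"] + list(signals))
        np.savetxt(csv_path, table, delimiter=",", header=header, comments="")
    if png_path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        for s, i in zip(signals, idx):
            ax.plot(t, td.data[:, i], label=s, lw=0.8)
        ax.set_xlabel("time (s)")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return table
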