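"""Engine-module wrapper around the streaming syllable detector, so the
auditory-feedback pipeline can run inside a workspace like any other block.

The template (and optional feedback waveform) are loaded from one-column
ASCII files; the detector itself is built lazily at the first execute (and
rebuilt on a PERIOD change) because its window lengths depend on the engine
rate.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from .base import LifecycleState, Module, register_module


@register_module
class DAFModule(Module):
    """Input ``audio`` (volts); outputs ``detect`` (5 V on the detection
    cycle) and ``feedback`` (playback samples)."""

    type_name = "daf_detector"
    INPUTS = ("audio",)
    OUTPUTS = ("detect", "feedback")
    PARAMS = {
        "template_path": "",
        "feedback_path": "",
        "rms_threshold": 0.02,
        "corr_threshold": 0.7,
        "rms_window": 0.010,
        "rms_eval_rate": 1000.0,
        "spec_window": 0.020,
        "stft_window": 128.0,
        "stft_hop": 64.0,
        "band_lo": 500.0,
        "band_hi": 10000.0,
        "refractory": -1.0,  # <0 -> default (feedback duration)
    }
    STATES = ("detection_count",)

    def update(self, state, event=None):
        if state == LifecycleState.INIT:
            self.detection_count = 0.0
        if state in (LifecycleState.INIT, LifecycleState.MODIFY, LifecycleState.PERIOD):
            self._detector = None  # rebuilt at next execute with the live rate

    def _build(self, rate: float):
        from ..daf import DAFConfig, DAFDetector, template_from_clip

        if not self.params["template_path"]:
            raise ValidationError(f"module {self.id!r}: template_path is required")
        clip = np.loadtxt(self.params["template_path"], ndmin=1)
        refractory = self.params["refractory"]
        config = DAFConfig(
            rate=rate,
            rms_window=self.params["rms_window"],
            rms_eval_rate=self.params["rms_eval_rate"],
            rms_threshold=self.params["rms_threshold"],
            spec_window=self.params["spec_window"],
            stft_window=int(self.params["stft_window"]),
            stft_hop=int(self.params["stft_hop"]),
            band=(self.params["band_lo"], self.params["band_hi"]),
            corr_threshold=self.params["corr_threshold"],
            refractory=None if refractory < 0 else refractory,
        )
        feedback = None
        if self.params["feedback_path"]:
            feedback = np.loadtxt(self.params["feedback_path"], ndmin=1)
        self._detector = DAFDetector(config, template_from_clip(clip, config), feedback)

    def execute(self, t, dt, inputs):
        if self._detector is None:
            self._build(1.0 / dt)
        detected, fb = self._detector.step(inputs["audio"])
        if detected:
            self.detection_count += 1.0
        return {"detect": 5.0 if detected else 0.0, "feedback": fb}
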