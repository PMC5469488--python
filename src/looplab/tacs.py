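"""EEG alpha-power feedback control of alternating-current stimulation.

The pipeline: incoming EEG (2 kHz) is filtered with a causal 6th-order
Butterworth band-pass at 8–12 Hz to isolate the alpha band; alpha power is
the mean squared filtered sample over a 1 s window.  A two-phase
calibration — 60 s eyes open (EO), 60 s eyes closed (EC), one power value
per second each — yields the stimulation threshold

    θ = 1.05 × (mean(P_EO) + mean(P_EC)) / 2.

After calibration the controller assesses the trailing 1 s of alpha power
at 0.25 Hz (every 4 s epoch boundary); if the power strictly exceeds θ, a
40 Hz sinusoidal stimulation command is emitted for the first 2 s of the
*next* epoch, otherwise stimulation stays off.  A dose-matched random arm
delivers the same number of stimulation epochs at seeded-random epoch
positions, independent of the measured power.

Everything is causal: no output sample depends on future input (an offline
zero-phase filter would not reproduce this contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfilt, sosfilt_zi

from .errors import ValidationError

__all__ = [
    "AlphaConfig",
    "design_alpha_filter",
    "AlphaFilter",
    "alpha_power",
    "calibrate",
    "AlphaController",
    "SessionResult",
    "session",
]


@dataclass
class AlphaConfig:
    rate: float = 2_000.0           # EEG sampling rate, Hz
    order: int = 6                  # Butterworth band-pass order
    band: tuple[float, float] = (8.0, 12.0)
    power_window: float = 1.0       # s entering each mean-power estimate
    decision_rate: float = 0.25     # Hz -> 4 s epochs
    threshold_factor: float = 1.05
    stim_frequency: float = 40.0    # Hz
    stim_duration: float = 2.0      # s at the start of a gated epoch
    stim_amplitude: float = 1.0     # command volts
    calib_phase: float = 60.0       # s per calibration phase (EO, then EC)
    hilbert_power: bool = False     # mean envelope²/2 instead of mean square

    def __post_init__(self):
        lo, hi = self.band
        if not (0.0 < lo < hi < self.rate / 2.0):
            raise ValidationError(f"band {self.band} outside (0, rate/2)")
        if self.power_window > self.epoch_length:
            raise ValidationError("power window cannot exceed the epoch length")
        if self.order < 2 or self.order % 2:
            raise ValidationError("filter order must be a positive even integer")
        if self.stim_duration > self.epoch_length:
            raise ValidationError("stim duration cannot exceed the epoch length")

    @property
    def epoch_length(self) -> float:
        return 1.0 / self.decision_rate

    @property
    def window_samples(self) -> int:
        return int(round(self.power_window * self.rate))


def design_alpha_filter(config: AlphaConfig) -> np.ndarray:
    """Second-order-section coefficients for the causal band-pass.

    A 6th-order band-pass comes from a 3rd-order Butterworth prototype.
    Raises at configuration time if the design is unstable at this rate.
    """
    sos = butter(
        config.order // 2, config.band, btype="bandpass", fs=config.rate, output="sos"
    )
    # poles of each biquad must be inside the unit circle
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValidationError(
                f"unstable band-pass design for band {config.band} at {config.rate} Hz"
            )
    return sos


class AlphaFilter:
    """Streaming (single-sample or chunked) stateful IIR band-pass.

    Chunked processing is exactly sample-for-sample identical to feeding one
    sample at a time: the second-order sections carry their internal state
    across calls.
    """

    def __init__(self, config: AlphaConfig):
        self.sos = design_alpha_filter(config)
        self.zi = np.zeros_like(sosfilt_zi(self.sos))

    def process(self, samples) -> np.ndarray:
        samples = np.atleast_1d(np.asarray(samples, dtype=float))
        out, self.zi = sosfilt(self.sos, samples, zi=self.zi)
        return out


def alpha_power(window, hilbert_power: bool = False) -> float:
    """Mean oscillation power (V²) of a filtered window.

    Default reading: the mean of the squared filtered samples.  The Hilbert
    variant uses mean(envelope²)/2, which agrees for a narrow-band signal.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 1:
        raise ValidationError("empty power window")
    if hilbert_power:
        return float(np.mean(np.abs(hilbert(window)) ** 2) / 2.0)
    return float(np.mean(window ** 2))


def calibrate(p_eo, p_ec, factor: float = 1.05) -> float:
    """Stimulation threshold from the two calibration power series:
    θ = factor × (mean(P_EO) + mean(P_EC)) / 2."""
    p_eo = np.asarray(p_eo, dtype=float)
    p_ec = np.asarray(p_ec, dtype=float)
    if p_eo.size == 0 or p_ec.size == 0:
        raise ValidationError("both calibration series must be non-empty")
    return float(factor * (p_eo.mean() + p_ec.mean()) / 2.0)


class AlphaController:
    """Streaming controller: calibration phases then threshold-gated epochs.

    Call :meth:`step` once per EEG sample; it returns the stimulation
    command sample.  Phase layout on the sample clock: [0, calib) is EO
    calibration, [calib, 2·calib) EC calibration, then 1/decision_rate
    epochs.  At each epoch boundary the trailing ``power_window`` of
    filtered EEG is assessed against θ (strict >) to gate the *next*
    epoch's first ``stim_duration`` seconds.
    """

    def __init__(self, config: AlphaConfig):
        self.config = config
        self.filter = AlphaFilter(config)
        nwin = config.window_samples
        self._ring = np.zeros(nwin)
        self._n = 0
        self.p_eo: list[float] = []
        self.p_ec: list[float] = []
        self.theta: float | None = None
        self.epoch_powers: list[float] = []
        self.stim_on_epochs: list[bool] = []
        self._stim_until = -1.0
        self._epoch_start = None

    # phase boundaries in samples
    @property
    def _calib_samples(self) -> int:
        return int(round(self.config.calib_phase * self.config.rate))

    def _trailing_power(self) -> float:
        cfg = self.config
        nwin = cfg.window_samples
        idx = np.arange(self._n - nwin, self._n) % nwin
        return alpha_power(self._ring[idx], cfg.hilbert_power)

    def step(self, sample: float) -> float:
        cfg = self.config
        cal = self._calib_samples
        epoch_samples = int(round(cfg.epoch_length * cfg.rate))
        n0 = self._n  # samples seen so far; the incoming sample has index n0

        # Epoch gating happens on the boundary, over the window that *ends*
        # there — before the incoming sample is seen.
        if n0 >= 2 * cal and (n0 - 2 * cal) % epoch_samples == 0:
            if self.theta is None:
                raise ValidationError("run phase entered before calibration completed")
            power = self._trailing_power()
            stim_on = power > self.theta  # strict: power == θ leaves stim off
            self.epoch_powers.append(power)
            self.stim_on_epochs.append(bool(stim_on))
            self._epoch_start = n0 / cfg.rate
            self._stim_until = (
                self._epoch_start + cfg.stim_duration if stim_on else -1.0
            )

        filtered = float(self.filter.process(sample)[0])
        self._ring[n0 % cfg.window_samples] = filtered
        self._n = n = n0 + 1

        sec = int(round(cfg.rate))  # one power value per second in calibration
        if n <= cal:
            if n % sec == 0 and n >= cfg.window_samples:
                self.p_eo.append(self._trailing_power())
            return 0.0
        if n <= 2 * cal:
            if n % sec == 0:
                self.p_ec.append(self._trailing_power())
            if n == 2 * cal:
                self.theta = calibrate(self.p_eo, self.p_ec, cfg.threshold_factor)
            return 0.0

        t_sample = n0 / cfg.rate  # time of the sample just processed
        if self._epoch_start is not None and t_sample < self._stim_until:
            return float(
                cfg.stim_amplitude
                * np.sin(2.0 * np.pi * cfg.stim_frequency * (t_sample - self._epoch_start))
            )
        return 0.0


@dataclass
class SessionResult:
    """Products of one recording session."""

    mode: str
    theta: float
    p_eo: np.ndarray
    p_ec: np.ndarray
    epoch_starts: np.ndarray          # s, absolute
    epoch_powers: np.ndarray          # trailing power at each boundary
    feedback_stim_on: np.ndarray      # bool, what the controller decided
    stim_on: np.ndarray               # bool, what was actually delivered
    stim: np.ndarray                  # command waveform aligned with the EEG
    filtered: np.ndarray              # alpha-filtered EEG

    @property
    def n_stim_epochs(self) -> int:
        return int(np.sum(self.stim_on))


def session(
    eeg,
    config: AlphaConfig | None = None,
    mode: str = "feedback",
    seed: int = 0,
    recorder_path=None,
    downsample: int = 8,
) -> SessionResult:
    """Process a full recording session from a raw EEG trace.

    The trace must cover both calibration phases plus at least one epoch.
    ``mode="feedback"`` delivers threshold-gated stimulation;
    ``mode="dose_matched_random"`` delivers the same *number* of
    stimulation epochs at seeded-random positions.  Processing is chunk-
    vectorized but sample-for-sample identical to the streaming controller.
    Pass ``recorder_path`` to store (eeg, alpha, stim) into a standard
    recorder HDF5 file.
    """
    cfg = config or AlphaConfig()
    if mode not in ("feedback", "dose_matched_random"):
        raise ValidationError(f"unknown session mode {mode!r}")
    eeg = np.asarray(eeg, dtype=float)
    rate = cfg.rate
    cal = int(round(cfg.calib_phase * rate))
    epoch_samples = int(round(cfg.epoch_length * rate))
    nwin = cfg.window_samples
    if len(eeg) < 2 * cal + epoch_samples:
        raise ValidationError(
            "EEG source shorter than calibration plus one epoch "
            f"({(2 * cal + epoch_samples) / rate:.0f} s needed, "
            f"{len(eeg) / rate:.0f} s given)"
        )

    filt = AlphaFilter(cfg)
    filtered = filt.process(eeg)
    sq = filtered ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])

    def trailing_power_at(n_end: int) -> float:
        if cfg.hilbert_power:
            return alpha_power(filtered[n_end - nwin:n_end], True)
        return float((csum[n_end] - csum[n_end - nwin]) / nwin)

    sec = int(round(rate))
    p_eo = np.array([trailing_power_at(k * sec) for k in range(1, int(cfg.calib_phase) + 1)
                     if k * sec >= nwin])
    p_ec = np.array([trailing_power_at(cal + k * sec)
                     for k in range(1, int(cfg.calib_phase) + 1)])
    theta = calibrate(p_eo, p_ec, cfg.threshold_factor)

    n_epochs = (len(eeg) - 2 * cal) // epoch_samples
    boundaries = 2 * cal + epoch_samples * np.arange(n_epochs)
    epoch_powers = np.array([trailing_power_at(b) for b in boundaries])
    feedback_on = epoch_powers > theta

    if mode == "feedback":
        stim_on = feedback_on.copy()
    else:
        rng = np.random.default_rng(seed)
        n_stim = int(feedback_on.sum())
        chosen = rng.choice(n_epochs, size=n_stim, replace=False)
        stim_on = np.zeros(n_epochs, dtype=bool)
        stim_on[np.sort(chosen)] = True

    stim = np.zeros(len(eeg))
    nstim = int(round(cfg.stim_duration * rate))
    for e in np.nonzero(stim_on)[0]:
        b = boundaries[e]
        tt = np.arange(nstim) / rate
        stim[b:b + nstim] = cfg.stim_amplitude * np.sin(
            2.0 * np.pi * cfg.stim_frequency * tt
        )

    result = SessionResult(
        mode=mode,
        theta=theta,
        p_eo=p_eo,
        p_ec=p_ec,
        epoch_starts=boundaries / rate,
        epoch_powers=epoch_powers,
        feedback_stim_on=feedback_on,
        stim_on=stim_on,
        stim=stim,
        filtered=filtered,
    )

    if recorder_path is not None:
        from .recorder import Recorder

        with Recorder(recorder_path, mode="overwrite") as rec:
            handle = rec.start_trial(
                signals=["eeg", "alpha", "stim"],
                period=1.0 / rate,
                downsample=downsample,
                parameters={
                    ("tacs", "theta"): theta,
                    ("tacs", "threshold_factor"): cfg.threshold_factor,
                    ("tacs", "stim_frequency"): cfg.stim_frequency,
                    ("tacs", "stim_amplitude"): cfg.stim_amplitude,
                },
            )
            handle.record_chunk(0, np.column_stack([eeg, filtered, stim]))
            for e, b in enumerate(boundaries):
                if stim_on[e]:
                    handle.add_tag(b / rate, f"stim epoch {e}")
            handle.stop(stop_time=len(eeg) / rate)
    return result
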