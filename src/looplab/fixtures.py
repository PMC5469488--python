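"""Synthetic signal generators standing in for hardware inputs.

Three families, all pure functions of (spec, seed):

* randomly timed square trigger trains for the characterization cases
  (5 Vpp pulses, by default 1800 events over 30 minutes);
* synthetic birdsong — sequences of spectrally distinct syllables
  (harmonic stacks and frequency sweeps, 20–80 ms) separated by jittered
  silent gaps, with ground-truth onset/offset/label tables;
* synthetic EEG — 1/f (pink) background noise plus a 10 Hz alpha
  oscillation whose amplitude follows an eyes-open/eyes-closed schedule.

The generated ground truth is sufficient to score every downstream
pipeline without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "PulseTrainSpec",
    "make_pulse_train",
    "SyllableSpec",
    "SyntheticSongSpec",
    "make_song",
    "render_syllable",
    "SyntheticEEGSpec",
    "make_eeg",
]


# ---------------------------------------------------------------------------
# Trigger trains
# ---------------------------------------------------------------------------


@dataclass
class PulseTrainSpec:
    """Randomly triggered square pulses (50% duty at the nominal 1 Hz event
    rate ⇒ 0.5 s pulse width), 5 Vpp."""

    duration: float = 1800.0
    n_events: int = 1800
    pulse_width: float = 0.5
    amplitude: float = 5.0
    min_gap: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 0 or self.duration <= 0:
            raise ValidationError("need duration > 0 and n_events >= 0")
        if self.n_events * (self.pulse_width + self.min_gap) > self.duration:
            raise ValidationError(
                f"cannot pack {self.n_events} pulses of {self.pulse_width}s "
                f"with {self.min_gap}s gaps into {self.duration}s"
            )


def make_pulse_train(spec: PulseTrainSpec):
    """Seeded random trigger train.

    Returns ``(signal, event_times)`` where ``signal`` is a vectorized
    function of time (volts) and ``event_times`` are the rising edges.
    Pulse start times are drawn by spreading the spare time uniformly at
    random between the minimally spaced pulses, so exactly ``n_events``
    pulses honor the minimum gap.
    """
    if spec.n_events == 0:
        return (lambda t: np.zeros_like(np.asarray(t, dtype=float))), np.empty(0)
    rng = np.random.default_rng(spec.seed)
    pitch = spec.pulse_width + spec.min_gap
    slack = spec.duration - spec.n_events * pitch
    offsets = np.sort(rng.uniform(0.0, slack, size=spec.n_events))
    starts = offsets + pitch * np.arange(spec.n_events)
    width = spec.pulse_width
    amp = spec.amplitude

    def signal(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = (idx >= 0) & (t < starts[np.clip(idx, 0, None)] + width)
        return np.where(inside, amp, 0.0)[()]

    return signal, starts


# ---------------------------------------------------------------------------
# Synthetic birdsong
# ---------------------------------------------------------------------------


@dataclass
class SyllableSpec:
    """One syllable signature: a harmonic stack (f0 plus harmonics) or a
    linear frequency sweep, Hann-enveloped.  Durations 20–80 ms."""

    kind: str = "harmonic"  # harmonic | sweep
    f0: float = 800.0
    f1: float = 0.0  # sweep end frequency (sweep kind only)
    n_harmonics: int = 4
    duration: float = 0.05
    amplitude: float = 0.5

    def __post_init__(self):
        if self.kind not in ("harmonic", "sweep"):
            raise ValidationError(f"unknown syllable kind {self.kind!r}")
        if not 0.005 <= self.duration <= 0.5:
            raise ValidationError("syllable duration out of range")


def render_syllable(syl: SyllableSpec, rate: float) -> np.ndarray:
    n = int(round(syl.duration * rate))
    t = np.arange(n) / rate
    if syl.kind == "harmonic":
        x = np.zeros(n)
        for k in range(1, syl.n_harmonics + 1):
            x += np.sin(2.0 * np.pi * k * syl.f0 * t) / k
    else:
        f1 = syl.f1 if syl.f1 > 0 else 2.0 * syl.f0
        sweep_rate = (f1 - syl.f0) / syl.duration
        phase = 2.0 * np.pi * (syl.f0 * t + 0.5 * sweep_rate * t ** 2)
        x = np.sin(phase)
    env = np.hanning(n)
    x = x * env
    peak = np.abs(x).max()
    return syl.amplitude * x / peak if peak > 0 else x


def _default_inventory() -> list[SyllableSpec]:
    return [
        SyllableSpec("harmonic", f0=800.0, n_harmonics=4, duration=0.050),
        SyllableSpec("harmonic", f0=1700.0, n_harmonics=3, duration=0.040),
        SyllableSpec("sweep", f0=2000.0, f1=4500.0, duration=0.060),
    ]


@dataclass
class SyntheticSongSpec:
    """A song: ``n_motifs`` repetitions of a syllable sequence with jittered
    inter-syllable gaps over a (possibly zero) noise floor."""

    rate: float = 30_000.0
    syllables: list[SyllableSpec] = field(default_factory=_default_inventory)
    sequence: tuple[int, ...] = (0, 1, 2)
    n_motifs: int = 10
    gap_mean: float = 0.08
    gap_jitter: float = 0.01
    lead_in: float = 0.2
    noise_floor: float = 0.0
    target: int = 0  # index (into syllables) of the target syllable
    seed: int = 0

    def __post_init__(self):
        if any(i >= len(self.syllables) for i in self.sequence):
            raise ValidationError("sequence indexes beyond the syllable inventory")
        if self.target >= len(self.syllables):
            raise ValidationError("target indexes beyond the syllable inventory")


def make_song(spec: SyntheticSongSpec):
    """Seeded synthetic song with ground truth.

    Returns ``(waveform, events)`` where events is a list of dicts with
    keys onset, offset (s), label (syllable index), is_target.  Gaps are
    gap_mean ± Gaussian jitter, floored at 10 ms so syllables never overlap.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    rendered = [render_syllable(s, rate) for s in spec.syllables]
    pieces = []
    events = []
    cursor = int(round(spec.lead_in * rate))
    pieces.append(np.zeros(cursor))
    for _ in range(spec.n_motifs):
        for si in spec.sequence:
            syl = rendered[si]
            events.append(
                {
                    "onset": cursor / rate,
                    "offset": (cursor + len(syl)) / rate,
                    "label": si,
                    "is_target": si == spec.target,
                }
            )
            pieces.append(syl)
            cursor += len(syl)
            gap = max(0.010, spec.gap_mean + spec.gap_jitter * rng.standard_normal())
            ngap = int(round(gap * rate))
            pieces.append(np.zeros(ngap))
            cursor += ngap
    wave = np.concatenate(pieces)
    if spec.noise_floor > 0:
        wave = wave + spec.noise_floor * rng.standard_normal(len(wave))
    return wave, events


# ---------------------------------------------------------------------------
# Synthetic EEG
# ---------------------------------------------------------------------------


@dataclass
class SyntheticEEGSpec:
    """Pink-noise background plus a 10 Hz alpha oscillation whose amplitude
    follows the eye-state schedule.

    ``schedule`` is a list of (state, duration_s) pairs; state "EO" uses
    ``eo_alpha``, "EC" uses ``ec_alpha``.  When None, a standard session is
    built: 60 s EO + 60 s EC calibration, then ``protocol`` segments
    ("EOEC" alternates every 30 s, "EO" stays open) up to ``duration``.
    """

    rate: float = 2_000.0
    duration: float = 720.0
    background: float = 0.5       # pink-noise SD, volts
    alpha_freq: float = 10.0
    eo_alpha: float = 0.5         # alpha amplitude, eyes open
    ec_alpha: float = 2.0         # alpha amplitude, eyes closed
    protocol: str = "EOEC"
    segment: float = 30.0         # EOEC alternation period, s
    calib_phase: float = 60.0
    schedule: list[tuple[str, float]] | None = None
    stim_artifact: float = 0.0    # 40 Hz leak amplitude when stim marked on
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("EO", "EOEC"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if min(self.eo_alpha, self.ec_alpha, self.background) < 0:
            raise ValidationError("amplitudes must be non-negative")


def _pink_noise(n: int, rng) -> np.ndarray:
    """1/f-power noise by spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** -0.5  # amplitude ∝ f^-1/2 ⇒ power ∝ 1/f
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def build_schedule(spec: SyntheticEEGSpec) -> list[tuple[str, float]]:
    if spec.schedule is not None:
        total = sum(d for _, d in spec.schedule)
        if abs(total - spec.duration) > 1e-9:
            raise ValidationError(
                f"schedule covers {total}s but duration is {spec.duration}s"
            )
        return list(spec.schedule)
    sched = [("EO", spec.calib_phase), ("EC", spec.calib_phase)]
    remaining = spec.duration - 2 * spec.calib_phase
    if remaining < 0:
        raise ValidationError("duration shorter than the calibration phases")
    state = "EO"
    while remaining > 1e-9:
        d = min(spec.segment, remaining) if spec.protocol == "EOEC" else remaining
        sched.append((state, d))
        remaining -= d
        if spec.protocol == "EOEC":
            state = "EC" if state == "EO" else "EO"
    return sched


def make_eeg(spec: SyntheticEEGSpec):
    """Seeded synthetic EEG.

    Returns ``(trace, segments)``; segments is a list of dicts with keys
    start, duration, state, alpha_amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    sched = build_schedule(spec)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    amp = np.zeros(n)
    segments = []
    start = 0.0
    for state, dur in sched:
        i0 = int(round(start * spec.rate))
        i1 = int(round((start + dur) * spec.rate))
        a = spec.eo_alpha if state == "EO" else spec.ec_alpha
        amp[i0:i1] = a
        segments.append(
            {"start": start, "duration": dur, "state": state, "alpha_amplitude": a}
        )
        start += dur
    trace = amp * np.sin(2.0 * np.pi * spec.alpha_freq * t)
    if spec.background > 0:
        trace = trace + spec.background * _pink_noise(n, rng)
    return trace, segments
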