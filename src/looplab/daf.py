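"""Template-matching auditory feedback pipeline.

Implements the two-mode online syllable detector used for distorted
auditory feedback (DAF) experiments: in *idle* mode the detector only
tracks the root-mean-square of the last 10 ms of audio, re-evaluated at
1 kHz; when the RMS exceeds a threshold (sound present) it switches to
*triggered* mode, where at every evaluation instant it computes the
spectrogram of the most recent 20 ms of signal and its Pearson correlation
with a template spectrogram (e.g. of a song syllable).  A correlation above
threshold is a detection and starts playback of a feedback waveform; the
detector drops back to idle when the RMS falls below threshold.

The STFT settings (Hann window of 128 samples, hop 64, 500–10 000 Hz band
at a 30 kHz rate) are exposed in :class:`DAFConfig`; they are this
package's defaults, chosen to resolve harmonic stacks of song-like
syllables at the stated window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .errors import ValidationError

__all__ = [
    "DAFConfig",
    "rms",
    "spectrogram_20ms",
    "template_corr",
    "template_from_clip",
    "DAFDetector",
    "detect_stream",
    "score_detections",
    "read_wav",
    "write_wav",
]


@dataclass
class DAFConfig:
    rate: float = 30_000.0           # audio/system rate, Hz
    rms_window: float = 0.010        # s of trailing audio entering the RMS
    rms_eval_rate: float = 1_000.0   # RMS (and correlation) cadence, Hz
    rms_threshold: float = 0.02      # volts
    spec_window: float = 0.020       # s of trailing audio entering the spectrogram
    stft_window: int = 128           # samples
    stft_hop: int = 64               # samples
    band: tuple[float, float] = (500.0, 10_000.0)
    corr_threshold: float = 0.7
    refractory: float | None = None  # s; None -> feedback duration (or 0.1 s)
    mute_during_playback: bool = False

    def __post_init__(self):
        if self.rms_window * self.rate < 1:
            raise ValidationError("RMS window must span at least one sample")
        if not (0.0 < self.corr_threshold < 1.0):
            raise ValidationError("correlation threshold must be in (0, 1)")
        lo, hi = self.band
        if not (0.0 <= lo < hi <= self.rate / 2.0):
            raise ValidationError(f"band {self.band} outside (0, rate/2)")
        ratio = self.rate / self.rms_eval_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("rate must be an integer multiple of the RMS eval rate")

    @property
    def eval_interval(self) -> int:
        """Samples between successive evaluation instants."""
        return int(round(self.rate / self.rms_eval_rate))

    @property
    def rms_samples(self) -> int:
        return int(round(self.rms_window * self.rate))

    @property
    def spec_samples(self) -> int:
        return int(round(self.spec_window * self.rate))


def rms(segment) -> float:
    """Root mean square of a buffer segment: sqrt(mean(x^2))."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 1:
        raise ValidationError("empty RMS segment")
    return float(np.sqrt(np.mean(segment ** 2)))


def _band_rows(config: DAFConfig) -> np.ndarray:
    freqs = np.fft.rfftfreq(config.stft_window, 1.0 / config.rate)
    lo, hi = config.band
    return np.nonzero((freqs >= lo) & (freqs <= hi))[0]


def spectrogram_20ms(segment, config: DAFConfig) -> np.ndarray:
    """STFT magnitude of one analysis window of audio.

    ``segment`` must be exactly ``config.spec_samples`` long.  Frames of
    ``stft_window`` samples advance by ``stft_hop``; each is Hann-windowed
    and the magnitude rows are restricted to the analysis band.  Returns a
    (frequency bins × frames) matrix.
    """
    segment = np.asarray(segment, dtype=float)
    n = config.spec_samples
    if len(segment) != n:
        raise ValidationError(f"segment must be {n} samples, got {len(segment)}")
    win = config.stft_window
    hop = config.stft_hop
    n_frames = 1 + (n - win) // hop
    if n_frames < 1:
        raise ValidationError("analysis window shorter than one STFT frame")
    taper = get_window("hann", win, fftbins=True)
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = segment[idx] * taper
    mag = np.abs(np.fft.rfft(frames, axis=1))  # (frames, bins)
    return mag[:, _band_rows(config)].T  # (bins, frames)


def template_corr(spec: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation between two spectrograms of identical shape.

    A zero-variance operand (e.g. silence) is defined to correlate at 0 —
    silence can never match a template.
    """
    spec = np.asarray(spec, dtype=float)
    template = np.asarray(template, dtype=float)
    if spec.shape != template.shape:
        raise ValidationError(
            f"shape mismatch: {spec.shape} vs template {template.shape}"
        )
    a = spec.ravel() - spec.mean()
    b = template.ravel() - template.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return 0.0
    return float(np.dot(a, b) / denom)


def template_from_clip(clip, config: DAFConfig, align: str = "end") -> np.ndarray:
    """Template spectrogram from a sound clip.

    The clip is reduced to one analysis window (20 ms by default): with
    ``align="end"`` the last ``spec_samples`` are used (detection then fires
    as the syllable completes); shorter clips are zero-padded at the front.
    """
    clip = np.asarray(clip, dtype=float)
    n = config.spec_samples
    if align not in ("start", "end"):
        raise ValidationError("align must be 'start' or 'end'")
    if len(clip) >= n:
        seg = clip[:n] if align == "start" else clip[-n:]
    else:
        pad = np.zeros(n - len(clip))
        seg = np.concatenate([clip, pad] if align == "start" else [pad, clip])
    tmpl = spectrogram_20ms(seg, config)
    if not np.isfinite(tmpl).all() or tmpl.shape[0] < 1:
        raise ValidationError("template spectrogram is degenerate")
    return tmpl


class DAFDetector:
    """Streaming idle/triggered detector over a circular buffer.

    Feed one sample at a time with :meth:`step`; each call returns
    ``(detected, feedback_sample)``.  Evaluation (RMS in idle mode, RMS +
    spectrogram correlation in triggered mode) happens only at the
    evaluation instants (every ``eval_interval`` samples).
    """

    def __init__(self, config: DAFConfig, template: np.ndarray,
                 feedback: np.ndarray | None = None):
        self.config = config
        self.template = np.asarray(template, dtype=float)
        self.feedback = (
            np.asarray(feedback, dtype=float) if feedback is not None else None
        )
        if config.refractory is not None:
            self.refractory = config.refractory
        elif self.feedback is not None and len(self.feedback):
            self.refractory = len(self.feedback) / config.rate
        else:
            self.refractory = 0.1
        self._buflen = max(config.spec_samples, config.rms_samples)
        self._buf = np.zeros(self._buflen)
        self._n = 0
        self.mode = "idle"
        self._last_detection = -np.inf
        self._fb_cursor = -1
        self.detections: list[float] = []
        # sanity: template shape must match live spectrograms
        probe = spectrogram_20ms(np.zeros(config.spec_samples), config)
        if probe.shape != self.template.shape:
            raise ValidationError(
                f"template shape {self.template.shape} does not match "
                f"STFT settings (expected {probe.shape})"
            )

    @property
    def playing(self) -> bool:
        return self._fb_cursor >= 0

    def _tail(self, n: int) -> np.ndarray:
        idx = np.arange(self._n - n, self._n) % self._buflen
        return self._buf[idx]

    def step(self, sample: float) -> tuple[bool, float]:
        cfg = self.config
        self._buf[self._n % self._buflen] = sample
        self._n += 1
        detected = False
        if self._n % cfg.eval_interval == 0 and self._n >= cfg.rms_samples:
            t = self._n / cfg.rate
            level = rms(self._tail(cfg.rms_samples))
            if self.mode == "idle":
                if level > cfg.rms_threshold:
                    self.mode = "triggered"
            else:
                muted = cfg.mute_during_playback and self.playing
                if not muted and self._n >= cfg.spec_samples:
                    spec = spectrogram_20ms(self._tail(cfg.spec_samples), cfg)
                    r = template_corr(spec, self.template)
                    if r > cfg.corr_threshold and t - self._last_detection >= self.refractory:
                        detected = True
                        self._last_detection = t
                        self.detections.append(t)
                        if self.feedback is not None and len(self.feedback):
                            self._fb_cursor = 0
                if level < cfg.rms_threshold and not self.playing:
                    self.mode = "idle"
        fb = 0.0
        if self.playing:
            fb = float(self.feedback[self._fb_cursor])
            self._fb_cursor += 1
            if self._fb_cursor >= len(self.feedback):
                self._fb_cursor = -1
        return detected, fb


def detect_stream(x, config: DAFConfig, template, feedback=None):
    """Run the streaming detector over a full recording.

    Returns (detection times array, feedback output array aligned with x).
    """
    det = DAFDetector(config, template, feedback)
    x = np.asarray(x, dtype=float)
    fb_out = np.zeros(len(x))
    step = det.step
    for i in range(len(x)):
        _, fb_out[i] = step(x[i])
    return np.asarray(det.detections), fb_out


def score_detections(detections, truth, tolerance: float):
    """Greedy one-to-one matching of detections to ground-truth times.

    Returns (hit_rate, false_positives, matches) where matches is a list of
    (truth_time, detection_time) pairs.  Truth events are visited in time
    order and each claims the earliest unused detection within tolerance.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    detections = sorted(float(d) for d in np.atleast_1d(detections))
    truth = sorted(float(g) for g in np.atleast_1d(truth))
    used = [False] * len(detections)
    matches = []
    j = 0
    for g in truth:
        while j < len(detections) and detections[j] < g - tolerance:
            j += 1
        for k in range(j, len(detections)):
            if detections[k] > g + tolerance:
                break
            if not used[k]:
                used[k] = True
                matches.append((g, detections[k]))
                break
    hit_rate = len(matches) / len(truth) if truth else 0.0
    fp = used.count(False)
    return hit_rate, fp, matches


# ---------------------------------------------------------------------------
# WAV I/O (16-bit PCM <-> float in [-1, 1])
# ---------------------------------------------------------------------------


def read_wav(path) -> tuple[float, np.ndarray]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    else:
        data = data.astype(float)
    return float(rate), data


def write_wav(path, rate: float, data) -> None:
    from scipy.io import wavfile

    data = np.clip(np.asarray(data, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(round(rate)), (data * 32767).astype(np.int16))
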