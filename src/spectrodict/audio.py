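"""Audio front-end: WAV loading, mel spectrograms and MFCC+delta sequences.

The front-end is deliberately fixed and simple: non-overlapping
1024-sample Hamming-windowed STFT frames at 44.1 kHz, mapped through a
40-band Slaney-style triangular mel filterbank spanning 500 Hz to
Nyquist, with the whole spectrogram scaled to unit RMS.  The 500 Hz
cutoff discards most low-frequency environmental noise at the cost of
any vocalisation energy below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft
from scipy.io import wavfile
from scipy.signal import resample_poly

from .exceptions import (
    AudioDecodeError,
    DegenerateInputError,
    EmptyAudioError,
    TooShortError,
)

__all__ = [
    "AudioClip",
    "MelSpectrogram",
    "MfccSequence",
    "FrontEndConfig",
    "load_audio",
    "mel_filterbank",
    "compute_mel_spectrogram",
    "compute_mfcc",
]


@dataclass
class FrontEndConfig:
    """Fixed spectral front-end parameters.

    ``log_mel`` controls whether the mel matrix is log-compressed before
    feature learning; the MFCC path always log-compresses internally.
    """

    sample_rate: int = 44100
    frame_size: int = 1024
    window: str = "hamming"
    overlap: int = 0
    n_mels: int = 40
    fmin_hz: float = 500.0
    log_mel: bool = False


@dataclass
class AudioClip:
    samples: np.ndarray  # mono, float64, amplitude
    sample_rate: int
    source_id: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class MelSpectrogram:
    """Frame (time) x band (mel frequency) magnitude matrix."""

    values: np.ndarray
    frame_duration_s: float
    band_centres_hz: np.ndarray = field(repr=False)
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


@dataclass
class MfccSequence:
    """Frame x coefficient matrix: 13 cepstra followed by their deltas."""

    values: np.ndarray
    frame_duration_s: float
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def load_audio(path, target_rate: int = 44100, source_id: str | None = None) -> AudioClip:
    """Load a WAV file as a mono clip at ``target_rate`` Hz.

    Multi-channel audio is downmixed by averaging; sample-rate conversion
    uses polyphase resampling.  A clip already at the target rate is
    returned bit-identical.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wavfile raises assorted types
        raise AudioDecodeError(f"cannot decode audio file {path!s}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"audio file {path!s} contains no samples")

    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)

    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    return AudioClip(samples=samples, sample_rate=int(target_rate),
                     source_id=source_id if source_id is not None else str(path))


def _hz_to_mel(f):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    f_sp = 200.0 / 3
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = math.log(6.4) / 27.0
    mel = f / f_sp
    above = f >= min_log_hz
    mel = np.where(above, min_log_mel + np.log(np.maximum(f, min_log_hz) / min_log_hz) / logstep, mel)
    return mel


def _mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    f_sp = 200.0 / 3
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = math.log(6.4) / 27.0
    hz = m * f_sp
    above = m >= min_log_mel
    hz = np.where(above, min_log_hz * np.exp(logstep * (np.maximum(m, min_log_mel) - min_log_mel)), hz)
    return hz


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int, fmin: float, fmax: float | None = None):
    """Slaney-style triangular, area-normalised mel filterbank.

    Returns ``(weights, centres_hz)`` where ``weights`` has shape
    ``(n_mels, n_fft // 2 + 1)`` and each row integrates (approximately)
    the same spectral area.
    """
    if fmax is None:
        fmax = sample_rate / 2.0
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    mel_edges = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_edges = _mel_to_hz(mel_edges)

    weights = np.zeros((n_mels, len(fft_freqs)))
    for j in range(n_mels):
        lower, centre, upper = hz_edges[j], hz_edges[j + 1], hz_edges[j + 2]
        up = (fft_freqs - lower) / (centre - lower)
        down = (upper - fft_freqs) / (upper - centre)
        weights[j] = np.maximum(0.0, np.minimum(up, down))
        # Slaney area normalisation: constant energy per band
        weights[j] *= 2.0 / (upper - lower)
    return weights, hz_edges[1:-1]


def compute_mel_spectrogram(clip: AudioClip, cfg: FrontEndConfig | None = None) -> MelSpectrogram:
    """Non-overlapping Hamming-windowed STFT magnitudes through the mel filterbank.

    The trailing partial frame is discarded and the whole matrix is
    scaled to unit RMS (one scalar per recording).
    """
    if cfg is None:
        cfg = FrontEndConfig()
    n = len(clip.samples)
    frame = cfg.frame_size
    n_frames = n // frame
    if n_frames < 1:
        raise TooShortError(
            f"clip {clip.source_id!r} has {n} samples; at least {frame} required")

    frames = clip.samples[: n_frames * frame].reshape(n_frames, frame)
    window = np.hamming(frame)
    spectra = np.abs(rfft(frames * window, axis=1))

    fb, centres = mel_filterbank(clip.sample_rate, frame, cfg.n_mels, cfg.fmin_hz)
    mel = spectra @ fb.T

    rms = math.sqrt(float(np.mean(mel**2)))
    if rms == 0.0:
        raise DegenerateInputError(
            f"clip {clip.source_id!r} is silent; RMS normalisation undefined")
    mel = mel / rms
    if cfg.log_mel:
        mel = np.log(mel + 1e-10)
    return MelSpectrogram(values=mel, frame_duration_s=frame / clip.sample_rate,
                          band_centres_hz=centres, source_id=clip.source_id)


def compute_mfcc(mel: MelSpectrogram, n_coeffs: int = 13) -> MfccSequence:
    """Log-compress, DCT-II along the band axis, keep the first ``n_coeffs``
    coefficients (c0 included), append symmetric-difference deltas."""
    if mel.n_frames < 3:
        raise TooShortError("MFCC deltas need at least 3 frames")
    logmel = np.log(np.maximum(mel.values, 1e-10))
    cep = dct(logmel, type=2, axis=1, norm="ortho")[:, :n_coeffs]

    padded = np.vstack([cep[:1], cep, cep[-1:]])  # edge replication
    deltas = (padded[2:] - padded[:-2]) / 2.0
    return MfccSequence(values=np.hstack([cep, deltas]),
                        frame_duration_s=mel.frame_duration_s,
                        source_id=mel.source_id)
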