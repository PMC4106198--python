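"""Median-based per-band spectral noise subtraction.

For each spectrogram, the per-band median over time estimates the
stationary noise floor; subtracting it and clipping at zero keeps only
energy rising above the median.  Simple, cheap, and effective against
stationary backgrounds; it is not designed for fluctuating noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import MelSpectrogram
from .exceptions import TooShortError

__all__ = ["NoiseProfile", "reduce_noise"]


@dataclass
class NoiseProfile:
    median_spectrum: np.ndarray  # per-band median magnitude


def reduce_noise(mel: MelSpectrogram) -> tuple[MelSpectrogram, NoiseProfile]:
    """Subtract the per-band median spectrum from every frame, clip at zero.

    One profile per recording. Returns the reduced spectrogram together
    with the profile for inspection.
    """
    if mel.n_frames == 0:
        raise TooShortError("cannot noise-reduce an empty spectrogram")
    median = np.median(mel.values, axis=0)
    reduced = np.maximum(0.0, mel.values - median)
    out = MelSpectrogram(values=reduced, frame_duration_s=mel.frame_duration_s,
                         band_centres_hz=mel.band_centres_hz, source_id=mel.source_id)
    return out, NoiseProfile(median_spectrum=median)
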