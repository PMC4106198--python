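"""Temporal summarisation of variable-length feature sequences.

Three schemes collapse a (frames x dims) sequence to a fixed-length
vector: per-dimension mean and standard deviation (2*dims), per-dimension
maximum (dims), or modulation coefficients (10*dims) — a 10-bin
downsampled magnitude spectrum of each dimension's temporal evolution,
capturing rhythmic/AM structure that mean/std and max ignore.

The module also owns the vocabulary of the twelve feature
configurations (feature type x summarisation) used throughout the
experiment grid, and their resulting dimensionalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import TooShortError

__all__ = [
    "SummaryVector",
    "summarise_mean_std",
    "summarise_max",
    "summarise_modulation",
    "summarise",
    "FEATURE_CONFIGS",
    "FeatureConfigSpec",
    "summary_dimension",
]

N_MODULATION_COEFFS = 10


@dataclass
class SummaryVector:
    values: np.ndarray
    scheme: str                      # mean_std | max | modulation
    source_window: tuple | None = None  # (start_s, end_s) or None for whole


def _as_matrix(seq) -> np.ndarray:
    X = seq.values if hasattr(seq, "values") else np.asarray(seq, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature sequence must be 2-D (frames x dims)")
    return X


def summarise_mean_std(seq) -> SummaryVector:
    """[per-dim mean, per-dim population std] -> length 2*dims."""
    X = _as_matrix(seq)
    if X.shape[0] < 1:
        raise TooShortError("cannot summarise an empty sequence")
    return SummaryVector(values=np.concatenate([X.mean(axis=0), X.std(axis=0, ddof=0)]),
                         scheme="mean_std")


def summarise_max(seq) -> SummaryVector:
    """Per-dimension maximum -> length dims."""
    X = _as_matrix(seq)
    if X.shape[0] < 1:
        raise TooShortError("cannot summarise an empty sequence")
    return SummaryVector(values=X.max(axis=0), scheme="max")


def summarise_modulation(seq, n_coeffs: int = N_MODULATION_COEFFS,
                         frame_duration_s: float | None = None) -> SummaryVector:
    """Magnitude spectrum along time, averaged into ``n_coeffs`` equal-width
    frequency bins spanning 0..Nyquist of the frame rate -> 10*dims.

    One full-length transform per sequence keeps the output length
    independent of duration; magnitudes are divided by the frame count so
    long recordings do not dominate short ones.
    """
    X = _as_matrix(seq)
    n = X.shape[0]
    if n < 2:
        raise TooShortError("modulation summary needs at least 2 frames")
    if frame_duration_s is None:
        frame_duration_s = getattr(seq, "frame_duration_s", 1.0)
    mags = np.abs(np.fft.rfft(X, axis=0)) / n
    freqs = np.fft.rfftfreq(n, d=frame_duration_s)
    nyquist = 0.5 / frame_duration_s
    edges = np.linspace(0.0, nyquist, n_coeffs + 1)
    # assign each FFT bin to one of the n_coeffs equal-width bands
    idx = np.minimum(np.searchsorted(edges, freqs, side="right") - 1, n_coeffs - 1)
    out = np.zeros((n_coeffs, X.shape[1]))
    for b in range(n_coeffs):
        mask = idx == b
        if np.any(mask):
            out[b] = mags[mask].mean(axis=0)
    return SummaryVector(values=out.T.ravel(), scheme="modulation")


_SUMMARISERS = {
    "mean_std": summarise_mean_std,
    "max": summarise_max,
    "modulation": summarise_modulation,
}


def summarise(seq, scheme: str) -> SummaryVector:
    """Dispatch on scheme name: mean_std | max | modulation."""
    try:
        fn = _SUMMARISERS[scheme]
    except KeyError:
        raise ValueError(f"unknown summarisation scheme {scheme!r}") from None
    return fn(seq)


@dataclass(frozen=True)
class FeatureConfigSpec:
    """One cell of the feature-type x summarisation grid."""

    label: str
    feature: str          # mfcc | melspec | learned | learned2
    scheme: str           # mean_std | max | modulation
    delta: int = 1        # frames per patch for learned features


# The twelve configurations; labels are the config-file vocabulary.
FEATURE_CONFIGS: dict[str, FeatureConfigSpec] = {
    "mfcc-ms": FeatureConfigSpec("mfcc-ms", "mfcc", "mean_std"),
    "mfcc-maxp": FeatureConfigSpec("mfcc-maxp", "mfcc", "max"),
    "mfcc-modul": FeatureConfigSpec("mfcc-modul", "mfcc", "modulation"),
    "melspec-ms": FeatureConfigSpec("melspec-ms", "melspec", "mean_std"),
    "melspec-maxp": FeatureConfigSpec("melspec-maxp", "melspec", "max"),
    "melspec-modul": FeatureConfigSpec("melspec-modul", "melspec", "modulation"),
    "melspec-kfl1-ms": FeatureConfigSpec("melspec-kfl1-ms", "learned", "mean_std", delta=1),
    "melspec-kfl2-ms": FeatureConfigSpec("melspec-kfl2-ms", "learned", "mean_std", delta=2),
    "melspec-kfl3-ms": FeatureConfigSpec("melspec-kfl3-ms", "learned", "mean_std", delta=3),
    "melspec-kfl4-ms": FeatureConfigSpec("melspec-kfl4-ms", "learned", "mean_std", delta=4),
    "melspec-kfl8-ms": FeatureConfigSpec("melspec-kfl8-ms", "learned", "mean_std", delta=8),
    "melspec-kfl4pl8kfl4-ms": FeatureConfigSpec("melspec-kfl4pl8kfl4-ms", "learned2",
                                                "mean_std", delta=4),
}

_SCHEME_MULT = {"mean_std": 2, "max": 1, "modulation": N_MODULATION_COEFFS}


def summary_dimension(label: str, n_mels: int = 40, n_mfcc: int = 26,
                      k: int = 500) -> int:
    """Length of the summary vector for a named feature configuration."""
    spec = FEATURE_CONFIGS[label]
    width = {"mfcc": n_mfcc, "melspec": n_mels, "learned": k, "learned2": k}[spec.feature]
    return width * _SCHEME_MULT[spec.scheme]
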