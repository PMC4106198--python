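"""Unsupervised dictionary learning on (stacked) mel frames.

The learner fits an overcomplete set of k unit basis vectors to the
directions of whitened spectro-temporal patches, using an online
streaming spherical k-means: for each incoming patch the nearest
centroid under cosine distance receives a count-weighted update and is
renormalised back onto the unit sphere.  Training is done in two
streamed passes — a reservoir-sampled, shuffled pass that fixes the
whitening transform and initialises the centroids, then a full pass
over every patch — so the result is far less sensitive to presentation
order than a true single-pass fit, while the trainer itself still only
ever holds one patch at a time.

Projection of a spectrogram into the learned space is the dot product
of each whitened patch with every basis vector; with Δ > 1 the patches
are Δ consecutive frames stacked into one vector, so the bases capture
short-term spectro-temporal modulation (up/down chirps, AM patterns)
rather than instantaneous spectra only.  A two-layer variant max-pools
the projected sequence by a factor of 8 in time and learns a second
dictionary on top, capturing structure at a longer timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from sklearn.random_projection import GaussianRandomProjection

from .audio import MelSpectrogram
from .exceptions import DimensionMismatchError, TooShortError, ZeroNormError

logger = logging.getLogger(__name__)

__all__ = [
    "PatchConfig",
    "WhiteningTransform",
    "FeatureDictionary",
    "FeatureSequence",
    "cosine_distance",
    "stack_frames",
    "normalise_patches",
    "fit_whitening",
    "reservoir_sample_pass",
    "OnlineSphericalKMeans",
    "fit_dictionary",
    "project",
    "maxpool_downsample",
    "fit_two_layer",
    "project_two_layer",
    "random_projection",
    "save_dictionary",
    "load_dictionary",
]

DEFAULT_K = 500
DEFAULT_RESERVOIR = 100_000


@dataclass
class PatchConfig:
    """How spectrogram frames are grouped into training patches."""

    delta: int = 4            # frames stacked per patch
    layer2: bool = False      # two-layer variant
    pool_factor: int = 8      # temporal max-pool between layers
    normalise: bool = True    # per-patch mean-subtract + unit-norm before whitening

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")


@dataclass
class WhiteningTransform:
    """PCA whitening: x -> diag(1/sqrt(eig+eps)) V^T (x - mean)."""

    mean: np.ndarray
    matrix: np.ndarray
    epsilon: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.matrix.T

    @classmethod
    def identity(cls, dim: int) -> "WhiteningTransform":
        return cls(mean=np.zeros(dim), matrix=np.eye(dim), epsilon=0.0)


@dataclass
class FeatureDictionary:
    """k unit basis vectors over whitened patches of Δ stacked frames."""

    bases: np.ndarray                 # (k, M*delta), each row unit norm
    whitening: WhiteningTransform
    patch: PatchConfig
    update_counts: np.ndarray = field(default=None)  # per-basis online tallies
    seed: int | None = None

    def __post_init__(self):
        if self.update_counts is None:
            self.update_counts = np.zeros(self.bases.shape[0], dtype=np.int64)

    @property
    def k(self) -> int:
        return self.bases.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.bases.shape[1]


@dataclass
class FeatureSequence:
    """Frame x basis matrix of projection coefficients."""

    values: np.ndarray
    frame_duration_s: float
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(angle between a and b); in [0, 2]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroNormError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def stack_frames(mel, delta: int) -> np.ndarray:
    """Row t = concatenation of frames t .. t+Δ-1.

    Accepts a MelSpectrogram, FeatureSequence or a plain (frames x dims)
    array; output has ``n_frames - delta + 1`` rows of ``dims * delta``
    columns.
    """
    X = mel.values if hasattr(mel, "values") else np.asarray(mel)
    n, m = X.shape
    if n < delta:
        raise TooShortError(f"need at least {delta} frames, got {n}")
    if delta == 1:
        return X.copy()
    cols = [X[d : n - delta + 1 + d] for d in range(delta)]
    return np.hstack(cols)


def normalise_patches(P: np.ndarray) -> np.ndarray:
    """Per-patch mean subtraction and division by Euclidean norm.

    Zero-norm patches are left at zero rather than producing NaNs; the
    trainer skips them.
    """
    P = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    return np.divide(P, norms, out=np.zeros_like(P), where=norms > 0)


def fit_whitening(sample: np.ndarray, epsilon: float = 1e-8) -> WhiteningTransform:
    """Eigendecomposition-based PCA whitening fitted on ``sample``.

    Rank-deficient directions are floored by ``epsilon`` instead of
    blowing up; a warning is logged when the sample is wide or deficient.
    """
    sample = np.asarray(sample, dtype=np.float64)
    n, d = sample.shape
    if n < d:
        logger.warning("whitening sample has fewer rows (%d) than columns (%d)", n, d)
    mean = sample.mean(axis=0)
    cov = np.cov(sample - mean, rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.any(eigvals < epsilon):
        logger.warning("whitening: %d eigenvalue(s) floored at epsilon=%g",
                       int(np.sum(eigvals < epsilon)), epsilon)
    matrix = (eigvecs / np.sqrt(np.maximum(eigvals, 0.0) + epsilon)).T
    return WhiteningTransform(mean=mean, matrix=matrix, epsilon=epsilon)


def reservoir_sample_pass(stream: Iterable[np.ndarray], capacity: int,
                          seed: int) -> np.ndarray:
    """Uniform without-replacement sample of min(capacity, N) rows from a
    single forward pass over ``stream`` (algorithm R), shuffled before
    return so downstream online fits see a random order."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: list[np.ndarray] = []
    n_seen = 0
    for row in stream:
        row = np.asarray(row, dtype=np.float64)
        if n_seen < capacity:
            reservoir.append(row.copy())
        else:
            j = rng.integers(0, n_seen + 1)
            if j < capacity:
                reservoir[j] = row.copy()
        n_seen += 1
    if n_seen == 0:
        raise TooShortError("cannot reservoir-sample an empty stream")
    sample = np.vstack(reservoir)
    rng.shuffle(sample)
    return sample


class OnlineSphericalKMeans:
    """Streaming spherical k-means with count-weighted (Hartigan-style) updates.

    State is k unit centroids plus per-centroid update tallies; its size
    is independent of how many patches are streamed through.  For each
    unit-normalised input x̂ the nearest centroid c (cosine distance,
    ties to the lowest index) is updated as
    ``c <- normalise(c + x̂ / (n_c + 1))`` and its tally incremented, so
    early updates move centroids far and later ones refine them.
    """

    def __init__(self, centroids: np.ndarray, counts: np.ndarray | None = None):
        self.centroids = np.asarray(centroids, dtype=np.float64).copy()
        norms = np.linalg.norm(self.centroids, axis=1, keepdims=True)
        self.centroids /= norms
        k = self.centroids.shape[0]
        self.counts = (np.zeros(k, dtype=np.int64) if counts is None
                       else np.asarray(counts, dtype=np.int64).copy())
        self.n_skipped = 0

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def partial_fit(self, x: np.ndarray) -> int:
        """Update with one patch (already whitened). Returns the index of
        the updated centroid, or -1 for a skipped zero-norm patch."""
        norm = np.linalg.norm(x)
        if norm == 0.0:
            self.n_skipped += 1
            return -1
        xhat = x / norm
        sims = self.centroids @ xhat
        j = int(np.argmax(sims))  # argmax takes the first max: lowest-index tie-break
        w = 1.0 / (self.counts[j] + 1)
        c = self.centroids[j] + w * xhat
        self.centroids[j] = c / np.linalg.norm(c)
        self.counts[j] += 1
        return j

    def mean_cosine_distance(self, X: np.ndarray) -> float:
        """Mean cosine distance of rows of X to their nearest centroid."""
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        sims = Xn @ self.centroids.T
        return float(np.mean(1.0 - sims.max(axis=1)))


def _patch_stream(sources: Sequence, delta: int) -> Iterator[np.ndarray]:
    for src in sources:
        X = src.values if hasattr(src, "values") else np.asarray(src)
        if X.shape[0] < delta:
            continue
        patches = stack_frames(X, delta)
        yield from patches


def fit_dictionary(sources: Sequence, cfg: PatchConfig | None = None,
                   k: int = DEFAULT_K, seed: int = 0,
                   reservoir_capacity: int = DEFAULT_RESERVOIR,
                   epsilon: float = 1e-8,
                   second_pass: bool = True,
                   carry_counts: bool = True,
                   whiten: bool = True) -> FeatureDictionary:
    """Two-pass streamed fit of a k-basis dictionary on stacked frames.

    Pass 1 reservoir-samples patches, shuffles them, fits the whitening
    transform, seeds the centroids from k distinct sampled patches and
    runs the online update over the sample.  Pass 2 streams every patch
    through the online update (tallies carried over by default).

    ``sources`` is any sequence of MelSpectrogram / FeatureSequence /
    arrays; recordings shorter than Δ frames are skipped.
    """
    if cfg is None:
        cfg = PatchConfig()
    rng = np.random.default_rng(seed)

    sample = reservoir_sample_pass(_patch_stream(sources, cfg.delta),
                                   reservoir_capacity, seed=int(rng.integers(2**31)))
    if sample.shape[0] < k:
        raise TooShortError(
            f"only {sample.shape[0]} patches available; need at least k={k}")
    if cfg.normalise:
        sample = normalise_patches(sample)
    whitening = (fit_whitening(sample, epsilon=epsilon) if whiten
                 else WhiteningTransform.identity(sample.shape[1]))
    white = whitening.apply(sample)

    # init: k distinct sampled patches with nonzero norm, normalised
    norms = np.linalg.norm(white, axis=1)
    candidates = np.flatnonzero(norms > 0)
    if len(candidates) < k:
        raise TooShortError(f"only {len(candidates)} usable patches for k={k} centroids")
    init = white[candidates[:k]]
    trainer = OnlineSphericalKMeans(init)

    for row in white:
        trainer.partial_fit(row)

    if second_pass:
        if not carry_counts:
            trainer.counts[:] = 0
        for patch in _patch_stream(sources, cfg.delta):
            if cfg.normalise:
                patch = normalise_patches(patch[None, :])[0]
            trainer.partial_fit(whitening.apply(patch)[0])

    if trainer.n_skipped:
        logger.warning("skipped %d zero-norm patches during training", trainer.n_skipped)
    return FeatureDictionary(bases=trainer.centroids, whitening=whitening,
                             patch=cfg, update_counts=trainer.counts, seed=seed)


def project(mel, dictionary: FeatureDictionary) -> FeatureSequence:
    """Project a spectrogram (or feature sequence) onto the dictionary.

    Each Δ-frame patch is preprocessed exactly as during training
    (optional per-patch normalisation, then the stored whitening) and
    dotted with every basis.  Dot products are kept signed.
    """
    X = mel.values if hasattr(mel, "values") else np.asarray(mel)
    delta = dictionary.patch.delta
    if X.shape[0] < delta:
        raise TooShortError(f"need at least {delta} frames to project, got {X.shape[0]}")
    patches = stack_frames(X, delta)
    if patches.shape[1] != dictionary.patch_dim:
        raise DimensionMismatchError(
            f"dictionary expects patch dim {dictionary.patch_dim}, got {patches.shape[1]}")
    if dictionary.patch.normalise:
        patches = normalise_patches(patches)
    white = dictionary.whitening.apply(patches)
    values = white @ dictionary.bases.T
    frame_dur = getattr(mel, "frame_duration_s", 1.0)
    return FeatureSequence(values=values, frame_duration_s=frame_dur,
                           source_id=getattr(mel, "source_id", ""))


def maxpool_downsample(seq: FeatureSequence, factor: int) -> FeatureSequence:
    """Element-wise max over consecutive blocks of ``factor`` frames; a
    trailing partial block is pooled as-is."""
    X = seq.values
    if X.shape[0] == 0:
        raise TooShortError("cannot pool an empty sequence")
    if factor == 1:
        return FeatureSequence(values=X.copy(), frame_duration_s=seq.frame_duration_s,
                               source_id=seq.source_id)
    n_out = -(-X.shape[0] // factor)  # ceil
    out = np.empty((n_out, X.shape[1]))
    for t in range(n_out):
        out[t] = X[t * factor : (t + 1) * factor].max(axis=0)
    return FeatureSequence(values=out, frame_duration_s=seq.frame_duration_s * factor,
                           source_id=seq.source_id)


def fit_two_layer(sources: Sequence, cfg: PatchConfig | None = None,
                  k: int = DEFAULT_K, seed: int = 0,
                  **fit_kwargs) -> tuple[FeatureDictionary, FeatureDictionary]:
    """Two-layer fit: dictionary on Δ-frame patches, project everything,
    max-pool by ``pool_factor``, then fit a second dictionary on Δ-frame
    patches of the pooled layer-1 features (patch dim k*Δ)."""
    if cfg is None:
        cfg = PatchConfig(layer2=True)
    layer1 = fit_dictionary(sources, cfg=cfg, k=k, seed=seed, **fit_kwargs)
    pooled = []
    for src in sources:
        X = src.values if hasattr(src, "values") else np.asarray(src)
        if X.shape[0] < cfg.delta:
            continue
        seq = project(src, layer1)
        pooled.append(maxpool_downsample(seq, cfg.pool_factor))
    layer2 = fit_dictionary(pooled, cfg=PatchConfig(delta=cfg.delta, normalise=cfg.normalise),
                            k=k, seed=seed + 1, **fit_kwargs)
    return layer1, layer2


def project_two_layer(mel, layer1: FeatureDictionary,
                      layer2: FeatureDictionary,
                      pool_factor: int | None = None) -> FeatureSequence:
    """Layer-1 projection, temporal max-pool, layer-2 projection."""
    if pool_factor is None:
        pool_factor = layer1.patch.pool_factor
    seq = project(mel, layer1)
    pooled = maxpool_downsample(seq, pool_factor)
    return project(pooled, layer2)


def random_projection(X: np.ndarray, out_dim: int, seed: int) -> np.ndarray:
    """Seeded Gaussian random projection of summary vectors to ``out_dim``.

    Used to standardise feature dimensionality across configurations so
    classifier degrees of freedom are decoupled from feature character.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    proj = GaussianRandomProjection(n_components=out_dim, random_state=seed)
    return proj.fit_transform(X)


def save_dictionary(path, dictionary: FeatureDictionary) -> None:
    """Serialise a dictionary (and its whitening/patch config) to one .npz."""
    np.savez(path,
             schema_version=1,
             bases=dictionary.bases,
             whitening_mean=dictionary.whitening.mean,
             whitening_matrix=dictionary.whitening.matrix,
             whitening_epsilon=dictionary.whitening.epsilon,
             delta=dictionary.patch.delta,
             layer2=dictionary.patch.layer2,
             pool_factor=dictionary.patch.pool_factor,
             normalise=dictionary.patch.normalise,
             update_counts=dictionary.update_counts,
             seed=-1 if dictionary.seed is None else dictionary.seed)


def load_dictionary(path) -> FeatureDictionary:
    with np.load(path) as z:
        wt = WhiteningTransform(mean=z["whitening_mean"], matrix=z["whitening_matrix"],
                                epsilon=float(z["whitening_epsilon"]))
        cfg = PatchConfig(delta=int(z["delta"]), layer2=bool(z["layer2"]),
                          pool_factor=int(z["pool_factor"]), normalise=bool(z["normalise"]))
        seed = int(z["seed"])
        return FeatureDictionary(bases=z["bases"], whitening=wt, patch=cfg,
                                 update_counts=z["update_counts"],
                                 seed=None if seed < 0 else seed)
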