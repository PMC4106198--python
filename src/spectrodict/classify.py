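"""Random-forest classification over summary vectors, in three label modes.

The classifier contract is fixed: 200 trees, entropy (information-gain)
split criterion, otherwise library defaults — no manual tuning.  Three
ways of using it are supported:

* ``single_label`` — one forest over mutually exclusive classes;
* ``binary_relevance`` — one forest per class, positive = label present;
* ``multilabel`` — one multi-output forest predicting every label jointly.

Long recordings can be split into fixed-duration decision windows, each
treated as a separate datum inheriting the recording's full label set;
per-window probabilities are pooled back to one score per recording by
mean or max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import DimensionMismatchError, ModeMismatchError
from .summarise import summarise

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "DecisionWindowing",
    "PredictionMatrix",
    "TrainingTable",
    "window_slices",
    "make_training_table",
    "train_classifier",
    "predict",
    "ClassifierModel",
    "N_TREES",
]

N_TREES = 200


@dataclass
class AnnotationSet:
    """Per-recording species annotations over an ordered vocabulary."""

    items: dict[str, frozenset[str]]      # recording id -> label set
    vocabulary: list[str]
    mode: str = "multilabel"              # single_label | multilabel

    def __post_init__(self):
        vocab = set(self.vocabulary)
        for rid, labels in self.items.items():
            unknown = set(labels) - vocab
            if unknown:
                raise ValueError(f"recording {rid!r} has labels outside vocabulary: {unknown}")
            if self.mode == "single_label" and len(labels) != 1:
                raise ValueError(f"single-label set but recording {rid!r} has {len(labels)} labels")

    def label_matrix(self, ids: list[str]) -> np.ndarray:
        """Binary (items x classes) indicator matrix in vocabulary order."""
        col = {c: j for j, c in enumerate(self.vocabulary)}
        Y = np.zeros((len(ids), len(self.vocabulary)), dtype=np.int64)
        for i, rid in enumerate(ids):
            for lab in self.items[rid]:
                Y[i, col[lab]] = 1
        return Y


@dataclass
class DecisionWindowing:
    """Decision-window length in seconds (None = whole audio) and the
    pooling statistic used to aggregate per-window scores."""

    window_s: float | None = None
    pool: str = "mean"  # mean | max; ignored for whole-audio

    def __post_init__(self):
        if self.pool not in ("mean", "max"):
            raise ValueError(f"unknown pooling {self.pool!r}")


@dataclass
class PredictionMatrix:
    scores: np.ndarray        # (items x classes), each in [0, 1]
    item_ids: list[str]
    vocabulary: list[str]


@dataclass
class TrainingTable:
    X: np.ndarray             # (rows x feature dim)
    Y: np.ndarray             # (rows x classes) binary
    row_ids: list[str]        # recording id per row (repeated across windows)
    vocabulary: list[str]


def window_slices(n_frames: int, frame_duration_s: float,
                  window_s: float | None) -> list[slice]:
    """Non-overlapping window slices over the feature-frame axis.

    Trailing partial windows are kept when they contain >= 1 frame; a
    recording shorter than one window yields a single partial window.
    """
    if window_s is None:
        return [slice(0, n_frames)]
    w = max(1, int(round(window_s / frame_duration_s)))
    if n_frames < w:
        logger.warning("recording shorter than one %gs window; using one partial window",
                       window_s)
        return [slice(0, n_frames)]
    return [slice(s, min(s + w, n_frames)) for s in range(0, n_frames, w)]


def _build_rows(sequences: dict, win: DecisionWindowing, scheme: str):
    """Summarise each decision window of each recording into one row."""
    rows, row_ids = [], []
    for rid, seq in sequences.items():
        X = seq.values
        for sl in window_slices(X.shape[0], seq.frame_duration_s, win.window_s):
            sub = X[sl]
            rows.append(summarise(sub, scheme).values)
            row_ids.append(rid)
    return np.vstack(rows), row_ids


def make_training_table(sequences: dict, ann: AnnotationSet,
                        win: DecisionWindowing, scheme: str = "mean_std") -> TrainingTable:
    """One row per decision window; each window inherits its recording's
    full label set.  ``sequences`` maps recording id -> FeatureSequence
    (or any object with ``values`` and ``frame_duration_s``)."""
    missing = [rid for rid in sequences if rid not in ann.items]
    if missing:
        raise ValueError(f"recordings without annotations: {missing[:5]}")
    X, row_ids = _build_rows(sequences, win, scheme)
    Y = ann.label_matrix(row_ids)
    return TrainingTable(X=X, Y=Y, row_ids=row_ids, vocabulary=list(ann.vocabulary))


@dataclass
class ClassifierModel:
    mode: str
    vocabulary: list[str]
    n_features: int
    forests: list = field(default_factory=list)   # one (multilabel/single) or per-class
    scheme: str = "mean_std"

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-row per-class probabilities, aligned with ``vocabulary``."""
        if X.shape[1] != self.n_features:
            raise DimensionMismatchError(
                f"model expects {self.n_features} features, got {X.shape[1]}")
        n, C = X.shape[0], len(self.vocabulary)
        S = np.zeros((n, C))
        if self.mode == "single_label":
            forest = self.forests[0]
            proba = forest.predict_proba(X)
            for j, cls in enumerate(forest.classes_):
                S[:, int(cls)] = proba[:, j]
        elif self.mode == "multilabel":
            forest = self.forests[0]
            proba = forest.predict_proba(X)
            if not isinstance(proba, list):
                proba = [proba]
            for c in range(C):
                classes = forest.classes_[c]
                if len(classes) == 1:
                    S[:, c] = float(classes[0])
                else:
                    S[:, c] = proba[c][:, int(np.argmax(classes == 1))]
        else:  # binary_relevance
            for c, forest in enumerate(self.forests):
                if forest is None:
                    S[:, c] = 0.0
                elif isinstance(forest, float):
                    S[:, c] = forest
                else:
                    S[:, c] = forest.predict_proba(X)[:, int(np.argmax(forest.classes_ == 1))]
        return S


def train_classifier(table: TrainingTable, mode: str, seed: int = 0) -> ClassifierModel:
    """Fit the random forest(s) for the given label mode.

    ``single_label`` requires every training row to carry exactly one
    label.  In ``binary_relevance`` a class with no positive training
    examples gets a constant score 0 (with a warning).
    """
    if mode not in ("single_label", "multilabel", "binary_relevance"):
        raise ValueError(f"unknown classifier mode {mode!r}")
    X, Y = table.X, table.Y
    present = np.flatnonzero(Y.any(axis=0))
    if len(present) < 2:
        raise ValueError("need at least 2 classes with at least 1 example each")

    model = ClassifierModel(mode=mode, vocabulary=list(table.vocabulary),
                            n_features=X.shape[1])

    def _forest(rs):
        return RandomForestClassifier(n_estimators=N_TREES, criterion="entropy",
                                      random_state=rs)

    if mode == "single_label":
        if not np.all(Y.sum(axis=1) == 1):
            raise ModeMismatchError("single_label mode requires exactly one label per row")
        y = np.argmax(Y, axis=1)
        forest = _forest(seed)
        forest.fit(X, y)
        model.forests = [forest]
    elif mode == "multilabel":
        forest = _forest(seed)
        forest.fit(X, Y)
        model.forests = [forest]
    else:
        forests = []
        for c in range(Y.shape[1]):
            y = Y[:, c]
            if y.sum() == 0:
                logger.warning("class %r has no positive training examples; constant score 0",
                               table.vocabulary[c])
                forests.append(None)
            elif y.sum() == len(y):
                forests.append(1.0)
            else:
                forest = _forest(seed + c)
                forest.fit(X, y)
                forests.append(forest)
        model.forests = forests
    return model


def predict(model: ClassifierModel, sequences: dict,
            win: DecisionWindowing, scheme: str = "mean_std",
            return_window_scores: bool = False):
    """Score each recording: per-window probabilities pooled by the
    configured statistic (whole-audio mode passes through)."""
    X, row_ids = _build_rows(sequences, win, scheme)
    window_scores = model.predict_scores(X)

    ids = list(sequences.keys())
    pos = {rid: i for i, rid in enumerate(ids)}
    pooled = np.zeros((len(ids), len(model.vocabulary)))
    groups: dict[str, list[int]] = {rid: [] for rid in ids}
    for r, rid in enumerate(row_ids):
        groups[rid].append(r)
    for rid, rows in groups.items():
        block = window_scores[rows]
        pooled[pos[rid]] = block.max(axis=0) if win.pool == "max" else block.mean(axis=0)
    pred = PredictionMatrix(scores=pooled, item_ids=ids, vocabulary=list(model.vocabulary))
    if return_window_scores:
        return pred, (window_scores, row_ids)
    return pred
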