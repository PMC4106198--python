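"""Evaluation statistics, crossvalidation folds and the experiment grid.

AUC is computed in its Mann-Whitney formulation — the probability that a
random positive is ranked above a random negative, with tied scores
contributing half credit — so chance performance is exactly 0.5
regardless of class balance.  MAP is the mean over evaluated items of
the average precision of each item's class ranking, which penalises
misorderings near the top of the ranked list more heavily than AUC.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import features as fl
from .audio import FrontEndConfig, compute_mel_spectrogram, compute_mfcc
from .classify import (AnnotationSet, DecisionWindowing, PredictionMatrix,
                       make_training_table, predict, train_classifier)
from .exceptions import UndefinedMetricError
from .noise import reduce_noise
from .summarise import FEATURE_CONFIGS

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSpec",
    "EvalResult",
    "auc",
    "mean_average_precision",
    "multilabel_auc",
    "enumerate_grid",
    "run_crossvalidation",
]


@dataclass
class FoldSpec:
    """Assignment of recordings to crossvalidation folds.

    ``by_group`` strategies (e.g. per-recordist stratification) keep all
    recordings of one group in the same fold, testing generalisation to
    unseen recording conditions.
    """

    assignments: dict[str, int]
    n_folds: int
    strategy: str = "random_split"  # random_split | by_group

    def fold_ids(self, fold: int) -> list[str]:
        return [rid for rid, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [rid for rid, f in self.assignments.items() if f != fold]


@dataclass
class EvalResult:
    auc: float                       # mean of per-fold micro AUC
    map: float                       # mean of per-fold MAP
    per_fold: list = field(default_factory=list)   # (auc, map) per fold
    auc_pooled: float = float("nan")  # AUC on scores pooled across folds
    map_pooled: float = float("nan")
    auc_macro: float = float("nan")  # mean per-fold macro AUC
    config: dict = field(default_factory=dict)
    train_rows_per_fold: list = field(default_factory=list)
    dictionary_fingerprints: list = field(default_factory=list)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive ranked above random negative),
    ties counted half.  Raises when either class is absent."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined with {n_pos} positives and {n_neg} negatives")
    ranks = rankdata(scores)  # average ranks handle ties as half credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _average_precision(scores: np.ndarray, relevant: np.ndarray) -> float:
    """AP of one ranked list; ties broken deterministically by class index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    rel = relevant[order]
    hits = np.cumsum(rel)
    ranks = np.arange(1, len(scores) + 1)
    precisions = hits[rel.astype(bool)] / ranks[rel.astype(bool)]
    return float(precisions.mean())


def mean_average_precision(pred: PredictionMatrix, ann: AnnotationSet) -> float:
    """Mean over items of the average precision of the item's class
    ranking.  Items with no true labels are excluded with a warning."""
    Y = ann.label_matrix(pred.item_ids)
    aps = []
    for i in range(len(pred.item_ids)):
        if Y[i].sum() == 0:
            logger.warning("item %r has no true labels; excluded from MAP",
                           pred.item_ids[i])
            continue
        aps.append(_average_precision(pred.scores[i], Y[i]))
    if not aps:
        raise UndefinedMetricError("no items with true labels; MAP undefined")
    return float(np.mean(aps))


def multilabel_auc(pred: PredictionMatrix, ann: AnnotationSet,
                   average: str = "micro") -> float:
    """AUC over a prediction matrix.

    ``micro`` pools all (item, class) score/label pairs into one ranking;
    ``macro`` averages per-class AUCs over classes that have both a
    positive and a negative item.
    """
    Y = ann.label_matrix(pred.item_ids)
    if average == "micro":
        return auc(pred.scores.ravel(), Y.ravel())
    if average == "macro":
        vals = []
        for c in range(Y.shape[1]):
            col = Y[:, c]
            if 0 < col.sum() < len(col):
                vals.append(auc(pred.scores[:, c], col))
        if not vals:
            raise UndefinedMetricError("no class has both positives and negatives")
        return float(np.mean(vals))
    raise ValueError(f"unknown AUC average {average!r}")


def enumerate_grid(feature_labels=None, noise_reduction=(False, True),
                   classifier_modes=("multilabel", "binary_relevance"),
                   windows=(1.0, 5.0, 60.0, None), pools=("mean", "max")) -> list[dict]:
    """Cartesian product of the experiment axes.

    With all four pooling durations this yields 12 x 2 x 2 x 4 x 2 = 384
    configurations; restricting the window axis scales the count down
    (two durations -> 192, whole-audio only -> 96).  The pooling-statistic
    axis is enumerated even for whole-audio windows, matching how the
    grid is counted, although pooling is a no-op there.
    """
    if feature_labels is None:
        feature_labels = list(FEATURE_CONFIGS)
    grid = []
    for feat, nr, mode, win, pool in itertools.product(
            feature_labels, noise_reduction, classifier_modes, windows, pools):
        grid.append({"feature": feat, "noise_reduction": nr, "classifier_mode": mode,
                     "window_s": win, "pool": pool})
    return grid


def _prepare_sequences(mels: dict, label: str, train_ids: list[str],
                       k: int, seed: int, fit_kwargs: dict,
                       extra_learning_mels=None):
    """Per-recording feature sequences for one feature configuration.

    Learned-feature dictionaries are fitted on the training recordings
    only (plus any ``extra_learning_mels``, which never reach the
    classifier); the fitted dictionary (or pair) is returned for
    inspection.
    """
    spec = FEATURE_CONFIGS[label]
    if spec.feature == "melspec":
        return dict(mels), None
    if spec.feature == "mfcc":
        return {rid: compute_mfcc(mel) for rid, mel in mels.items()}, None
    train_mels = [mels[rid] for rid in train_ids]
    if extra_learning_mels:
        train_mels = train_mels + list(extra_learning_mels)
    if spec.feature == "learned":
        cfg = fl.PatchConfig(delta=spec.delta)
        d = fl.fit_dictionary(train_mels, cfg=cfg, k=k, seed=seed, **fit_kwargs)
        return {rid: fl.project(mel, d) for rid, mel in mels.items()}, d
    # two-layer
    cfg = fl.PatchConfig(delta=spec.delta, layer2=True)
    d1, d2 = fl.fit_two_layer(train_mels, cfg=cfg, k=k, seed=seed, **fit_kwargs)
    return {rid: fl.project_two_layer(mel, d1, d2) for rid, mel in mels.items()}, (d1, d2)


def dictionary_fingerprint(d) -> str:
    """Stable content hash of a fitted dictionary (leakage diagnostics)."""
    h = hashlib.sha256()
    if isinstance(d, tuple):
        for part in d:
            h.update(np.ascontiguousarray(part.bases).tobytes())
    else:
        h.update(np.ascontiguousarray(d.bases).tobytes())
    return h.hexdigest()


def run_crossvalidation(clips, ann: AnnotationSet, folds: FoldSpec, config: dict,
                        seed: int = 0, frontend: FrontEndConfig | None = None,
                        k: int = 500, mels: dict | None = None,
                        fit_kwargs: dict | None = None,
                        extra_learning_mels=None,
                        extra_train: tuple | None = None) -> EvalResult:
    """One crossvalidated experiment for one grid configuration.

    For each fold, feature learning (if any) sees training-fold audio
    only; the classifier is trained on training folds and evaluated on
    the held-out fold.  Per-fold micro AUC and MAP are averaged for the
    headline statistics; pooled-score variants are stored alongside.

    ``mels`` may carry precomputed raw mel spectrograms (keyed by
    recording id) so the front-end is not recomputed per configuration.
    ``extra_learning_mels`` is extra (possibly unlabelled) audio used in
    dictionary fitting only; ``extra_train`` is an
    ``(mels dict, AnnotationSet)`` pair of extra labelled data added to
    classifier training in every fold but never evaluated.
    """
    fit_kwargs = fit_kwargs or {}
    if mels is None:
        mels = {c.source_id: compute_mel_spectrogram(c, frontend) for c in clips}
    if config.get("noise_reduction"):
        mels = {rid: reduce_noise(mel)[0] for rid, mel in mels.items()}
        if extra_learning_mels:
            extra_learning_mels = [reduce_noise(m)[0] for m in extra_learning_mels]

    extra_mels, extra_ann = ({}, None)
    if extra_train is not None:
        extra_mels, extra_ann = extra_train
        if config.get("noise_reduction"):
            extra_mels = {rid: reduce_noise(m)[0] for rid, m in extra_mels.items()}
        overlap = set(extra_mels) & set(mels)
        if overlap:
            raise ValueError(f"extra training ids collide with dataset ids: {overlap}")
        ann = AnnotationSet(items={**ann.items, **extra_ann.items},
                            vocabulary=list(ann.vocabulary), mode=ann.mode)

    label = config["feature"]
    scheme = FEATURE_CONFIGS[label].scheme
    win = DecisionWindowing(window_s=config.get("window_s"), pool=config.get("pool", "mean"))
    mode = config.get("classifier_mode", "multilabel")

    per_fold = []
    macro_vals = []
    all_scores, all_Y = [], []
    all_item_scores = []
    train_rows_per_fold = []
    dict_fps = []
    for fold in range(folds.n_folds):
        test_ids = folds.fold_ids(fold)
        train_ids = folds.train_ids(fold) + list(extra_mels)
        if not test_ids:
            raise ValueError(f"fold {fold} has no test items")
        fold_seed = seed * 1000 + fold
        seqs, fitted = _prepare_sequences({**mels, **extra_mels}, label, train_ids,
                                          k, fold_seed, fit_kwargs,
                                          extra_learning_mels=extra_learning_mels)
        if fitted is not None:
            dict_fps.append(dictionary_fingerprint(fitted))
        table = make_training_table({rid: seqs[rid] for rid in train_ids}, ann, win, scheme)
        train_rows_per_fold.append(table.X.shape[0])
        logger.info("fold %d: %d training rows (%d recordings)", fold,
                    table.X.shape[0], len(train_ids))
        model = train_classifier(table, mode, seed=fold_seed)
        pred = predict(model, {rid: seqs[rid] for rid in test_ids}, win, scheme)

        fold_auc = multilabel_auc(pred, ann, average="micro")
        fold_map = mean_average_precision(pred, ann)
        try:
            macro_vals.append(multilabel_auc(pred, ann, average="macro"))
        except UndefinedMetricError:
            pass
        per_fold.append((fold_auc, fold_map))
        Y = ann.label_matrix(pred.item_ids)
        all_scores.append(pred.scores)
        all_Y.append(Y)
        all_item_scores.append((pred.item_ids, pred.scores))

    pooled_scores = np.vstack(all_scores)
    pooled_Y = np.vstack(all_Y)
    pooled_auc = auc(pooled_scores.ravel(), pooled_Y.ravel())
    pooled_ids = [rid for ids, _ in all_item_scores for rid in ids]
    pooled_pred = PredictionMatrix(scores=pooled_scores, item_ids=pooled_ids,
                                   vocabulary=list(ann.vocabulary))
    pooled_map = mean_average_precision(pooled_pred, ann)

    return EvalResult(
        auc=float(np.mean([a for a, _ in per_fold])),
        map=float(np.mean([m for _, m in per_fold])),
        per_fold=per_fold,
        auc_pooled=pooled_auc,
        map_pooled=pooled_map,
        auc_macro=float(np.mean(macro_vals)) if macro_vals else float("nan"),
        config=dict(config),
        train_rows_per_fold=train_rows_per_fold,
        dictionary_fingerprints=dict_fps,
    )
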