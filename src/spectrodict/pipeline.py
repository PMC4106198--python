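"""End-to-end experiment orchestration from a single configuration.

A run executes extract -> (noise-reduce) -> (learn dictionary) ->
project -> summarise -> train -> predict -> evaluate, with per-stage
on-disk caching keyed by a fingerprint of the configuration that
produced each artifact, so repeated runs and grid sweeps only recompute
what changed.  Three data-composition modes are supported: standard
crossvalidation, feature-learning augmentation (extra audio used for
dictionary fitting only) and training augmentation (extra labelled data
added to classifier fitting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio import FrontEndConfig, MelSpectrogram, compute_mel_spectrogram, load_audio
from .classify import AnnotationSet
from .evaluate import EvalResult, FoldSpec, run_crossvalidation
from .summarise import FEATURE_CONFIGS
from .synth import generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "read_dataset", "run", "fingerprint"]


def fingerprint(obj) -> str:
    """Stable content hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class PipelineConfig:
    dataset: dict
    feature: str = "mfcc-ms"
    noise_reduction: bool = False
    classifier_mode: str = "multilabel"
    window_s: float | None = None
    pool: str = "mean"
    k: int = 500
    seed: int = 0
    reservoir_capacity: int = 100_000
    frontend: dict = dataclasses.field(default_factory=dict)
    feature_learning_extra: dict | None = None
    training_extra: dict | None = None
    cache_dir: str = "cache"
    out_dir: str = "results"

    def __post_init__(self):
        if self.feature not in FEATURE_CONFIGS:
            raise ValueError(
                f"unknown feature configuration {self.feature!r}; "
                f"expected one of {sorted(FEATURE_CONFIGS)}")
        if self.classifier_mode not in ("single_label", "multilabel", "binary_relevance"):
            raise ValueError(f"unknown classifier mode {self.classifier_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _load_annotations_csv(path: Path, mode_hint: str | None = None) -> AnnotationSet:
    df = pd.read_csv(path, dtype=str).fillna("")
    items = {}
    for _, row in df.iterrows():
        labels = frozenset(l for l in str(row["labels"]).split(";") if l)
        items[row["recording_id"]] = labels
    vocabulary = sorted({l for labs in items.values() for l in labs})
    mode = mode_hint or ("single_label" if all(len(v) == 1 for v in items.values())
                         else "multilabel")
    return AnnotationSet(items=items, vocabulary=vocabulary, mode=mode)


def read_dataset(path) -> tuple[list, AnnotationSet, FoldSpec]:
    """Read a dataset directory: WAV files + annotations.csv + folds.csv."""
    root = Path(path)
    ann = _load_annotations_csv(root / "annotations.csv")
    folds_df = pd.read_csv(root / "folds.csv", dtype={"recording_id": str, "fold": int})
    assignments = dict(zip(folds_df["recording_id"], folds_df["fold"]))
    folds = FoldSpec(assignments=assignments, n_folds=int(folds_df["fold"].max()) + 1)
    clips = [load_audio(root / f"{rid}.wav", source_id=rid) for rid in ann.items]
    return clips, ann, folds


def _resolve_dataset(ref: dict):
    """Dataset reference: {"path": dir} or {"synthetic": {...generate_dataset kwargs}}."""
    if "path" in ref:
        return read_dataset(ref["path"])
    if "synthetic" in ref:
        ds = generate_dataset(**ref["synthetic"])
        return ds.clips, ds.annotations, ds.folds
    raise ValueError("dataset reference needs a 'path' or 'synthetic' key")


def _mel_stage(clips, frontend: FrontEndConfig, cache: Path | None, key: str) -> dict:
    """Compute (or load cached) raw mel spectrograms keyed by recording id."""
    path = cache / f"mel-{key}.npz" if cache else None
    if path is not None and path.exists():
        try:
            with np.load(path, allow_pickle=False) as z:
                meta = json.loads(str(z["meta"]))
                return {rid: MelSpectrogram(values=z[f"v_{rid}"],
                                            frame_duration_s=meta["frame_duration_s"],
                                            band_centres_hz=z["centres"],
                                            source_id=rid)
                        for rid in meta["ids"]}
        except Exception:  # noqa: BLE001
            logger.warning("mel cache %s unreadable; recomputing", path)
    t0 = time.monotonic()
    mels = {c.source_id: compute_mel_spectrogram(c, frontend) for c in clips}
    logger.info("mel extraction: %d recordings in %.1fs", len(mels), time.monotonic() - t0)
    if path is not None:
        first = next(iter(mels.values()))
        arrays = {f"v_{rid}": m.values for rid, m in mels.items()}
        np.savez(path, meta=json.dumps({"ids": list(mels),
                                        "frame_duration_s": first.frame_duration_s}),
                 centres=first.band_centres_hz, **arrays)
    return mels


def run(config, workdir: str | Path = ".") -> EvalResult:
    """Execute one full crossvalidated experiment from a config (path,
    dict or PipelineConfig).  Writes a results CSV row and a run manifest
    under ``out_dir`` and returns the EvalResult."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)

    workdir = Path(workdir)
    cache = workdir / config.cache_dir
    cache.mkdir(parents=True, exist_ok=True)
    out_dir = workdir / config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    cfg_fp = fingerprint(config.to_dict())
    result_path = cache / f"result-{cfg_fp}.json"
    if result_path.exists():
        try:
            with open(result_path) as fh:
                payload = json.load(fh)
            logger.info("run %s served from cache", cfg_fp)
            result = EvalResult(**payload)
            result.per_fold = [tuple(p) for p in result.per_fold]
            return result
        except Exception:  # noqa: BLE001
            logger.warning("result cache %s unreadable; recomputing", result_path)

    frontend = FrontEndConfig(**config.frontend)
    clips, ann, folds = _resolve_dataset(config.dataset)
    mel_key = fingerprint({"dataset": config.dataset, "frontend": config.frontend})
    mels = _mel_stage(clips, frontend, cache, mel_key)

    extra_learning_mels = None
    if config.feature_learning_extra:
        xclips, _, _ = _resolve_dataset(config.feature_learning_extra)
        xkey = fingerprint({"dataset": config.feature_learning_extra,
                            "frontend": config.frontend})
        extra_learning_mels = list(_mel_stage(xclips, frontend, cache, xkey).values())

    extra_train = None
    if config.training_extra:
        tclips, tann, _ = _resolve_dataset(config.training_extra)
        tkey = fingerprint({"dataset": config.training_extra, "frontend": config.frontend})
        tmels = _mel_stage(tclips, frontend, cache, tkey)
        tann = AnnotationSet(items=tann.items, vocabulary=list(ann.vocabulary),
                             mode=ann.mode)
        extra_train = (tmels, tann)

    run_cfg = {"feature": config.feature, "noise_reduction": config.noise_reduction,
               "classifier_mode": config.classifier_mode,
               "window_s": config.window_s, "pool": config.pool}
    t0 = time.monotonic()
    result = run_crossvalidation(
        clips, ann, folds, run_cfg, seed=config.seed, k=config.k, mels=mels,
        fit_kwargs={"reservoir_capacity": config.reservoir_capacity},
        extra_learning_mels=extra_learning_mels, extra_train=extra_train)
    logger.info("crossvalidation finished in %.1fs", time.monotonic() - t0)

    payload = dataclasses.asdict(result)
    with open(result_path, "w") as fh:
        json.dump(payload, fh)

    row = {"fingerprint": cfg_fp, **run_cfg, "auc": result.auc, "map": result.map,
           "auc_pooled": result.auc_pooled, "map_pooled": result.map_pooled,
           "auc_macro": result.auc_macro,
           **{f"fold{i}_auc": a for i, (a, _) in enumerate(result.per_fold)},
           **{f"fold{i}_map": m for i, (_, m) in enumerate(result.per_fold)}}
    csv_path = out_dir / "results.csv"
    pd.DataFrame([row]).to_csv(csv_path, mode="a", index=False,
                               header=not csv_path.exists())
    with open(out_dir / f"manifest-{cfg_fp}.json", "w") as fh:
        json.dump({"config": config.to_dict(), "fingerprint": cfg_fp,
                   "n_recordings": len(clips),
                   "train_rows_per_fold": result.train_rows_per_fold,
                   "dictionary_fingerprints": result.dictionary_fingerprints}, fh, indent=1)
    return result
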