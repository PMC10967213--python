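"""Repeated stratified cross-validation with optional external validation.

Internal validation: stratified k-fold, repeated with fresh shuffles; the
model is re-initialized and trained from scratch in every fold, scored on
the held-out fifth, and — when an external dataset is supplied — also
scored on that fully untouched cohort before the fold ends. With the
defaults (k=5, 10 repeats) this yields 50 internal and 50 external AUCs.

Seed handling: one master seed feeds a ``numpy`` SeedSequence from which
per-repeat fold shuffles and per-fold model-init seeds are spawned, so a
run is reproducible end to end and every seed is recorded in the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, SurvConvMixer, train_model
from .imaging import ImageLayout


class ValidationError(ValueError):
    pass


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the normalized Mann-Whitney U.

    Ties between a positive and a negative score count 1/2. Requires both
    classes present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("scores and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC undefined: only one class present")
    return float(roc_auc_score(y, s))


@dataclass
class ValidationResult:
    """All per-fold AUCs plus their summaries and the seeds that made them."""

    internal_aucs: list[float]
    external_aucs: list[float]
    k: int
    repeats: int
    master_seed: int
    fold_seeds: list[int] = field(default_factory=list)

    @property
    def internal_mean(self) -> float:
        return float(np.mean(self.internal_aucs))

    @property
    def internal_sd(self) -> float:
        return float(np.std(self.internal_aucs, ddof=1)) if len(self.internal_aucs) > 1 else 0.0

    @property
    def external_mean(self) -> float:
        return float(np.mean(self.external_aucs)) if self.external_aucs else float("nan")

    @property
    def external_sd(self) -> float:
        return float(np.std(self.external_aucs, ddof=1)) if len(self.external_aucs) > 1 else 0.0

    def summary(self) -> dict:
        out = {
            "k": self.k,
            "repeats": self.repeats,
            "n_folds": len(self.internal_aucs),
            "internal_mean_auc": self.internal_mean,
            "internal_sd_auc": self.internal_sd,
        }
        if self.external_aucs:
            out["external_mean_auc"] = self.external_mean
            out["external_sd_auc"] = self.external_sd
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                **self.summary(),
                "master_seed": self.master_seed,
                "fold_seeds": self.fold_seeds,
                "internal_aucs": self.internal_aucs,
                "external_aucs": self.external_aucs,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def default_model_factory(cfg: ModelConfig) -> Callable[[np.ndarray, np.ndarray, ImageLayout, int], SurvConvMixer]:
    """Train-from-scratch factory used by :func:`repeated_cv`."""

    def fit(images: np.ndarray, labels: np.ndarray, layout: ImageLayout, seed: int) -> SurvConvMixer:
        fold_cfg = ModelConfig(**{**cfg.to_dict(), "seed": seed})
        model, _ = train_model(images, labels, fold_cfg, layout)
        return model

    return fit


def repeated_cv(
    images: np.ndarray,
    labels: Sequence[int],
    layout: ImageLayout,
    model_factory: Callable[[np.ndarray, np.ndarray, ImageLayout, int], SurvConvMixer],
    k: int = 5,
    repeats: int = 10,
    external: tuple[np.ndarray, Sequence[int]] | None = None,
    seed: int = 0,
) -> ValidationResult:
    """Repeated stratified k-fold CV; returns k*repeats internal (and external) AUCs.

    Stratification guarantees both classes in every fold (the AUC is
    otherwise undefined). External samples never enter any training split.
    """
    images = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(
            f"class counts {counts.tolist()} too small for stratified {k}-fold CV"
        )
    ext_images = ext_labels = None
    if external is not None:
        ext_images = np.asarray(external[0], dtype=float)
        ext_labels = np.asarray(external[1], dtype=int)
        if len(np.unique(ext_labels)) < 2:
            raise ValidationError("external set must contain both classes")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(repeats * (k + 1))]
    internal: list[float] = []
    ext_aucs: list[float] = []
    fold_seeds: list[int] = []
    si = 0
    for rep in range(repeats):
        shuffle_seed = child_seeds[si]; si += 1
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=shuffle_seed)
        for train_idx, val_idx in skf.split(images.reshape(len(y), -1), y):
            assert not set(train_idx) & set(val_idx)
            init_seed = child_seeds[si]; si += 1
            fold_seeds.append(init_seed)
            model = model_factory(images[train_idx], y[train_idx], layout, init_seed)
            internal.append(auc(model.predict(images[val_idx]), y[val_idx]))
            if ext_images is not None:
                ext_aucs.append(auc(model.predict(ext_images), ext_labels))
    return ValidationResult(
        internal_aucs=internal,
        external_aucs=ext_aucs,
        k=k,
        repeats=repeats,
        master_seed=seed,
        fold_seeds=fold_seeds,
    )
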