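"""Flux-feature assembly (NaN padding over the reaction union) and the
random-forest classification protocol (1000 Gini trees, balanced class
weights, stratified 80/20 split, 8-fold CV on the training part, OOB score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .contextualize import ContextModel, FluxProfile
from .expression import CANCER, HEALTHY


@dataclass
class FeatureMatrix:
    """Samples x reaction-union flux matrix; a cell is NaN iff the reaction
    is absent from that sample's context model."""

    values: pd.DataFrame  # index: sample ids, columns: reaction ids (sorted)
    labels: dict[str, str]
    origin: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def label_vector(self) -> np.ndarray:
        """healthy = 0, cancer = 1."""
        return np.array([1 if self.labels[s] == CANCER else 0 for s in self.sample_ids])


def assemble_features(
    models: list[tuple[ContextModel, FluxProfile]],
    labels: dict[str, str],
    origin: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Union feature list in lexicographic order; fluxes of active reactions,
    NaN padding where a reaction is missing from a sample's model."""
    if len(models) < 2:
        raise ValueError("need >= 2 samples to assemble features")
    sample_ids = [cm.sample_id for cm, _ in models]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    union = sorted(set().union(*(cm.active_reactions for cm, _ in models)))
    rows = []
    for cm, fp in models:
        row = [fp.fluxes[r] if r in cm.active_reactions else np.nan for r in union]
        rows.append(row)
    values = pd.DataFrame(rows, index=sample_ids, columns=union)
    return FeatureMatrix(
        values=values,
        labels={s: labels[s] for s in sample_ids},
        origin={s: (origin or {}).get(s, "real") for s in sample_ids},
    )


def impute_missing(fm: FeatureMatrix, strategy: str = "zero") -> FeatureMatrix:
    """zero: an absent reaction carries no flux.  sentinel: fill with a value
    below the observed range (min - 1.5 * range) so trees can isolate absence."""
    if strategy == "zero":
        filled = fm.values.fillna(0.0)
    elif strategy == "sentinel":
        arr = fm.values.to_numpy()
        observed = arr[~np.isnan(arr)]
        lo, hi = (observed.min(), observed.max()) if observed.size else (0.0, 0.0)
        filled = fm.values.fillna(lo - 1.5 * (hi - lo))
    else:
        raise ValueError(f"unknown missing-value strategy {strategy!r}")
    return FeatureMatrix(values=filled, labels=dict(fm.labels), origin=dict(fm.origin))


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 1000
    split_criterion: str = "gini"
    class_weight: str = "balanced"
    test_fraction: float = 0.2
    cv_folds: int = 8
    oob: bool = True
    missing_strategy: str = "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClassifierReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> precision/recall/f1
    confusion: list[list[int]]  # rows true, cols predicted; [healthy, cancer]
    cv_scores: list[float]
    cv_mean: float
    cv_sd: float
    oob_score: float | None
    misclassified: list[dict]  # sample_id, true, predicted, origin
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "cv_scores": self.cv_scores,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "oob_score": self.oob_score,
            "misclassified": self.misclassified,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def train_rf(
    fm: FeatureMatrix, cfg: RFConfig = RFConfig()
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Stratified 80/20 split, forest fit on the training part, held-out
    report, stratified k-fold CV on the training part, OOB from the forest."""
    y = fm.label_vector()
    if len(set(y)) < 2:
        raise ValueError("both classes must be present to train")
    fm = impute_missing(fm, cfg.missing_strategy)
    X = fm.values.to_numpy()
    samples = np.array(fm.sample_ids)

    X_tr, X_te, y_tr, y_te, s_tr, s_te = train_test_split(
        X,
        y,
        samples,
        test_size=cfg.test_fraction,
        stratify=y,
        random_state=cfg.seed,
        shuffle=True,
    )
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        class_weight=cfg.class_weight,
        oob_score=cfg.oob,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X_tr, y_tr)

    y_pred = model.predict(X_te)
    acc = float((y_pred == y_te).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_te, y_pred, labels=[0, 1], zero_division=0
    )
    per_class = {
        HEALTHY: {"precision": float(prec[0]), "recall": float(rec[0]), "f1": float(f1[0])},
        CANCER: {"precision": float(prec[1]), "recall": float(rec[1]), "f1": float(f1[1])},
    }
    conf = confusion_matrix(y_te, y_pred, labels=[0, 1]).tolist()

    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    cv_model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        n_jobs=1,
    )
    cv_scores = cross_val_score(cv_model, X_tr, y_tr, cv=cv).tolist()

    mis = [
        {
            "sample_id": str(s),
            "true": HEALTHY if yt == 0 else CANCER,
            "predicted": HEALTHY if yp == 0 else CANCER,
            "origin": fm.origin.get(str(s), "real"),
        }
        for s, yt, yp in zip(s_te, y_te, y_pred)
        if yt != yp
    ]

    report = ClassifierReport(
        accuracy=acc,
        per_class=per_class,
        confusion=conf,
        cv_scores=[float(v) for v in cv_scores],
        cv_mean=float(np.mean(cv_scores)),
        cv_sd=float(np.std(cv_scores)),
        oob_score=float(model.oob_score_) if cfg.oob else None,
        misclassified=mis,
        n_train=len(y_tr),
        n_test=len(y_te),
    )
    return model, report
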