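"""Classifier evaluation with leave-one-chemical-out cross-validation.

The fold unit is the chemical: for each chemical the model is trained on
all other chemicals' biomarker profiles and emits a probability-of-NGHC
score for the held-out chemical; the AUC is computed from the pooled
out-of-fold scores (Mann-Whitney convention, ties count one half).

Seven classifier families are exposed under short tags: decision tree
(``dt``), bagged trees (``bagging``), boosted trees (``boosting``),
k-nearest neighbours (``knn``), naive Bayes (``nb``), support vector
machine (``svm``) and random forest (``rf``). Hyperparameters other than
the RF tree count are library defaults; the RF uses sqrt(n_features) per
split and its tree count can be selected on the same LOOCV grid 10..100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .consensus import BiomarkerSet
from .deg import ChemicalProfileMatrix
from .errors import ValidationError
from .io import CLASS_NEGATIVE, CLASS_POSITIVE

logger = logging.getLogger(__name__)

ALGORITHMS = ("dt", "bagging", "boosting", "knn", "nb", "svm", "rf")

#: RF tree-count selection grid.
DEFAULT_TREE_GRID = tuple(range(10, 101, 10))


@dataclass
class FeatureTable:
    """Chemicals x biomarker-genes matrix of log2 ratios with labels."""

    X: pd.DataFrame
    y: pd.Series
    dataset_id: str = ""
    exposure_style: str = ""

    def validate(self) -> "FeatureTable":
        if not self.X.index.equals(self.y.index):
            raise ValidationError(
                f"features {self.dataset_id}/{self.exposure_style}: X rows and "
                "labels are misaligned"
            )
        if self.X.isna().any().any():
            raise ValidationError(
                f"features {self.dataset_id}/{self.exposure_style}: missing cells"
            )
        counts = self.y.value_counts()
        for cls in (CLASS_POSITIVE, CLASS_NEGATIVE):
            if counts.get(cls, 0) < 1:
                raise ValidationError(
                    f"features {self.dataset_id}/{self.exposure_style}: no "
                    f"chemical of class {cls}"
                )
        return self


@dataclass
class CvResult:
    """Per-chemical out-of-fold scores and the resulting AUC."""

    dataset_id: str
    exposure_style: str
    algorithm: str
    scores: pd.Series
    labels: pd.Series
    auc: float
    n_trees_selected: int | None = None

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "exposure_style": self.exposure_style,
            "algorithm": self.algorithm,
            "scores": {str(k): float(v) for k, v in self.scores.items()},
            "labels": {str(k): str(v) for k, v in self.labels.items()},
            "auc": float(self.auc),
            "n_trees_selected": self.n_trees_selected,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CvResult":
        return cls(
            dataset_id=raw["dataset_id"],
            exposure_style=raw["exposure_style"],
            algorithm=raw["algorithm"],
            scores=pd.Series(raw["scores"], dtype=float),
            labels=pd.Series(raw["labels"], dtype=object),
            auc=float(raw["auc"]),
            n_trees_selected=raw.get("n_trees_selected"),
        )


def build_features(
    profiles: ChemicalProfileMatrix, biomarker_set: BiomarkerSet
) -> FeatureTable:
    """Restrict a profile matrix to a biomarker set's genes.

    Genes absent from the platform are dropped and logged; zero overlap is
    an error. Column values are the profile entries, untransformed.
    """
    present = [g for g in biomarker_set.genes if g in profiles.profiles.index]
    absent = [g for g in biomarker_set.genes if g not in profiles.profiles.index]
    if not present:
        raise ValidationError(
            f"build_features: no gene of set {biomarker_set.name} is measured "
            f"in {profiles.dataset_id}/{profiles.exposure_style}"
        )
    if absent:
        logger.info(
            "build_features: %s/%s: dropped %d absent gene(s): %s",
            profiles.dataset_id,
            profiles.exposure_style,
            len(absent),
            absent,
        )
    X = profiles.profiles.loc[present].T
    y = profiles.labels.loc[X.index]
    return FeatureTable(
        X, y, profiles.dataset_id, profiles.exposure_style
    ).validate()


def make_classifier(algorithm: str, seed: int = 0, params: Mapping | None = None):
    """Instantiate a classifier by tag; ``params`` overrides defaults."""
    params = dict(params or {})
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(), random_state=seed, **params
        )
    if algorithm == "boosting":
        return AdaBoostClassifier(random_state=seed, **params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "nb":
        return GaussianNB(**params)
    if algorithm == "svm":
        return SVC(kernel=params.pop("kernel", "linear"), random_state=seed, **params)
    if algorithm == "rf":
        n_trees = params.pop("n_trees", 100)
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed,
            **params,
        )
    raise ValidationError(
        f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
    )


def auc_from_scores(labels: Sequence[str], scores: Sequence[float]) -> float:
    """AUC of probability-of-NGHC scores (ties contribute one half)."""
    y = np.asarray([1 if lab == CLASS_POSITIVE else 0 for lab in labels])
    if y.min() == y.max():
        raise ValidationError("auc_from_scores: need both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _fit_and_score(estimator, X_train, y_train, X_test) -> np.ndarray:
    """Fit and emit probability-of-NGHC scores for X_test.

    Margin-based learners without predict_proba are calibrated into [0, 1]
    by a rank-preserving min-max map of the training decision values, which
    leaves the AUC unchanged.
    """
    estimator.fit(X_train, y_train)
    classes = list(estimator.classes_)
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X_test)
        return proba[:, classes.index(CLASS_POSITIVE)]
    raw = np.atleast_1d(estimator.decision_function(X_test))
    train_raw = np.atleast_1d(estimator.decision_function(X_train))
    # decision_function is oriented toward classes_[1]
    if classes.index(CLASS_POSITIVE) == 0:
        raw, train_raw = -raw, -train_raw
    lo, hi = float(train_raw.min()), float(train_raw.max())
    if hi == lo:
        return np.full(raw.shape, 0.5)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def loocv(
    features: FeatureTable,
    algorithm: str = "rf",
    params: Mapping | None = None,
    seed: int = 0,
) -> CvResult:
    """Leave-one-chemical-out cross-validation.

    Each chemical is scored by a model trained on all other chemicals; a
    degenerate single-class training fold scores 0.5 with a warning. The
    same seed is passed to every fold's estimator, so stochastic learners
    are reproducible.
    """
    features.validate()
    counts = features.y.value_counts()
    for cls in (CLASS_POSITIVE, CLASS_NEGATIVE):
        if counts.get(cls, 0) < 2:
            raise ValidationError(
                f"loocv: need >=2 chemicals per class, got "
                f"{counts.to_dict()}"
            )
    template = make_classifier(algorithm, seed=seed, params=params)
    X = features.X.to_numpy(float)
    y = features.y.to_numpy(object)
    scores = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(set(y_train)) < 2:
            warnings.warn(
                f"loocv: single-class training fold for chemical "
                f"{features.X.index[i]}; scoring 0.5",
                stacklevel=2,
            )
            scores[i] = 0.5
            continue
        scores[i] = _fit_and_score(clone(template), X[mask], y_train, X[i : i + 1])[0]
    score_series = pd.Series(scores, index=features.X.index, name="score")
    auc = auc_from_scores(features.y, score_series)
    n_trees = getattr(template, "n_estimators", None) if algorithm == "rf" else None
    return CvResult(
        features.dataset_id,
        features.exposure_style,
        algorithm,
        score_series,
        features.y.copy(),
        auc,
        n_trees_selected=n_trees,
    )


def select_n_trees(
    features: FeatureTable,
    grid: Iterable[int] = DEFAULT_TREE_GRID,
    seed: int = 0,
    params: Mapping | None = None,
) -> int:
    """Pick the RF tree count with the best LOOCV AUC (ties -> smaller)."""
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValidationError("select_n_trees: empty grid")
    best_count, best_auc = None, -np.inf
    for count in grid:
        run_params = dict(params or {})
        run_params["n_trees"] = count
        auc = loocv(features, "rf", params=run_params, seed=seed).auc
        if auc > best_auc:
            best_count, best_auc = count, auc
    logger.info(
        "select_n_trees: %s/%s: chose %d trees (LOOCV AUC %.3f)",
        features.dataset_id,
        features.exposure_style,
        best_count,
        best_auc,
    )
    return int(best_count)
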