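"""Stage 1: boosted classification of mitochondrial proteins.

Proteomic surveys of purified mitochondria are individually noisy —
contaminants co-purify and genuine residents are missed — so membership
calls are made by boosting over the binary detection profile of each
protein across experiments: AdaBoost.M1 with one-feature decision
stumps, evaluated by stratified 10-fold cross-validation against
curated gold-standard positive (GSP) and negative (GSN) gene sets.
Proteins outside the high-confidence call are tiered by a voting
policy: middle confidence if listed in a reference compendium or
detected in more than ``vote_threshold`` experiments, low otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Set

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric was requested with a zero denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positives")
    return c.TP / (c.TP + c.FN)


def fdr(c: ConfusionCounts) -> float:
    """False discovery rate FP / (FP + TP)."""
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("FDR undefined: no predicted positives")
    return c.FP / (c.FP + c.TP)


def validate_detection_matrix(matrix: pd.DataFrame) -> None:
    """Enforce the detection-matrix contract: binary values, unique ids."""
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in detection matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate dataset identifiers in detection matrix")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("detection matrix values must be 0/1")


def train_boosted_classifier(matrix: pd.DataFrame, labels: pd.Series,
                             rounds: int = 50, seed: int = 0) -> AdaBoostClassifier:
    """Fit AdaBoost.M1 over depth-1 decision stumps on detection profiles.

    ``labels`` gives 1 for GSP and 0 for GSN genes (a subset of the
    matrix rows).  The fitted model exposes its weak learners
    (``estimators_``) and their vote weights (``estimator_weights_``).
    Deterministic given seed and input order.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    validate_detection_matrix(matrix)
    labels = labels.reindex(matrix.index).dropna()
    if labels.nunique() < 2:
        raise ValueError("training labels must contain both classes")
    X = matrix.loc[labels.index].to_numpy()
    y = labels.to_numpy().astype(int)
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=rounds,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def crossvalidate_10fold(matrix: pd.DataFrame, labels: pd.Series,
                         rounds: int = 50, seed: int = 0,
                         n_folds: int = 10):
    """Stratified k-fold CV of the boosted classifier on labeled genes.

    Returns (aggregated ConfusionCounts, per-fold metrics DataFrame).
    Each fold serves once as the test set; counts are summed across
    folds so the aggregate sensitivity/FDR use every labeled gene once.
    """
    labels = labels.reindex(matrix.index).dropna()
    y = labels.to_numpy().astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise ValueError(f"need >= {n_folds} labeled genes per class")
    X = matrix.loc[labels.index].to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    total = ConfusionCounts(0, 0, 0, 0)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=rounds, random_state=seed,
        )
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        c = ConfusionCounts(
            TP=int(((pred == 1) & (truth == 1)).sum()),
            FP=int(((pred == 1) & (truth == 0)).sum()),
            FN=int(((pred == 0) & (truth == 1)).sum()),
            TN=int(((pred == 0) & (truth == 0)).sum()),
        )
        total = total + c
        rows.append({"fold": fold, "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN})
    return total, pd.DataFrame(rows)


def predict_membership(model: AdaBoostClassifier, matrix: pd.DataFrame) -> pd.Series:
    """Classify every gene in the matrix; 1 = mitochondrial call."""
    return pd.Series(model.predict(matrix.to_numpy()).astype(int), index=matrix.index)


def assemble_inventory(predictions: pd.Series, gsp: Set[str],
                       reference_members: Set[str], matrix: pd.DataFrame,
                       vote_threshold: int = 5) -> pd.Series:
    """Assign every gene a confidence tier: high, middle or low.

    High confidence = classifier positives plus curated restoration of
    any GSP gene the classifier missed.  Among the remainder, middle
    confidence requires reference-compendium membership or detection in
    strictly more than ``vote_threshold`` experiments; everything else
    is low confidence.
    """
    genes = matrix.index
    predictions = predictions.reindex(genes).fillna(0).astype(int)
    counts = matrix.sum(axis=1)
    tiers = {}
    for g in genes:
        if predictions[g] == 1 or g in gsp:
            tiers[g] = "high"
        elif g in reference_members or counts[g] > vote_threshold:
            tiers[g] = "middle"
        else:
            tiers[g] = "low"
    return pd.Series(tiers, index=genes, name="tier")


def inventory_report(tiers: pd.Series, matrix: pd.DataFrame, gsp: Set[str],
                     reference_members: Set[str]) -> pd.DataFrame:
    """Per-gene tier table with detection counts and evidence flags."""
    return pd.DataFrame({
        "gene": tiers.index,
        "tier": tiers.values,
        "detection_count": matrix.sum(axis=1).reindex(tiers.index).values,
        "in_gsp": [int(g in gsp) for g in tiers.index],
        "in_reference": [int(g in reference_members) for g in tiers.index],
    })
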