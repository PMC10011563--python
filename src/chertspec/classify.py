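"""Supervised domain classification of preprocessed spectra.

Protocol: specimens of unknown affinity are set aside; the labelled
remainder is split 60/40 (stratified on group, seed-controlled), and three
learners are fitted on the training block — logistic regression with L2
ridge (C = 1), k-nearest neighbours (Euclidean, k = 5) and a random forest
of 50 trees.  Each is evaluated by leave-one-out cross-validation on the
training block (accuracy and ROC-AUC from held-out scores) and then on the
test block, and finally asked to predict the unknowns; when all three
agree, the consensus verdict is reported.

The whole protocol is reproducible bit-for-bit from (matrix, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier

LEARNERS = ("logistic_regression", "knn", "random_forest")


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    excluded_ids: list[str]
    fraction: float
    seed: int
    stratified: bool = True


def split_train_test(
    labels: pd.Series,
    fraction: float = 0.6,
    seed: int = 0,
    exclude_labels: Sequence[str] = ("unknown",),
    max_attempts: int = 100,
) -> SplitSpec:
    """Stratified random train/test split of labelled specimens.

    `labels` maps specimen_id -> group; specimens labelled in
    `exclude_labels` (or unlabelled) are excluded and later treated as
    unknowns.  The training count is ceil(n * fraction), so 47 labelled
    specimens at fraction 0.6 give a 29/18 split.  Stratification allocates
    per class proportionally; a draw leaving a class absent from either
    side is redrawn up to `max_attempts` times.
    """
    labels = pd.Series(labels)
    excluded = list(labels.index[labels.isna() | labels.isin(exclude_labels)])
    labelled = labels.drop(excluded)
    n = len(labelled)
    if n < 2:
        raise ValueError("need at least 2 labelled specimens to split")
    n_train = int(np.ceil(n * fraction - 1e-9))
    if n_train >= n:
        raise ValueError("empty test set: lower the training fraction")
    if n_train < 1:
        raise ValueError("empty training set: raise the training fraction")
    rng = np.random.default_rng(seed)
    classes = sorted(labelled.unique())
    for _ in range(max_attempts):
        train: list[str] = []
        # proportional allocation per class, largest-remainder on the rest
        sizes = {}
        for c in classes:
            ids = list(labelled.index[labelled == c])
            sizes[c] = (ids, len(ids) * fraction)
        floors = {c: int(np.floor(v)) for c, (_, v) in sizes.items()}
        remainder = n_train - sum(floors.values())
        by_frac = sorted(classes, key=lambda c: sizes[c][1] - floors[c], reverse=True)
        for c in by_frac[:remainder]:
            floors[c] += 1
        for c in classes:
            ids, _ = sizes[c]
            take = min(floors[c], len(ids))
            train.extend(rng.choice(ids, size=take, replace=False).tolist())
        test = [i for i in labelled.index if i not in set(train)]
        tr_classes = set(labelled.loc[train])
        te_classes = set(labelled.loc[test])
        if tr_classes == set(classes) == te_classes:
            return SplitSpec(
                train_ids=sorted(train), test_ids=sorted(test),
                excluded_ids=excluded, fraction=fraction, seed=seed,
            )
    raise ValueError(
        f"could not draw a split with every class on both sides in "
        f"{max_attempts} attempts"
    )


def _make_learners(seed: int | None) -> dict:
    return {
        # L2 ridge is sklearn's default penalty
        "logistic_regression": LogisticRegression(C=1.0, max_iter=5000),
        "knn": KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
        "random_forest": RandomForestClassifier(n_estimators=50, random_state=seed),
    }


def train_models(
    X: pd.DataFrame, y: pd.Series, seed: int | None = 0
) -> dict:
    """Fit the three learners on identical features; returns name -> model."""
    y = pd.Series(y).loc[X.index]
    if y.nunique() < 2:
        raise ValueError("training set has a single class")
    if len(X) < 6:
        raise ValueError("need >= 6 training rows (kNN with 5 neighbours)")
    models = _make_learners(seed)
    for m in models.values():
        m.fit(X.to_numpy(dtype=float), y.to_numpy())
    return models


def _positive_scores(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Score for the lexicographically last class (consistent AUC direction)."""
    proba = model.predict_proba(X)
    pos = list(model.classes_).index(sorted(classes)[-1])
    return proba[:, pos]


def loo_cv(
    X: pd.DataFrame, y: pd.Series, learner: str, seed: int | None = 0
) -> tuple[float, float]:
    """Leave-one-out cross-validation: (accuracy, ROC-AUC) from held-out scores.

    Scores are class probabilities for the logistic regression and random
    forest and neighbour-vote fractions for kNN (5 neighbours give 6 score
    levels, so the kNN ROC curve is step-like).
    """
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}")
    y = pd.Series(y).loc[X.index]
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    Xa = X.to_numpy(dtype=float)
    ya = y.to_numpy()
    classes = np.unique(ya)
    preds = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    positive = sorted(classes)[-1]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_classes = np.unique(ya[mask])
        if len(fold_classes) == 1:
            # the held-out specimen was the only member of its class
            preds[i] = fold_classes[0]
            scores[i] = 1.0 if fold_classes[0] == positive else 0.0
            continue
        model = _make_learners(seed)[learner]
        model.fit(Xa[mask], ya[mask])
        preds[i] = model.predict(Xa[i: i + 1])[0]
        scores[i] = _positive_scores(model, Xa[i: i + 1], classes)[0]
    acc = float((preds == ya).mean())
    if len(classes) == 2:
        auc = float(roc_auc_score((ya == sorted(classes)[-1]).astype(int), scores))
    else:
        auc = float("nan")
    return acc, auc


def evaluate_on_test(
    models: Mapping[str, object], X_test: pd.DataFrame, y_test: pd.Series
) -> pd.DataFrame:
    """Test-block accuracy and ROC-AUC per model, plus per-specimen predictions.

    With a single-class test block AUC is undefined and reported as NaN.
    Returns a frame indexed by learner with columns accuracy/roc_auc and a
    ``predictions`` DataFrame attached under ``.attrs``.
    """
    y_test = pd.Series(y_test).loc[X_test.index]
    Xa = X_test.to_numpy(dtype=float)
    ya = y_test.to_numpy()
    classes = np.unique(ya)
    rows = {}
    pred_cols = {}
    for name, model in models.items():
        pred = model.predict(Xa)
        acc = float((pred == ya).mean())
        if len(classes) == 2:
            s = _positive_scores(model, Xa, classes)
            auc = float(roc_auc_score((ya == sorted(classes)[-1]).astype(int), s))
        else:
            auc = float("nan")
        rows[name] = {"accuracy": acc, "roc_auc": auc}
        pred_cols[name] = pred
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "learner"
    preds = pd.DataFrame(pred_cols, index=X_test.index)
    preds["truth"] = ya
    report.attrs["predictions"] = preds
    return report


def predict_unknowns(
    models: Mapping[str, object], X_unknown: pd.DataFrame
) -> pd.DataFrame:
    """Per-model class predictions for unknowns with a consensus verdict.

    The returned frame has one row per unknown specimen, one column per
    model plus ``consensus`` ("no consensus" when models disagree).
    """
    if len(X_unknown) == 0:
        raise ValueError("empty unknown set")
    Xa = X_unknown.to_numpy(dtype=float)
    cols = {name: model.predict(Xa) for name, model in models.items()}
    df = pd.DataFrame(cols, index=X_unknown.index)
    df["consensus"] = [
        row.iloc[0] if row.nunique() == 1 else "no consensus"
        for _, row in df.iterrows()
    ]
    return df


@dataclass
class ClassifierReport:
    split: SplitSpec
    loo: pd.DataFrame                   # learner x (accuracy, roc_auc)
    test: pd.DataFrame                  # learner x (accuracy, roc_auc)
    unknown_predictions: pd.DataFrame | None


def run_supervised_protocol(
    matrix: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    fraction: float = 0.6,
    seed: int = 0,
    exclude_labels: Sequence[str] = ("unknown",),
) -> ClassifierReport:
    """The full supervised protocol on a feature matrix with group labels."""
    labels = pd.Series(dict(labels)).reindex(matrix.index)
    split = split_train_test(labels, fraction, seed, exclude_labels)
    X_tr = matrix.loc[split.train_ids]
    y_tr = labels.loc[split.train_ids]
    models = train_models(X_tr, y_tr, seed=seed)
    loo = pd.DataFrame(
        {name: dict(zip(("accuracy", "roc_auc"), loo_cv(X_tr, y_tr, name, seed)))
         for name in LEARNERS}
    ).T
    loo.index.name = "learner"
    test = evaluate_on_test(models, matrix.loc[split.test_ids], labels)
    unknown = None
    if split.excluded_ids:
        unknown = predict_unknowns(models, matrix.loc[split.excluded_ids])
    return ClassifierReport(split=split, loo=loo, test=test,
                            unknown_predictions=unknown)
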