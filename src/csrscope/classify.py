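"""Downstream per-sample analysis: z-scoring, PCA projection, ridge
classification.

Feature tables are normalized per feature to mean 0 / sd 1; held-out data
are normalized independently with their *own* parameters and then rotated
into the principal-component space fitted on the training set.  Genotype /
diagnosis prediction uses L2-regularized (multinomial) logistic regression
with the regularizer chosen by stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class ZScoreParams:
    mean: pd.Series
    std: pd.Series
    kept: list[str]  # features with non-zero variance


def zscore(table: pd.DataFrame, params: ZScoreParams | None = None
           ) -> tuple[pd.DataFrame, ZScoreParams]:
    """Per-feature standardization (constant features dropped with warning).

    With ``params`` given, applies the stored normalization instead of
    fitting (used to reproduce the training normalization exactly).
    """
    if params is None:
        mean = table.mean()
        std = table.std(ddof=0)
        kept = list(table.columns[std > 0])
        dropped = [c for c in table.columns if c not in kept]
        if dropped:
            log.warning("dropping %d constant features: %s", len(dropped), dropped)
        params = ZScoreParams(mean[kept], std[kept], kept)
    normalized = (table[params.kept] - params.mean) / params.std
    return normalized, params


@dataclass
class PCAResult:
    components: np.ndarray  # n_components x n_features (rotation)
    explained_variance: np.ndarray
    train_scores: pd.DataFrame
    test_scores: pd.DataFrame | None
    features: list[str]


def pca_fit_project(train: pd.DataFrame, test: pd.DataFrame | None = None,
                    n_components: int | None = None) -> PCAResult:
    """Fit principal components on the (normalized) training table and
    rotate independently-normalized test samples into the same space."""
    train_n, params = zscore(train)
    n_components = n_components or min(train_n.shape)
    pca = PCA(n_components=n_components)
    pca.fit(train_n.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    train_scores = pd.DataFrame(train_n.to_numpy() @ pca.components_.T,
                                index=train.index, columns=cols)
    test_scores = None
    if test is not None:
        test_n, _ = zscore(test[params.kept])
        test_n = test_n.reindex(columns=params.kept).fillna(0.0)
        test_scores = pd.DataFrame(test_n.to_numpy() @ pca.components_.T,
                                   index=test.index, columns=cols)
    return PCAResult(pca.components_, pca.explained_variance_, train_scores,
                     test_scores, params.kept)


@dataclass
class RidgeResult:
    classes: np.ndarray
    probabilities: pd.DataFrame  # test samples x classes
    predictions: pd.Series
    coefficients: pd.DataFrame  # classes x features
    regularization: float
    cv_accuracy: float


def ridge_classify(train_X: pd.DataFrame, train_y: pd.Series,
                   test_X: pd.DataFrame | None = None,
                   n_folds: int | None = None, seed: int = 0,
                   Cs: int = 10) -> RidgeResult:
    """Cross-validated L2 logistic regression on z-scored features.

    Training and test tables are normalized independently.  Fold count
    defaults to min(10, smallest class size).  The argmax of the class
    probabilities decides the label.
    """
    y = np.asarray(train_y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >=2 classes with >=2 samples each")
    n_folds = n_folds or min(10, int(counts.min()))
    train_n, params = zscore(train_X)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(Cs=Cs, cv=cv, max_iter=5000,  # L2 default
                                 scoring="accuracy", random_state=seed)
    model.fit(train_n.to_numpy(), y)
    # mean CV accuracy at the selected regularizer
    scores = next(iter(model.scores_.values()))  # folds x Cs (shared)
    best_idx = int(np.argmax(scores.mean(axis=0)))
    cv_acc = float(scores.mean(axis=0)[best_idx])
    if test_X is not None:
        test_n, _ = zscore(test_X[params.kept])
        test_n = test_n.reindex(columns=params.kept).fillna(0.0)
        probs = model.predict_proba(test_n.to_numpy())
        index = test_X.index
    else:
        probs = model.predict_proba(train_n.to_numpy())
        index = train_X.index
    prob_df = pd.DataFrame(probs, index=index, columns=model.classes_)
    preds = prob_df.idxmax(axis=1)
    coef = pd.DataFrame(model.coef_, columns=params.kept,
                        index=(model.classes_ if model.coef_.shape[0] > 1
                               else [model.classes_[1]]))
    return RidgeResult(model.classes_, prob_df, preds, coef,
                       float(np.ravel(model.C_)[0]), cv_acc)
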