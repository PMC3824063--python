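"""Random-forest classification of precursor candidates.

The ensemble follows a specific protocol: 1000 binary decision trees,
each grown on a bag of 66% of the training precursors drawn *without*
replacement and restricted to 3 of the 10 features drawn without
replacement — the feature subset is fixed per tree, not per split.
Out-of-bag (OOB) votes for a training sample aggregate only the trees
whose bag excluded that sample, giving an unbiased accuracy estimate
and the confusion matrix. Feature importance is the mean decrease in
OOB accuracy after permuting one feature's values among each tree's
OOB samples.

Individual trees are scikit-learn ``DecisionTreeClassifier``s grown
to purity with Gini splits; the bagging, feature subsetting, OOB
aggregation and permutation importance are implemented here because
they differ from the conventional bootstrap/per-split-mtry forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class ForestConfig:
    n_trees: int = 1000
    bag_fraction: float = 0.66
    features_per_tree: int = 3
    vote_threshold: float = 0.5
    per_split: bool = False  # variant: mtry=3 at every split instead of per tree
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bag_fraction < 1:
            raise ValueError("bag_fraction must be in (0, 1)")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def class_errors(self) -> dict[str, float]:
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        return {
            POSITIVE: self.fn / pos if pos else float("nan"),
            NEGATIVE: self.fp / neg if neg else float("nan"),
        }


@dataclass
class _Tree:
    clf: DecisionTreeClassifier
    feature_idx: np.ndarray  # columns used by this tree
    bag_mask: np.ndarray  # boolean, True where the sample was in the bag


@dataclass
class ForestModel:
    config: ForestConfig
    trees: list[_Tree] = field(repr=False, default_factory=list)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    oob_votes: np.ndarray | None = None  # positive-vote fraction per training sample
    oob_accuracy: float = float("nan")
    confusion: ConfusionMatrix | None = None
    _train_X: np.ndarray | None = field(repr=False, default=None)
    _train_y: np.ndarray | None = field(repr=False, default=None)


def _extract_xy(matrix: pd.DataFrame, feature_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in feature_names if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    X = matrix[list(feature_names)].to_numpy(dtype=float)
    y = (matrix["label"].to_numpy() == POSITIVE).astype(int)
    return X, y


def train(matrix: pd.DataFrame, cfg: ForestConfig | None = None) -> ForestModel:
    """Train the forest on a labeled feature matrix.

    ``matrix`` must carry the ten feature columns plus a ``label``
    column with values "positive"/"negative" and both classes present.
    Fully reproducible given ``cfg.rng_seed``.
    """
    cfg = cfg or ForestConfig()
    X, y = _extract_xy(matrix, FEATURE_COLUMNS)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < 10:
            logger.warning("only %d training samples in class %d", count, cls)

    rng = np.random.default_rng(cfg.rng_seed)
    bag_size = int(np.floor(cfg.bag_fraction * n))
    n_feat = X.shape[1]
    trees: list[_Tree] = []
    for _ in range(cfg.n_trees):
        bag = rng.choice(n, size=bag_size, replace=False)
        if cfg.per_split:
            feats = np.arange(n_feat)
            max_features = cfg.features_per_tree
        else:
            feats = np.sort(rng.choice(n_feat, size=cfg.features_per_tree, replace=False))
            max_features = None
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(X[bag][:, feats], y[bag])
        mask = np.zeros(n, dtype=bool)
        mask[bag] = True
        trees.append(_Tree(clf, feats, mask))

    model = ForestModel(config=cfg, trees=trees, _train_X=X, _train_y=y)
    _compute_oob(model)
    return model


def _compute_oob(model: ForestModel) -> None:
    X, y = model._train_X, model._train_y
    n = len(y)
    pos_votes = np.zeros(n)
    n_votes = np.zeros(n)
    for t in model.trees:
        oob = ~t.bag_mask
        if not oob.any():
            continue
        preds = t.clf.predict(X[np.ix_(oob, t.feature_idx)])
        pos_votes[oob] += preds
        n_votes[oob] += 1
    if (n_votes == 0).any():
        logger.warning("%d training samples were never out of bag", int((n_votes == 0).sum()))
    with np.errstate(invalid="ignore"):
        frac = np.where(n_votes > 0, pos_votes / np.maximum(n_votes, 1), 0.0)
    model.oob_votes = frac
    pred = (frac > model.config.vote_threshold).astype(int)
    model.oob_accuracy = float((pred == y).mean())
    model.confusion = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def importance(model: ForestModel, seed: int | None = None) -> pd.Series:
    """Permutation feature importance: mean decrease in OOB accuracy.

    For every tree and every feature the tree uses, the feature's
    values are permuted among that tree's OOB samples and the drop in
    per-tree OOB accuracy recorded; trees not using the feature
    contribute zero change. Returned sorted descending.
    """
    X, y = model._train_X, model._train_y
    rng = np.random.default_rng(model.config.rng_seed + 1 if seed is None else seed)
    n_feat = X.shape[1]
    decreases = np.zeros(n_feat)
    counts = np.zeros(n_feat)
    for t in model.trees:
        oob = np.flatnonzero(~t.bag_mask)
        if oob.size == 0:
            continue
        Xo = X[np.ix_(oob, t.feature_idx)]
        base_acc = (t.clf.predict(Xo) == y[oob]).mean()
        counts += 1  # every tree contributes to every feature's mean
        for col, f in enumerate(t.feature_idx):
            Xp = Xo.copy()
            Xp[:, col] = Xp[rng.permutation(oob.size), col]
            perm_acc = (t.clf.predict(Xp) == y[oob]).mean()
            decreases[f] += base_acc - perm_acc
    mean_decrease = decreases / np.maximum(counts, 1)
    ser = pd.Series(mean_decrease, index=list(model.feature_names))
    return ser.sort_values(ascending=False)


def classify(model: ForestModel, test_matrix: pd.DataFrame) -> pd.DataFrame:
    """Vote fractions and predicted labels for test candidates.

    A candidate is predicted positive iff its positive-vote fraction
    strictly exceeds the vote threshold (ties are negative).
    """
    if test_matrix.empty:
        return pd.DataFrame(columns=["vote_fraction", "predicted_label"])
    missing = [c for c in model.feature_names if c not in test_matrix.columns]
    if missing:
        raise ValueError(f"test matrix missing columns: {missing}")
    X = test_matrix[list(model.feature_names)].to_numpy(dtype=float)
    votes = np.zeros(len(X))
    for t in model.trees:
        votes += t.clf.predict(X[:, t.feature_idx])
    frac = votes / len(model.trees)
    labels = np.where(frac > model.config.vote_threshold, POSITIVE, NEGATIVE)
    return pd.DataFrame(
        {"vote_fraction": frac, "predicted_label": labels}, index=test_matrix.index
    )
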