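"""Probabilistic tree-ensemble engines behind the habitat models.

The habitat-model pipeline is engine-agnostic: any classifier satisfying
:class:`TreeEnsembleEngine` can be plugged in.  The contract requires
(i) per-draw presence probabilities across the ensemble, from which the
pipeline forms the predictive mean and an uncertainty width, and
(ii) per-variable split counts, from which variable importance is computed
as the proportion of split decisions using each variable.

The default :class:`BaggedTreesEngine` is a seeded bagged ensemble of CART
classification trees; it is fully deterministic given its random state.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.ensemble import RandomForestClassifier


@runtime_checkable
class TreeEnsembleEngine(Protocol):
    """Contract for habitat-model engines (ensemble-of-trees classifiers)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeEnsembleEngine": ...

    def predict_draws(self, X: np.ndarray) -> np.ndarray:
        """(n_draws, n_obs) presence probabilities, one row per ensemble draw."""
        ...

    def split_counts(self) -> np.ndarray:
        """Number of ensemble split decisions using each variable."""
        ...

    def clone(self, random_state: int) -> "TreeEnsembleEngine":
        """Fresh unfitted engine with a new random state (for CV refits)."""
        ...


class BaggedTreesEngine:
    """Bagged CART trees with per-tree probability draws and split counts.

    Each tree is grown on a bootstrap resample considering all features at
    every split, so split counts concentrate on informative predictors.
    ``min_samples_leaf`` regularises the leaf probabilities.
    """

    def __init__(self, n_trees: int = 80, min_samples_leaf: int = 8,
                 max_features: float | None = None, random_state: int = 0):
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self._model: RandomForestClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreesEngine":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        self._model = RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        return self

    def _require_fit(self) -> RandomForestClassifier:
        if self._model is None:
            raise RuntimeError("engine is not fitted")
        return self._model

    def predict_draws(self, X: np.ndarray) -> np.ndarray:
        model = self._require_fit()
        pos = int(np.where(model.classes_ == 1)[0][0])
        return np.stack([est.predict_proba(X)[:, pos] for est in model.estimators_])

    def split_counts(self) -> np.ndarray:
        model = self._require_fit()
        counts = np.zeros(model.n_features_in_)
        for est in model.estimators_:
            feats = est.tree_.feature
            used, n = np.unique(feats[feats >= 0], return_counts=True)
            counts[used] += n
        return counts

    def clone(self, random_state: int) -> "BaggedTreesEngine":
        return BaggedTreesEngine(self.n_trees, self.min_samples_leaf,
                                 self.max_features, random_state)
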