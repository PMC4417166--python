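"""Bagged regression forest with explicit out-of-bag bookkeeping.

A bootstrap-aggregated ensemble of CART regression trees in the style of the
classical randomForest regression defaults: 500 trees, floor(p/3) candidate
features per split, terminal nodes of at least 5 samples.  The bootstrap
sample of every tree is drawn and recorded here (rather than inside the tree
learner) so that permutation importance can be computed tree-by-tree on each
tree's genuine out-of-bag rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = ["ForestConfig", "BaggedRegressionForest"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: int | None = None  # None -> floor(p / 3), min 1
    min_samples_leaf: int = 5

    def resolved_max_features(self, n_features: int) -> int:
        if self.max_features is not None:
            return self.max_features
        return max(1, n_features // 3)


class BaggedRegressionForest:
    """Fit with ``fit``; predict by averaging the per-tree predictions.

    Each tree sees an n-out-of-n bootstrap sample; the complementary rows
    are its out-of-bag (OOB) set, kept in ``oob_indices_``.  Given the seed,
    fitting, prediction and importance are fully deterministic.
    """

    def __init__(self, config: ForestConfig = ForestConfig(), seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_indices_: list[np.ndarray] = []
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedRegressionForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 training rows")
        rng = np.random.default_rng(self.seed)
        mtry = self.config.resolved_max_features(p)
        self.trees_ = []
        self.oob_indices_ = []
        all_rows = np.arange(n)
        for _ in range(self.config.n_trees):
            boot = rng.integers(0, n, size=n)
            inbag = np.zeros(n, dtype=bool)
            inbag[boot] = True
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.config.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(all_rows[~inbag])
        self.X_, self.y_ = X, y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)

    def oob_prediction(self) -> np.ndarray:
        """Per-row mean prediction over the trees that did not train on it
        (NaN for rows that are in-bag everywhere)."""
        n = self.X_.shape[0]
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if oob.size:
                acc[oob] += tree.predict(self.X_[oob])
                cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)

    def permutation_importance(self, scale: bool = True) -> np.ndarray:
        """Per-feature increase in out-of-bag MSE under permutation (%IncMSE).

        For each tree and feature, the tree's OOB MSE is computed before and
        after shuffling that feature's OOB values; the importance is the mean
        increase over trees, divided (when ``scale``) by its standard error
        across trees.  Trees with no OOB rows are excluded
        from the averages for all features.  A feature with identical values
        in every row gets importance exactly 0: permutation changes nothing.
        """
        if self.X_ is None:
            raise RuntimeError("forest is not fitted")
        n, p = self.X_.shape
        rng = np.random.default_rng(self.seed + 1)
        deltas: list[np.ndarray] = []  # one length-p row per usable tree
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if oob.size == 0:
                continue
            X_oob = self.X_[oob]
            y_oob = self.y_[oob]
            base_mse = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
            row = np.zeros(p)
            for j in range(p):
                col = X_oob[:, j]
                if np.all(col == col[0]):
                    continue  # permuting a constant column is a no-op
                perm = rng.permutation(oob.size)
                X_perm = X_oob.copy()
                X_perm[:, j] = col[perm]
                row[j] = float(np.mean((tree.predict(X_perm) - y_oob) ** 2)) - base_mse
            deltas.append(row)
        if not deltas:
            raise RuntimeError("no tree has out-of-bag rows; cannot compute importance")
        D = np.vstack(deltas)
        mean = D.mean(axis=0)
        if not scale:
            return mean
        se = D.std(axis=0, ddof=1) / np.sqrt(D.shape[0]) if D.shape[0] > 1 else np.zeros(p)
        out = np.zeros(p)
        nonzero = se > 0
        out[nonzero] = mean[nonzero] / se[nonzero]
        # zero spread with nonzero mean: infinitely significant by convention
        out[~nonzero & (mean != 0)] = np.sign(mean[~nonzero & (mean != 0)]) * np.inf
        return out
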