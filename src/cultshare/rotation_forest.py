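"""Rotation forest for regression.

An ensemble of unpruned regression trees, each trained on a different random
rotation of feature space: per tree, the features are randomly partitioned
into subsets; for each subset a principal-axis rotation (all components kept)
is fitted on a random instance subsample; the per-subset loadings are
assembled into a block rotation matrix applied to the full training set
before growing the tree.  Predictions average the trees.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = ["RotationForestRegressor"]


class RotationForestRegressor(RegressorMixin, BaseEstimator):
    """Rotation-forest ensemble of regression trees.

    Parameters
    ----------
    n_estimators : number of trees.
    n_feature_subsets : number of disjoint feature subsets per tree; must not
        exceed the number of features.
    sample_fraction : fraction of training instances drawn (without
        replacement) to fit each subset's principal-axis rotation.
    random_state : seed controlling subset draws, subsampling and the trees.
    """

    def __init__(
        self,
        n_estimators: int = 10,
        n_feature_subsets: int = 3,
        sample_fraction: float = 0.75,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.n_feature_subsets = n_feature_subsets
        self.sample_fraction = sample_fraction
        self.max_depth = max_depth
        self.random_state = random_state

    def _rotation(self, X, rng):
        n, p = X.shape
        perm = rng.permutation(p)
        subsets = np.array_split(perm, self.n_feature_subsets)
        R = np.zeros((p, p))
        for sub in subsets:
            n_sub = max(2, int(round(self.sample_fraction * n)))
            rows = rng.choice(n, size=min(n_sub, n), replace=False)
            block = X[np.ix_(rows, sub)]
            if np.allclose(block.std(axis=0), 0.0):
                comps = np.eye(len(sub))
            else:
                pca = PCA(n_components=len(sub), svd_solver="full")
                pca.fit(block)
                comps = pca.components_.T  # columns = principal axes
            R[np.ix_(sub, sub)] = comps
        return R

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] < 2:
            raise ValueError("rotation forest needs at least 2 features")
        if self.n_feature_subsets > X.shape[1]:
            raise ValueError(
                f"n_feature_subsets={self.n_feature_subsets} exceeds "
                f"n_features={X.shape[1]}"
            )
        rng = np.random.default_rng(self.random_state)
        self.rotations_ = []
        self.trees_ = []
        for t in range(self.n_estimators):
            R = self._rotation(X, rng)
            tree = DecisionTreeRegressor(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X @ R, y)
            self.rotations_.append(R)
            self.trees_.append(tree)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "trees_")
        X = check_array(X)
        preds = np.zeros(X.shape[0])
        for R, tree in zip(self.rotations_, self.trees_):
            preds += tree.predict(X @ R)
        return preds / len(self.trees_)
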