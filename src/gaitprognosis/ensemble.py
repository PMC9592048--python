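"""Imbalance-aware tree ensemble and majority-vote hyperparameter search.

The discharge-ambulation cohorts are small and imbalanced (roughly 27
community vs 6 household patients), so the workhorse classifier is a balanced
random forest: every tree is grown on a bootstrap of the minority class paired
with an equal-sized random undersample of the majority class, which makes each
per-tree training multiset exactly class-balanced while the aggregate retains
the full forest's variance reduction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np
from sklearn import config_context
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

#: Feature-subsampling modes searched during tuning.  "auto" is kept as an
#: alias of "sqrt" (the historical library default for classification trees).
MAX_FEATURES_MODES = ("auto", "log2", "sqrt")


@dataclass(frozen=True)
class Hyperparameters:
    """Forest hyperparameters exposed to the randomized search."""

    n_estimators: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features_mode: str = "sqrt"

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.max_features_mode not in MAX_FEATURES_MODES:
            raise ValueError(f"max_features_mode must be one of {MAX_FEATURES_MODES}")

    def to_dict(self) -> dict:
        return asdict(self)

    def estimator_params(self) -> dict:
        """Keyword arguments for :class:`BalancedRandomForestClassifier`."""
        mode = "sqrt" if self.max_features_mode == "auto" else self.max_features_mode
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "min_samples_leaf": self.min_samples_leaf,
            "max_features": mode,
        }


class BalancedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with per-tree balanced undersampling of the majority class.

    Each of the ``n_estimators`` trees is trained on a bootstrap sample (with
    replacement) of the minority class together with an equal-sized random
    undersample (without replacement) of the majority class.  Aggregate
    prediction is the mean of per-tree class probabilities; on an exact
    probability tie the minority class is predicted — for ambulation
    prognosis this is the household class, the clinically conservative call.

    Parameters follow the sklearn tree conventions; ``max_features`` accepts
    "sqrt", "log2", "auto" (alias of "sqrt") or None.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels.
    minority_class_ : scalar
        The class with the smaller training support.
    estimators_ : list of fitted trees (CART regression trees on the 0/1
        class indicator, which is split-for-split identical to Gini
        classification trees for a binary target)
    estimators_sample_indices_ : list of ndarray
        Training-row indices (into the fit X) drawn for each tree.
    feature_importances_ : ndarray
        Mean impurity-decrease importances across trees.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        max_features: str | None = "sqrt",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=np.float32)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"expected exactly 2 classes, got {len(self.classes_)}: {self.classes_!r}"
            )
        counts = np.bincount(y_enc, minlength=2)
        minority = int(np.argmin(counts))
        self.minority_class_ = self.classes_[minority]
        n_min = int(counts[minority])
        idx_min = np.flatnonzero(y_enc == minority)
        idx_maj = np.flatnonzero(y_enc != minority)
        # Trees are grown as regression trees on the 0/1 class indicator:
        # variance reduction on a binary target selects exactly the Gini
        # splits, leaf means are class-1 probabilities, and impurity
        # importances coincide — while skipping per-tree label validation,
        # which dominates runtime at these cohort sizes.
        y_float = y_enc.astype(np.float64)

        rng = check_random_state(self.random_state)
        max_features = "sqrt" if self.max_features == "auto" else self.max_features
        self.estimators_ = []
        self.estimators_sample_indices_ = []
        with config_context(skip_parameter_validation=True):
            for _ in range(self.n_estimators):
                boot_min = rng.choice(idx_min, size=n_min, replace=True)
                under_maj = rng.choice(idx_maj, size=n_min, replace=False)
                rows = np.concatenate([boot_min, under_maj])
                tree = DecisionTreeRegressor(
                    max_depth=self.max_depth,
                    min_samples_split=self.min_samples_split,
                    min_samples_leaf=self.min_samples_leaf,
                    max_features=max_features,
                    random_state=rng.randint(np.iinfo(np.int32).max),
                )
                tree.fit(X[rows], y_float[rows], check_input=False)
                self.estimators_.append(tree)
                self.estimators_sample_indices_.append(rows)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = validate_data(self, X, dtype=np.float32, reset=False)
        X = np.ascontiguousarray(X, dtype=np.float32)
        p1 = np.zeros(X.shape[0])
        for tree in self.estimators_:
            p1 += tree.tree_.predict(X)[:, 0]
        p1 /= len(self.estimators_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        proba = self.predict_proba(X)
        labels = self.classes_[np.argmax(proba, axis=1)]
        ties = proba[:, 0] == proba[:, 1]
        labels[ties] = self.minority_class_
        return labels

    @property
    def feature_importances_(self):
        check_is_fitted(self, "estimators_")
        return np.mean([t.feature_importances_ for t in self.estimators_], axis=0)


def train_balanced_forest(
    X, y, hp: Hyperparameters | None = None, seed: int = 0
) -> BalancedRandomForestClassifier:
    """Fit a balanced random forest with the given hyperparameters and seed."""
    hp = hp or Hyperparameters()
    clf = BalancedRandomForestClassifier(random_state=seed, **hp.estimator_params())
    return clf.fit(np.asarray(X, dtype=float), np.asarray(y))


#: Default randomized-search space over the tuned forest hyperparameters.
DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "n_estimators": [50, 100, 200, 400],
    "max_depth": [None, 2, 4, 8, 16],
    "min_samples_split": [2, 4, 6, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["auto", "log2", "sqrt"],
}


def tune_hyperparameters(
    X,
    y,
    search_space: dict[str, list] | None = None,
    n_iter: int = 100,
    n_draws: int = 50,
    folds: int = 5,
    seed_start: int = 0,
) -> tuple[Hyperparameters, Counter]:
    """Majority-vote randomized hyperparameter search.

    Runs ``n_iter`` independent randomized searches (each sampling
    ``n_draws`` configurations, scored by weighted F1 under stratified
    ``folds``-fold CV) with incremented random seeds, and returns the
    configuration that wins most often; ties resolve to the winner seen at
    the earliest seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    space = search_space or DEFAULT_SEARCH_SPACE

    votes: Counter = Counter()
    first_seen: dict[tuple, int] = {}
    for s in range(seed_start, seed_start + n_iter):
        search = RandomizedSearchCV(
            BalancedRandomForestClassifier(random_state=s),
            param_distributions=space,
            n_iter=n_draws,
            scoring="f1_weighted",
            cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=s),
            random_state=s,
        )
        search.fit(X, y)
        key = tuple(sorted(search.best_params_.items()))
        votes[key] += 1
        first_seen.setdefault(key, s)

    best_key = max(votes, key=lambda k: (votes[k], -first_seen[k]))
    params = dict(best_key)
    hp = Hyperparameters(
        n_estimators=params.get("n_estimators", 100),
        max_depth=params.get("max_depth"),
        min_samples_split=params.get("min_samples_split", 2),
        min_samples_leaf=params.get("min_samples_leaf", 1),
        max_features_mode=params.get("max_features", "sqrt"),
    )
    return hp, votes
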