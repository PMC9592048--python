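"""Feature-selection front-end: correlation filtering, seed-aggregated
recursive feature elimination, and backward elimination.

The selection protocol mirrors the clinical study design it reimplements:
(1) drop multicollinear features (|Pearson r| above a threshold, keeping the
earlier feature in catalog order); (2) run RFECV many times with incremented
seeds and aggregate each feature's impurity importance across runs into a
single normalized ranking; (3) walk backward from the full feature set to a
single feature, scoring each prefix of the ranking by seed-averaged LOSO
weighted F1, and keep the subset that maximizes it (ties favour fewer
features).

Note: selection is performed on the full cohort, as in the original protocol,
which leaks information into the subsequent LOSO evaluation; the package
reproduces that protocol rather than a nested (leak-free) variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from .ensemble import BalancedRandomForestClassifier, Hyperparameters
from .evaluation import ConfusionCounts, loso_predict, weighted_f1


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Drop features that are highly correlated with an earlier-ordered one.

    Zero-variance features are dropped first; then feature pairs are scanned
    in column order and, whenever ``|r| > threshold``, the later column is
    dropped.  The fitted filter records ``kept_features_``, and ``log_`` as
    (kept, dropped, r) triples (r is NaN for zero-variance drops).
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate correlations")
        values = X.to_numpy(dtype=float)
        names = list(X.columns)
        log: list[tuple[str, str, float]] = []

        variances = values.var(axis=0)
        nonzero = [j for j in range(len(names)) if variances[j] > 0.0]
        for j in range(len(names)):
            if variances[j] == 0.0:
                log.append(("", names[j], float("nan")))

        kept: list[int] = []
        if nonzero:
            corr = np.corrcoef(values[:, nonzero], rowvar=False)
            corr = np.atleast_2d(corr)
            for pos, j in enumerate(nonzero):
                drop_for = None
                for kpos, k in enumerate(kept):
                    r = corr[pos, nonzero.index(k)]
                    if abs(r) > self.threshold:
                        drop_for = (names[k], float(r))
                        break
                if drop_for is None:
                    kept.append(j)
                else:
                    log.append((drop_for[0], names[j], drop_for[1]))
        self.kept_features_ = [names[j] for j in kept]
        self.log_ = log
        self.n_features_in_ = len(names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return X[self.kept_features_]


def drop_correlated(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Functional wrapper over :class:`CorrelationFilter`.

    Returns the reduced table and the (kept, dropped, r) audit log.
    """
    filt = CorrelationFilter(threshold=threshold).fit(table)
    reduced = filt.transform(table)
    reduced.attrs.update(table.attrs)
    return reduced, filt.log_


@dataclass
class ImportanceRanking:
    """Normalized aggregated feature importances (descending order)."""

    importances: pd.Series  # indexed by feature name, sums to 1

    def __post_init__(self) -> None:
        if (self.importances < 0).any():
            raise ValueError("importances must be nonnegative")
        total = float(self.importances.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"importances must sum to 1, got {total}")

    @property
    def ranked_features(self) -> list[str]:
        """Feature names by descending importance (stable for ties)."""
        return list(self.importances.sort_values(ascending=False, kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        order = self.ranked_features
        return pd.DataFrame(
            {
                "feature": order,
                "normalized_importance": self.importances.loc[order].to_numpy(),
                "rank": np.arange(1, len(order) + 1),
            }
        )


def aggregate_importance(
    table: pd.DataFrame,
    labels,
    estimator: BalancedRandomForestClassifier | None = None,
    n_iter: int = 100,
    folds: int = 5,
    seed_start: int = 0,
) -> ImportanceRanking:
    """Seed-aggregated RFECV importance ranking.

    For each seed, recursive feature elimination with internal stratified
    ``folds``-fold cross-validation (weighted-F1 scoring, one feature removed
    per round) selects a feature subset; the refit estimator's
    impurity-decrease importances are accumulated over seeds (features not
    selected in a run contribute 0 for that run) and normalized to sum to 1.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    X = pd.DataFrame(table)
    names = list(X.columns)
    if len(names) == 1:
        return ImportanceRanking(pd.Series([1.0], index=names))

    base = estimator if estimator is not None else BalancedRandomForestClassifier()
    accumulated = pd.Series(0.0, index=names)
    for s in range(seed_start, seed_start + n_iter):
        est = clone(base)
        est.set_params(random_state=s)
        rfecv = RFECV(
            est,
            step=1,
            cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=s),
            scoring="f1_weighted",
            min_features_to_select=1,
        )
        rfecv.fit(X.to_numpy(dtype=float), y)
        selected = np.asarray(names)[rfecv.support_]
        accumulated.loc[selected] += rfecv.estimator_.feature_importances_
    total = float(accumulated.sum())
    if total <= 0:
        # Degenerate (all-zero importances); fall back to a uniform ranking.
        accumulated[:] = 1.0
        total = float(accumulated.sum())
    return ImportanceRanking(accumulated / total)


@dataclass
class SelectionCurve:
    """Backward-elimination performance curve and the chosen subset."""

    curve: pd.DataFrame  # columns: k, mean_f1, sd_f1
    chosen_k: int
    chosen_features: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.curve.copy()
        out["chosen"] = out["k"] == self.chosen_k
        return out


def backward_elimination(
    table: pd.DataFrame,
    labels,
    ranking: ImportanceRanking,
    hp: Hyperparameters | None = None,
    n_seeds: int = 100,
    seed_start: int = 0,
) -> SelectionCurve:
    """Score every top-k prefix of the importance ranking by LOSO weighted F1.

    For k from the full feature count down to 1, the top-k features by
    aggregated importance are evaluated with seed-averaged LOSO weighted F1;
    the returned subset maximizes the mean (ties resolve to smaller k).
    """
    X = pd.DataFrame(table)
    y = np.asarray(labels)
    order = ranking.ranked_features
    if set(order) != set(X.columns):
        raise ValueError("ranking does not cover exactly the table's features")

    rows = []
    best: tuple[float, int] | None = None
    chosen_features: list[str] = []
    for k in range(len(order), 0, -1):
        feats = order[:k]
        f1s = []
        for s in range(seed_start, seed_start + n_seeds):
            res = loso_predict(X[feats], y, hp, seed=s)
            f1s.append(weighted_f1(ConfusionCounts.from_labels(y, res["predicted"].to_numpy())))
        mean_f1 = float(np.mean(f1s))
        rows.append({"k": k, "mean_f1": mean_f1, "sd_f1": float(np.std(f1s))})
        if best is None or mean_f1 >= best[0]:  # >= so smaller k wins ties
            best = (mean_f1, k)
            chosen_features = feats
    curve = pd.DataFrame(rows)
    return SelectionCurve(curve=curve, chosen_k=best[1], chosen_features=list(chosen_features))
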