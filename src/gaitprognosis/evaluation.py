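"""Leave-one-subject-out evaluation, seed averaging, and the study metrics.

The cohorts are tiny (tens of patients), so every model is scored by
leave-one-subject-out (LOSO) cross-validation, and — because the balanced
forest is stochastic — the whole LOSO loop is repeated over a schedule of
incremented random seeds with mean and SD reported.  Metrics: weighted F1
(primary), accuracy, and AUROC on the community-class probability.  A
transition analysis breaks correct classifications down by the patients'
admission-to-discharge ambulation trajectory, the clinically decisive slice
of the cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import COMMUNITY, HOUSEHOLD
from .ensemble import BalancedRandomForestClassifier, Hyperparameters


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts in ambulation-class terms.

    ``tp_community`` counts community ambulators predicted community,
    ``fn_community`` those predicted household (and symmetrically for the
    household class, so one class's false negatives are the other's false
    positives).
    """

    tp_community: int
    fn_community: int
    tp_household: int
    fn_household: int

    def __post_init__(self) -> None:
        if min(self.tp_community, self.fn_community, self.tp_household, self.fn_household) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def support_community(self) -> int:
        return self.tp_community + self.fn_community

    @property
    def support_household(self) -> int:
        return self.tp_household + self.fn_household

    @property
    def total(self) -> int:
        return self.support_community + self.support_household

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors must have equal length")
        return cls(
            tp_community=int(np.sum((y_true == COMMUNITY) & (y_pred == COMMUNITY))),
            fn_community=int(np.sum((y_true == COMMUNITY) & (y_pred == HOUSEHOLD))),
            tp_household=int(np.sum((y_true == HOUSEHOLD) & (y_pred == HOUSEHOLD))),
            fn_household=int(np.sum((y_true == HOUSEHOLD) & (y_pred == COMMUNITY))),
        )


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def weighted_f1(cc: ConfusionCounts) -> float:
    """Support-weighted mean of the per-class F1 scores."""
    if cc.total < 1:
        raise ValueError("confusion counts are all zero")
    pred_c = cc.tp_community + cc.fn_household
    pred_h = cc.tp_household + cc.fn_community
    prec_c = cc.tp_community / pred_c if pred_c else 0.0
    prec_h = cc.tp_household / pred_h if pred_h else 0.0
    rec_c = cc.tp_community / cc.support_community if cc.support_community else 0.0
    rec_h = cc.tp_household / cc.support_household if cc.support_household else 0.0
    f1_c = _f1(prec_c, rec_c)
    f1_h = _f1(prec_h, rec_h)
    return (cc.support_community * f1_c + cc.support_household * f1_h) / cc.total


def accuracy(cc: ConfusionCounts) -> float:
    """Proportion of correctly classified patients."""
    if cc.total < 1:
        raise ValueError("confusion counts are all zero")
    return (cc.tp_community + cc.tp_household) / cc.total


def auroc(scores, labels) -> float:
    """Probability that a random community patient outscores a random
    household patient (ties counted 1/2), i.e. the Mann-Whitney AUROC of the
    community-class probability."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute AUROC")
    return float(roc_auc_score((labels == COMMUNITY).astype(int), np.asarray(scores, dtype=float)))


def loso_predict(
    table: pd.DataFrame,
    labels,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out predictions for every patient.

    For each patient, a balanced forest (seeded with ``seed``) is trained on
    all other patients and applied to the held-out one.  Returns a DataFrame
    indexed like ``table`` with columns ``predicted`` and ``score`` (the
    community-class probability).
    """
    hp = hp or Hyperparameters()
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients for LOSO evaluation")
    community_col = None
    preds = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    params = hp.estimator_params()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(set(y_train.tolist())) < 2:
            pid = table.index[i]
            raise ValueError(
                f"training fold excluding patient {pid!r} contains a single class"
            )
        clf = BalancedRandomForestClassifier(random_state=seed, **params)
        clf.fit(X[mask], y_train)
        if community_col is None:
            community_col = int(np.where(clf.classes_ == COMMUNITY)[0][0])
        proba = clf.predict_proba(X[i : i + 1])
        preds[i] = clf.predict(X[i : i + 1])[0]
        scores[i] = proba[0, community_col]
    return pd.DataFrame({"predicted": preds, "score": scores}, index=table.index)


@dataclass
class EvaluationReport:
    """Seed-averaged LOSO results for one model variant."""

    model: str
    n_seeds: int
    metrics: dict[str, dict[str, float]]  # metric -> {"mean": ..., "sd": ...}
    modal_confusion: ConfusionCounts
    per_seed_confusions: list[ConfusionCounts]
    predictions: pd.DataFrame  # patients x seeds predicted labels
    mean_scores: pd.Series  # per-patient community probability, seed-averaged
    classification_fluctuated: bool
    transition_recall: dict[str, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "n_seeds": self.n_seeds,
            "metrics": self.metrics,
            "modal_confusion": vars(self.modal_confusion),
            "classification_fluctuated": self.classification_fluctuated,
            "per_patient": {
                "modal_prediction": self.predictions.mode(axis=1)[0].to_dict(),
                "mean_community_probability": self.mean_scores.round(6).to_dict(),
            },
        }
        if self.transition_recall is not None:
            out["transition_recall"] = self.transition_recall
        return out


def seed_averaged_evaluation(
    table: pd.DataFrame,
    labels,
    hp: Hyperparameters | None = None,
    n_seeds: int = 100,
    seed_start: int = 0,
    adm_labels=None,
    model: str = "model",
) -> EvaluationReport:
    """Repeat LOSO evaluation over incremented seeds and aggregate.

    Reports mean and SD of weighted F1, accuracy, and AUROC; the modal (most
    frequent) confusion matrix; whether any patient's predicted label
    fluctuated across seeds; and, when admission labels are given, the
    per-transition-group recall of the modal predictions.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    y = np.asarray(labels)
    per_metric: dict[str, list[float]] = {"weighted_f1": [], "accuracy": [], "auroc": []}
    confusions: list[ConfusionCounts] = []
    pred_cols = {}
    score_sum = np.zeros(len(table))
    for s in range(seed_start, seed_start + n_seeds):
        res = loso_predict(table, y, hp, seed=s)
        cc = ConfusionCounts.from_labels(y, res["predicted"].to_numpy())
        confusions.append(cc)
        per_metric["weighted_f1"].append(weighted_f1(cc))
        per_metric["accuracy"].append(accuracy(cc))
        per_metric["auroc"].append(auroc(res["score"].to_numpy(), y))
        pred_cols[s] = res["predicted"]
        score_sum += res["score"].to_numpy()

    predictions = pd.DataFrame(pred_cols)
    fluctuated = bool((predictions.nunique(axis=1) > 1).any())
    modal = Counter((c.tp_community, c.fn_community, c.tp_household, c.fn_household) for c in confusions)
    modal_cc = ConfusionCounts(*modal.most_common(1)[0][0])
    metrics = {
        name: {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        for name, vals in per_metric.items()
    }
    modal_pred = predictions.mode(axis=1)[0].to_numpy()
    transition = None
    if adm_labels is not None:
        transition = transition_analysis(adm_labels, y, modal_pred)
    return EvaluationReport(
        model=model,
        n_seeds=n_seeds,
        metrics=metrics,
        modal_confusion=modal_cc,
        per_seed_confusions=confusions,
        predictions=predictions,
        mean_scores=pd.Series(score_sum / n_seeds, index=table.index),
        classification_fluctuated=fluctuated,
        transition_recall=transition,
    )


def transition_analysis(adm_labels, dis_labels, predictions) -> dict[str, dict[str, float]]:
    """Correct-classification fraction per admission->discharge group.

    Groups are household->household, community->community,
    household->community, and community->household; empty groups are omitted.
    """
    adm = np.asarray(adm_labels)
    dis = np.asarray(dis_labels)
    pred = np.asarray(predictions)
    if not (len(adm) == len(dis) == len(pred)):
        raise ValueError("label vectors must have equal length")
    out: dict[str, dict[str, float]] = {}
    for a in (HOUSEHOLD, COMMUNITY):
        for d in (HOUSEHOLD, COMMUNITY):
            mask = (adm == a) & (dis == d)
            n = int(mask.sum())
            if n == 0:
                continue
            correct = int((pred[mask] == d).sum())
            out[f"{a}->{d}"] = {"n": n, "correct": correct, "fraction": correct / n}
    return out
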