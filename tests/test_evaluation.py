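"""Metrics, LOSO protocol, seed averaging, transition analysis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score

from gaitprognosis.cohort import COMMUNITY, HOUSEHOLD
from gaitprognosis.ensemble import Hyperparameters
from gaitprognosis.evaluation import (
    ConfusionCounts,
    accuracy,
    auroc,
    loso_predict,
    seed_averaged_evaluation,
    transition_analysis,
    weighted_f1,
)

from conftest import separator_table


# ----------------------------------------------------------------- oracles


def labels_from_counts(cc: ConfusionCounts):
    """Reconstruct (y_true, y_pred) vectors realizing the confusion counts."""
    y_true, y_pred = [], []
    for n, t, p in [
        (cc.tp_community, COMMUNITY, COMMUNITY),
        (cc.fn_community, COMMUNITY, HOUSEHOLD),
        (cc.tp_household, HOUSEHOLD, HOUSEHOLD),
        (cc.fn_household, HOUSEHOLD, COMMUNITY),
    ]:
        y_true += [t] * n
        y_pred += [p] * n
    return np.array(y_true), np.array(y_pred)


def auroc_pairs(scores, labels):
    """All-pairs concordance count with ties scored 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == COMMUNITY]
    neg = scores[labels == HOUSEHOLD]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ----------------------------------------------------------------- metrics


@pytest.mark.parametrize(
    "cc, f1, acc",
    [
        (ConfusionCounts(23, 4, 6, 0), 0.889, 0.879),
        (ConfusionCounts(25, 2, 6, 0), 0.943, 0.939),
        (ConfusionCounts(24, 3, 6, 0), 0.916, 0.909),
    ],
)
def test_reference_cohort_metrics(cc, f1, acc):
    assert weighted_f1(cc) == pytest.approx(f1, abs=5e-4)
    assert accuracy(cc) == pytest.approx(acc, abs=5e-4)


def test_perfect_confusion_matrix():
    cc = ConfusionCounts(27, 0, 6, 0)
    assert weighted_f1(cc) == 1.0
    assert accuracy(cc) == 1.0


def test_metrics_match_sklearn_on_random_counts():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        cc = ConfusionCounts(*rng.integers(0, 30, size=4))
        if cc.total == 0:
            continue
        y_true, y_pred = labels_from_counts(cc)
        assert weighted_f1(cc) == pytest.approx(
            f1_score(y_true, y_pred, average="weighted", zero_division=0), abs=1e-12
        )
        assert accuracy(cc) == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError):
        weighted_f1(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError):
        accuracy(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


def test_auroc_trivial_cases():
    assert auroc([0.9, 0.8, 0.1], [COMMUNITY, COMMUNITY, HOUSEHOLD]) == 1.0
    assert auroc([0.5, 0.5, 0.5], [COMMUNITY, HOUSEHOLD, COMMUNITY]) == 0.5
    assert auroc([0.9, 0.8, 0.3], [COMMUNITY, HOUSEHOLD, COMMUNITY]) == 0.5


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        auroc([0.1, 0.9], [COMMUNITY, COMMUNITY])


def test_auroc_matches_pair_counting():
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(2, 21))
        labels = np.array([COMMUNITY, HOUSEHOLD] + list(rng.choice([COMMUNITY, HOUSEHOLD], n - 2)))
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n)  # include ties
        assert auroc(scores, labels) == pytest.approx(auroc_pairs(scores, labels), abs=1e-12)


# ----------------------------------------------------------------- LOSO


def test_loso_yields_one_prediction_per_patient():
    X, y = separator_table(n_per_class=6, n_noise=2)
    res = loso_predict(X, y, Hyperparameters(n_estimators=20), seed=0)
    assert len(res) == len(X)
    assert set(res.columns) == {"predicted", "score"}


def test_loso_perfectly_separable_all_correct():
    X, y = separator_table(n_per_class=8, n_noise=0)
    res = loso_predict(X, y, Hyperparameters(n_estimators=30), seed=1)
    assert (res["predicted"].to_numpy() == y).all()


def test_loso_single_class_fold_names_patient():
    X, _ = separator_table(n_per_class=3, n_noise=1)
    y = np.array([HOUSEHOLD] + [COMMUNITY] * 5)
    X.index = [f"P{i}" for i in range(6)]
    with pytest.raises(ValueError, match="P0"):
        loso_predict(X, y, seed=0)


def test_seed_averaging_single_seed_sd_zero():
    X, y = separator_table(n_per_class=6, n_noise=1)
    report = seed_averaged_evaluation(X, y, Hyperparameters(n_estimators=20), n_seeds=1)
    for metric in report.metrics.values():
        assert metric["sd"] == 0.0
    assert report.n_seeds == 1


def test_stable_predictions_not_flagged_as_fluctuating():
    X, y = separator_table(n_per_class=8, n_noise=0)
    report = seed_averaged_evaluation(X, y, Hyperparameters(n_estimators=30), n_seeds=3)
    assert not report.classification_fluctuated
    assert report.metrics["weighted_f1"]["mean"] == 1.0


def test_seed_mean_stabilizes_with_more_seeds():
    # The spread of the seed-averaged weighted F1 across disjoint seed blocks
    # should shrink as each block grows.
    rng = np.random.default_rng(5)
    n = 18
    y = np.array([COMMUNITY] * 13 + [HOUSEHOLD] * 5)
    X = pd.DataFrame({
        "weak": np.where(y == COMMUNITY, 0.4, 0.0) + rng.normal(0, 1.0, n),
        "noise": rng.normal(size=n),
    })
    hp = Hyperparameters(n_estimators=15)

    def block_means(block_size, n_blocks=3):
        means = []
        for b in range(n_blocks):
            f1s = []
            for s in range(b * block_size, (b + 1) * block_size):
                res = loso_predict(X, y, hp, seed=s)
                f1s.append(weighted_f1(ConfusionCounts.from_labels(y, res["predicted"].to_numpy())))
            means.append(np.mean(f1s))
        return np.std(means)

    assert block_means(12) <= block_means(1)


# ----------------------------------------------------------- transition table


def test_transition_perfect_predictions():
    adm = [HOUSEHOLD] * 3 + [COMMUNITY] * 4
    dis = [HOUSEHOLD, HOUSEHOLD, COMMUNITY] + [COMMUNITY] * 4
    out = transition_analysis(adm, dis, dis)
    assert all(v["fraction"] == 1.0 for v in out.values())
    assert out["household->community"]["n"] == 1


@pytest.mark.parametrize("h2c_correct, expected", [(0, 0.0), (2, 0.5), (1, 0.25)])
def test_transition_reference_groups(h2c_correct, expected):
    adm = [HOUSEHOLD] * 8 + [COMMUNITY] * 21 + [HOUSEHOLD] * 4
    dis = [HOUSEHOLD] * 8 + [COMMUNITY] * 21 + [COMMUNITY] * 4
    pred = (
        [HOUSEHOLD] * 8
        + [COMMUNITY] * 21
        + [COMMUNITY] * h2c_correct
        + [HOUSEHOLD] * (4 - h2c_correct)
    )
    out = transition_analysis(adm, dis, pred)
    assert out["household->household"]["fraction"] == 1.0
    assert out["community->community"]["fraction"] == 1.0
    assert out["household->community"]["fraction"] == pytest.approx(expected)


def test_transition_length_mismatch_rejected():
    with pytest.raises(ValueError):
        transition_analysis([HOUSEHOLD], [HOUSEHOLD, COMMUNITY], [HOUSEHOLD, COMMUNITY])
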