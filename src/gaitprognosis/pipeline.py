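"""End-to-end experiment orchestration.

Runs the full prognostic-modeling experiment over a configured cohort: feature
extraction under the fixed-distance (10 m walk) and/or fixed-duration
(first 10-360 s of a six-minute walk) paradigms, the model variants (PI,
PI+FA, PI+IMU, PI+FA+IMU), correlation filtering, seed-aggregated RFECV
ranking, backward elimination, majority-vote hyperparameter tuning, and
seed-averaged LOSO evaluation, writing every artifact plus a machine-readable
summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cohort import CohortConfig, simulate_cohort
from .ensemble import DEFAULT_SEARCH_SPACE, tune_hyperparameters
from .evaluation import (
    ConfusionCounts,
    accuracy,
    loso_predict,
    seed_averaged_evaluation,
    transition_analysis,
    weighted_f1,
)
from .features import FIXED_DURATIONS_S, BoutSpec, FeatureCatalog, extract_feature_table
from .selection import aggregate_importance, backward_elimination, drop_correlated

logger = logging.getLogger(__name__)

#: Feature namespaces per model variant.
MODEL_VARIANTS: dict[str, tuple[str, ...]] = {
    "PI": ("PI",),
    "PI+FA": ("PI", "FA"),
    "PI+IMU": ("PI", "IMU"),
    "PI+FA+IMU": ("PI", "FA", "IMU"),
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: str | None = None  # files mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    paradigms: tuple[str, ...] = ("fixed_distance",)
    duration_s: int = 60  # fixed-duration paradigm bout length
    durations: tuple[int, ...] = FIXED_DURATIONS_S  # sweep candidates
    variants: tuple[str, ...] = ("PI+FA", "PI+IMU", "PI+FA+IMU")
    correlation_threshold: float = 0.9
    rfecv_iters: int = 100
    selection_seeds: int = 100
    tuning_iters: int = 100
    tuning_draws: int = 50
    tuning_folds: int = 5
    eval_seeds: int = 100
    search_space: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEARCH_SPACE.items()})
    sampen_m: int = 2
    sampen_r: float = 0.2
    sweep_seeds: int = 5
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(MODEL_VARIANTS)
        if unknown:
            raise ValueError(f"unknown model variants: {sorted(unknown)}")
        if not self.variants:
            raise ValueError("at least one model variant is required")
        bad = set(self.durations) - set(FIXED_DURATIONS_S)
        if bad:
            raise ValueError(f"durations {sorted(bad)} outside the supported set {FIXED_DURATIONS_S}")

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload)
        if "cohort" in payload and isinstance(payload["cohort"], dict):
            payload["cohort"] = CohortConfig(**payload["cohort"])
        for key in ("paradigms", "durations", "variants"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # where artifacts land does not alter them
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: ExperimentConfig):
    if config.mode == "synthetic":
        return simulate_cohort(config.cohort)
    if config.mode == "files":
        if not config.input_dir:
            raise ValueError("files mode requires input_dir")
        return gio.read_cohort_dir(config.input_dir)
    raise ValueError(f"unknown input mode {config.mode!r}")


def _variant_table(full_table: pd.DataFrame, variant: str) -> pd.DataFrame:
    namespaces = MODEL_VARIANTS[variant]
    cols = [c for c in full_table.columns if c.split(".", 1)[0] in namespaces]
    sub = full_table[cols].copy()
    sub.attrs.update(full_table.attrs)
    return sub


def run_duration_sweep(
    config: ExperimentConfig,
    cohort: pd.DataFrame | None = None,
    recordings: dict | None = None,
    variant: str = "PI+FA+IMU",
) -> tuple[pd.DataFrame, int]:
    """Pre-optimization weighted F1 per fixed-duration bout length.

    Evaluates each candidate duration with default hyperparameters and no
    feature selection, averaging LOSO weighted F1 over ``sweep_seeds`` seeds,
    and returns (table, selected duration).  The argmax duration is selected;
    ties resolve to the shorter bout.  Durations longer than the available
    recordings are skipped with a warning.
    """
    if cohort is None or recordings is None:
        cohort, recordings = _load_inputs(config)
    catalog = FeatureCatalog.default().subset(MODEL_VARIANTS[variant])
    rows = []
    for duration in config.durations:
        spec = BoutSpec(paradigm="fixed_duration", duration_s=duration)
        try:
            table = extract_feature_table(
                cohort, recordings, spec, catalog, config.sampen_m, config.sampen_r
            )
        except ValueError as exc:
            warnings.warn(f"skipping duration {duration}s: {exc}")
            continue
        if table.empty:
            warnings.warn(f"skipping duration {duration}s: no patients with long enough recordings")
            continue
        y = cohort.loc[table.index, "label_dis"].to_numpy()
        f1s = []
        for s in range(config.seed, config.seed + config.sweep_seeds):
            res = loso_predict(table, y, None, seed=s)
            f1s.append(weighted_f1(ConfusionCounts.from_labels(y, res["predicted"].to_numpy())))
        rows.append({"duration_s": duration, "mean_f1": float(np.mean(f1s)), "sd_f1": float(np.std(f1s))})
    if not rows:
        raise ValueError("no duration could be evaluated")
    sweep = pd.DataFrame(rows)
    best = sweep.sort_values(["mean_f1", "duration_s"], ascending=[False, True]).iloc[0]
    return sweep, int(best["duration_s"])


def run_variant(
    table: pd.DataFrame,
    labels,
    adm_labels,
    config: ExperimentConfig,
    variant: str,
) -> dict:
    """Optimization + evaluation for one model variant on one paradigm."""
    base = config.seed
    reduced, corr_log = drop_correlated(table, config.correlation_threshold)
    ranking = aggregate_importance(
        reduced, labels, n_iter=config.rfecv_iters, folds=config.tuning_folds, seed_start=base
    )
    curve = backward_elimination(
        reduced, labels, ranking, hp=None, n_seeds=config.selection_seeds, seed_start=base
    )
    selected = reduced[curve.chosen_features]
    hp, votes = tune_hyperparameters(
        selected,
        labels,
        search_space=config.search_space,
        n_iter=config.tuning_iters,
        n_draws=config.tuning_draws,
        folds=config.tuning_folds,
        seed_start=base,
    )
    report = seed_averaged_evaluation(
        selected,
        labels,
        hp=hp,
        n_seeds=config.eval_seeds,
        seed_start=base,
        adm_labels=adm_labels,
        model=variant,
    )
    return {
        "variant": variant,
        "correlation_log": corr_log,
        "ranking": ranking,
        "curve": curve,
        "hyperparameters": hp,
        "votes": votes,
        "report": report,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full experiment; returns (and optionally writes) a bundle.

    The bundle maps ``results[paradigm_tag][variant]`` to the per-variant
    artifacts of :func:`run_variant`, plus the cohort, feature tables, and a
    JSON-serializable summary.
    """
    cohort, recordings = _load_inputs(config)
    y_all = cohort["label_dis"]
    adm_all = cohort["label_adm"]

    specs: list[BoutSpec] = []
    for paradigm in config.paradigms:
        if paradigm == "fixed_distance":
            specs.append(BoutSpec(paradigm="fixed_distance"))
        elif paradigm == "fixed_duration":
            specs.append(BoutSpec(paradigm="fixed_duration", duration_s=config.duration_s))
        else:
            raise ValueError(f"unknown paradigm {paradigm!r}")

    catalog = FeatureCatalog.default()
    results: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    for spec in specs:
        full = extract_feature_table(
            cohort, recordings, spec, catalog, config.sampen_m, config.sampen_r
        )
        tables[spec.tag] = full
        y = y_all.loc[full.index].to_numpy()
        adm = adm_all.loc[full.index].to_numpy()
        results[spec.tag] = {}
        for variant in config.variants:
            logger.info("running %s / %s", spec.tag, variant)
            results[spec.tag][variant] = run_variant(
                _variant_table(full, variant), y, adm, config, variant
            )

    summary = _summarize(config, results)
    bundle = {
        "config": config,
        "cohort": cohort,
        "recordings": recordings,
        "tables": tables,
        "results": results,
        "summary": summary,
    }
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _summarize(config: ExperimentConfig, results: dict) -> dict:
    summary: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "paradigms": {},
    }
    for tag, variants in results.items():
        summary["paradigms"][tag] = {}
        for variant, res in variants.items():
            report = res["report"]
            summary["paradigms"][tag][variant] = {
                "metrics": report.metrics,
                "selected_features": res["curve"].chosen_features,
                "hyperparameters": res["hyperparameters"].to_dict(),
                "modal_confusion": vars(report.modal_confusion),
                "classification_fluctuated": report.classification_fluctuated,
                "transition_recall": report.transition_recall,
            }
    return summary


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["cohort"].to_csv(out_dir / "cohort.csv")
    for tag, table in bundle["tables"].items():
        table.to_csv(out_dir / f"features_{tag}.csv")
    for tag, variants in bundle["results"].items():
        for variant, res in variants.items():
            stem = f"{tag}_{variant.replace('+', '_')}"
            res["ranking"].to_frame().to_csv(out_dir / f"importance_{stem}.csv", index=False)
            res["curve"].to_frame().to_csv(out_dir / f"selection_curve_{stem}.csv", index=False)
            with open(out_dir / f"hyperparameters_{stem}.json", "w") as fh:
                json.dump(
                    {
                        "chosen": res["hyperparameters"].to_dict(),
                        "votes": {str(dict(k)): v for k, v in res["votes"].items()},
                    },
                    fh,
                    indent=2,
                )
            with open(out_dir / f"report_{stem}.json", "w") as fh:
                json.dump(res["report"].to_dict(), fh, indent=2)
            cc = res["report"].modal_confusion
            pd.DataFrame(
                [
                    {"true": "community", "pred_community": cc.tp_community, "pred_household": cc.fn_community},
                    {"true": "household", "pred_community": cc.fn_household, "pred_household": cc.tp_household},
                ]
            ).to_csv(out_dir / f"confusion_{stem}.csv", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)


def default_study_config(seed: int = 0) -> ExperimentConfig:
    """The package's standard desk-scale study configuration.

    The cohort composition is the canonical 33-patient split (6
    household-stable, 23 community-stable, 4 household-to-community -> 27
    community / 6 household at discharge) under the fixed-distance paradigm,
    with the optimization loop sized for a workstation run: 20 RFECV
    repetitions, 5 seeds per backward-elimination point, a 5x10 randomized
    hyperparameter search, and 20 evaluation seeds.
    """
    return ExperimentConfig(
        cohort=CohortConfig(seed=seed),
        paradigms=("fixed_distance",),
        variants=("PI+FA", "PI+IMU"),
        rfecv_iters=20,
        selection_seeds=5,
        tuning_iters=5,
        tuning_draws=10,
        eval_seeds=20,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Built-in worked example (reference cohort of 33 patients, 27 community / 6
# household at discharge).  Confusion counts, transition-group outcomes, and
# the metric values they imply, used as a fast self-check of the metric stack.

REFERENCE_CONFUSIONS: dict[str, ConfusionCounts] = {
    "PI+FA": ConfusionCounts(tp_community=23, fn_community=4, tp_household=6, fn_household=0),
    "PI+IMU": ConfusionCounts(tp_community=25, fn_community=2, tp_household=6, fn_household=0),
    "PI+FA+IMU": ConfusionCounts(tp_community=24, fn_community=3, tp_household=6, fn_household=0),
}

REFERENCE_METRICS: dict[str, dict[str, float]] = {
    "PI+FA": {"weighted_f1": 0.889, "accuracy": 0.879, "community_recall_pct": 85.0},
    "PI+IMU": {"weighted_f1": 0.943, "accuracy": 0.939, "community_recall_pct": 93.0},
    "PI+FA+IMU": {"weighted_f1": 0.916, "accuracy": 0.909, "community_recall_pct": 89.0},
}

#: Transition groups (admission -> discharge) of the reference cohort and the
#: number of household-to-community patients each model classified correctly.
REFERENCE_TRANSITION_GROUPS = {"household->household": 8, "community->community": 21, "household->community": 4}
REFERENCE_H2C_CORRECT = {"PI+FA": 0, "PI+IMU": 2, "PI+FA+IMU": 1}


def reference_transition_fractions(model: str) -> dict[str, float]:
    """Per-group correct-classification percentages of the reference models.

    Stable groups are always classified perfectly by every reference model;
    the household-to-community group separates them.
    """
    h2c = REFERENCE_H2C_CORRECT[model]
    return {
        "household->household": 100.0,
        "community->community": 100.0,
        "household->community": 100.0 * h2c / REFERENCE_TRANSITION_GROUPS["household->community"],
    }


def verify_worked_examples(tolerance: float = 5e-4) -> pd.DataFrame:
    """Recompute every reference metric from its confusion counts.

    Each reference value is printed to 3 decimals (recalls to whole
    percents), so agreement is checked within half a unit of the printed
    precision by default.  Returns a table of (model, metric, computed,
    expected, passed).
    """
    rows = []
    for model, cc in REFERENCE_CONFUSIONS.items():
        computed = {
            "weighted_f1": weighted_f1(cc),
            "accuracy": accuracy(cc),
            "community_recall_pct": 100.0 * cc.tp_community / cc.support_community,
        }
        for metric, expected in REFERENCE_METRICS[model].items():
            value = computed[metric]
            tol = 0.5 if metric == "community_recall_pct" else tolerance
            rows.append(
                {
                    "model": model,
                    "metric": metric,
                    "computed": value,
                    "expected": expected,
                    "passed": bool(abs(value - expected) <= tol),
                }
            )
    # Transition worked example: reconstruct label vectors from the group
    # sizes and per-model correct counts, then run the transition analysis.
    for model, h2c_correct in REFERENCE_H2C_CORRECT.items():
        adm, dis, pred = _reference_transition_vectors(h2c_correct)
        fractions = transition_analysis(adm, dis, pred)
        expected = reference_transition_fractions(model)
        for group, frac in expected.items():
            value = 100.0 * fractions[group]["fraction"]
            rows.append(
                {
                    "model": model,
                    "metric": f"transition:{group}",
                    "computed": value,
                    "expected": frac,
                    "passed": bool(abs(value - frac) <= 1e-9),
                }
            )
    return pd.DataFrame(rows)


def _reference_transition_vectors(h2c_correct: int):
    adm, dis, pred = [], [], []
    for _ in range(REFERENCE_TRANSITION_GROUPS["household->household"]):
        adm.append("household"); dis.append("household"); pred.append("household")
    for _ in range(REFERENCE_TRANSITION_GROUPS["community->community"]):
        adm.append("community"); dis.append("community"); pred.append("community")
    n_h2c = REFERENCE_TRANSITION_GROUPS["household->community"]
    for i in range(n_h2c):
        adm.append("household"); dis.append("community")
        pred.append("community" if i < h2c_correct else "household")
    return adm, dis, pred
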