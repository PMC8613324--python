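"""Full-grid experiment orchestration.

One experiment runs every (dataset, selector method, k, classifier
configuration) cell under both training schemes with a shared fold
assignment per dataset, writes a tidy results table, and derives the
scheme comparison, the per-combination bias matrix and the
bias-versus-dimensionality regression.  Completed cells are cached on disk
by a provenance hash, so an interrupted experiment resumes without
recomputation and a finished one replays for free.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import evaluation
from .cv import derive_seed, run_scheme_a, run_scheme_b, stratified_kfold
from .datasets import DatasetSpec, RadiomicsDataset, generate_dataset, read_dataset
from .evaluation import EvaluationResult, SchemeComparison, evaluate
from .feature_selection import K_GRID, SELECTOR_METHODS, SelectorConfig
from .models import CLASSIFIER_NAMES, ClassifierConfig, enumerate_grid
from .preprocessing import preprocess

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentOutput", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs.

    Datasets may be CSV paths or DatasetSpecs (generated on the fly).
    Defaults reproduce the full grid shape: 7 selectors x 6 k values x all
    classifier grid points x 2 schemes per dataset.
    """

    datasets: list[Any] = field(default_factory=list)
    selector_methods: tuple[str, ...] = SELECTOR_METHODS
    k_grid: tuple[int, ...] = K_GRID
    classifier_names: tuple[str, ...] = CLASSIFIER_NAMES
    grid_overrides: dict[str, dict[str, list[Any]]] | None = None
    n_folds: int = 10
    seed: int = 0
    output_dir: Path | None = None
    n_jobs: int = 1
    n_boot: int = 2000


@dataclass
class ExperimentOutput:
    results: pd.DataFrame
    comparisons: dict[str, SchemeComparison]
    combination_bias: pd.DataFrame
    regression: evaluation.BiasRegressionResult | None
    evaluations: list[EvaluationResult] = field(default_factory=list)


def _load_dataset(entry: Any, seed: int) -> RadiomicsDataset:
    if isinstance(entry, RadiomicsDataset):
        return entry
    if isinstance(entry, DatasetSpec):
        return generate_dataset(entry)
    return read_dataset(entry)


def _cell_key(dataset: RadiomicsDataset, sel: SelectorConfig,
              clf: ClassifierConfig, scheme: str, seed: int) -> str:
    import hashlib

    content = hashlib.sha256(
        dataset.features.tobytes() + dataset.outcome.tobytes()
    ).hexdigest()[:16]
    return f"{dataset.name}|{content}|{sel.method}|k={sel.k}|{clf.label()}|{scheme}|{seed}"


def _run_cell(
    dataset: RadiomicsDataset,
    sel: SelectorConfig,
    clf: ClassifierConfig,
    folds,
    scheme: str,
    seed: int,
    cache_dir: Path | None,
) -> dict[str, Any]:
    import hashlib

    key = _cell_key(dataset, sel, clf, scheme, seed)
    cache_file = None
    if cache_dir is not None:
        digest = hashlib.sha256(key.encode()).hexdigest()[:24]
        cache_file = cache_dir / f"{digest}.json"
        if cache_file.exists():
            payload = json.loads(cache_file.read_text())
            payload["probs"] = np.asarray(payload["probs"])
            payload["cached"] = True
            return payload
    runner = run_scheme_a if scheme == "A" else run_scheme_b
    try:
        preds = runner(dataset, sel, clf, folds, seed=seed)
    except ValueError as exc:
        logger.warning("skipped cell %s: %s", key, exc)
        return {"key": key, "skipped": True, "error": str(exc)}
    payload = {
        "key": key,
        "skipped": False,
        "probs": preds.probs,
        "scheme": scheme,
        "cached": False,
    }
    if cache_file is not None:
        serial = dict(payload, probs=list(map(float, preds.probs)), cached=None)
        serial.pop("cached")
        cache_file.write_text(json.dumps(serial))
    return payload


def run_experiment(config: ExperimentConfig) -> ExperimentOutput:
    """Run the full grid under both schemes and derive all reports.

    Preprocessing (column-mean imputation + z-scoring) happens once per
    dataset, up front.  Grid cells are independent jobs; the worker count
    never affects the values, only the wall time.
    """
    if not config.datasets:
        raise ValueError("experiment config lists no datasets")
    cache_dir = None
    if config.output_dir is not None:
        out = Path(config.output_dir)
        (out / "cache").mkdir(parents=True, exist_ok=True)
        cache_dir = out / "cache"

    rows: list[dict[str, Any]] = []
    all_evals: list[EvaluationResult] = []
    comparisons: dict[str, SchemeComparison] = {}
    reg_points: list[tuple[float, float]] = []

    for entry in config.datasets:
        raw = _load_dataset(entry, config.seed)
        if len(np.unique(raw.outcome)) < 2:
            raise ValueError(f"dataset {raw.name!r} has a single outcome class")
        dataset, _ = preprocess(raw)
        fold_seed = derive_seed(config.seed, dataset.name, "folds")
        folds = stratified_kfold(dataset.outcome, K=config.n_folds, seed=fold_seed)

        cells = []
        clf_configs = enumerate_grid(config.classifier_names, config.grid_overrides)
        for method in config.selector_methods:
            for k in config.k_grid:
                sel = SelectorConfig(method=method, k=min(k, dataset.n_features))
                for clf in clf_configs:
                    for scheme in ("A", "B"):
                        cells.append((sel, clf, scheme))

        def one(cell):
            sel, clf, scheme = cell
            return _run_cell(dataset, sel, clf, folds, scheme, config.seed, cache_dir)

        payloads = Parallel(n_jobs=config.n_jobs)(delayed(one)(c) for c in cells)

        evals_a: list[EvaluationResult] = []
        evals_b: list[EvaluationResult] = []
        for (sel, clf, scheme), payload in zip(cells, payloads):
            if payload.get("skipped"):
                rows.append(
                    {
                        "dataset": dataset.name,
                        "selector": sel.method,
                        "k": sel.k,
                        "classifier": clf.label(),
                        "scheme": scheme,
                        "error": payload["error"],
                    }
                )
                continue
            from .cv import PooledPredictions

            preds = PooledPredictions(
                probs=np.asarray(payload["probs"]),
                labels=dataset.outcome.copy(),
                fold_of=folds.fold_of.copy(),
                scheme=scheme,
                dataset_name=dataset.name,
                selector=sel,
                classifier=clf,
            )
            ev = evaluate(preds)
            (evals_a if scheme == "A" else evals_b).append(ev)
            all_evals.append(ev)
            rows.append(
                {
                    "dataset": dataset.name,
                    "selector": sel.method,
                    "k": sel.k,
                    "classifier": clf.label(),
                    "scheme": scheme,
                    "auc_roc": ev.auc_roc,
                    "auc_pr": ev.auc_pr,
                    "accuracy": ev.accuracy,
                    "sensitivity": ev.sensitivity,
                    "specificity": ev.specificity,
                    "precision": ev.precision,
                    "recall": ev.recall,
                    "cached": payload.get("cached", False),
                }
            )
        if evals_a and evals_b:
            comp = evaluation.compare_schemes(
                evals_a,
                evals_b,
                n_boot=config.n_boot,
                seed=derive_seed(config.seed, dataset.name, "boot"),
            )
            comparisons[dataset.name] = comp
            reg_points.append((dataset.samples_per_feature, comp.delta["auc_roc"]))

    results = pd.DataFrame(rows)
    combo = (
        evaluation.combination_bias(all_evals) if all_evals else pd.DataFrame()
    )
    regression = (
        evaluation.bias_vs_dimensionality(reg_points) if len(reg_points) >= 3 else None
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        results.to_csv(out / "results.csv", index=False)
        report = {
            name: {
                "delta": comp.delta,
                "p_values": comp.p_values,
                "best_a_auc_roc": comp.best_a.auc_roc,
                "best_b_auc_roc": comp.best_b.auc_roc,
            }
            for name, comp in comparisons.items()
        }
        if regression is not None:
            report["_bias_vs_dimensionality"] = {
                "pearson_r": regression.pearson_r,
                "slope": regression.slope,
                "intercept": regression.intercept,
                "p_value": regression.p_value,
            }
        (out / "comparison.json").write_text(json.dumps(report, indent=2))

    return ExperimentOutput(
        results=results,
        comparisons=comparisons,
        combination_bias=combo,
        regression=regression,
        evaluations=all_evals,
    )
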