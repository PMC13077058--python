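"""End-to-end orchestration: score, evaluate, robustness.

These functions glue the filter, the baselines, the two-stage harness, the
paired tests and the perturbations into the three reproducible reports the
command-line interface exposes. A single top-level seed fixes every
downstream stream through stable per-component derivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .baselines import SelectorConfig, l1en_rank, mi_rank, mrmr_select, relieff_rank
from .data import FeatureTable, RankingResult
from .evaluate import (
    EvalRun,
    ModelSpec,
    SplitSpec,
    permutation_importance,
    run_two_stage,
    stratified_split,
)
from .filter import GumbelTailFilter
from .paired import PairedTestResult, compare_runs
from .perturb import add_feature_noise, apply_mcar_impute, flip_labels

logger = logging.getLogger(__name__)

SELECTORS = ("gumbel", "mi", "mrmr", "relieff", "l1en")


def training_table(data: FeatureTable, split: SplitSpec) -> FeatureTable:
    """The 80% training split (train + validation rows) used for selection."""
    rows = np.sort(np.concatenate([split.train_idx, split.val_idx]))
    return data.take_rows(rows)


def compute_rankings(
    train: FeatureTable,
    k: int,
    seed: int,
    selectors: tuple[str, ...] = SELECTORS,
    B_lambda: int = 1000,
) -> tuple[dict[str, RankingResult], object]:
    """All requested selector rankings on the training split.

    Returns the rankings plus the fitted Gumbel results object (which carries
    the bootstrap CIs) when the gumbel selector was requested.
    """
    cfg = SelectorConfig(k=k, seed=derive_seed(seed, "selector"))
    rankings: dict[str, RankingResult] = {}
    gumbel_results = None
    for sel in selectors:
        if sel == "gumbel":
            gumbel_results = GumbelTailFilter(train).fit(
                bootstrap=B_lambda > 0, B=max(B_lambda, 2),
                seed=derive_seed(seed, "lambda_bootstrap"),
            )
            rankings[sel] = gumbel_results.rank(k)
        elif sel == "mi":
            rankings[sel] = mi_rank(train, cfg)
        elif sel == "mrmr":
            rankings[sel] = mrmr_select(train, k, cfg)
        elif sel == "relieff":
            rankings[sel] = relieff_rank(train, cfg)
        elif sel == "l1en":
            rankings[sel] = l1en_rank(train, cfg)
        else:
            raise ValueError(f"unknown selector {sel!r}")
    return rankings, gumbel_results


def run_score(
    data: FeatureTable,
    k: int = 10,
    B: int = 1000,
    seed: int = 42,
    selectors: tuple[str, ...] = SELECTORS,
) -> dict:
    """Per-method ordered feature lists, Gumbel list annotated with CIs."""
    split = stratified_split(data.y, derive_seed(seed, "split"))
    train = training_table(data, split)
    rankings, gumbel = compute_rankings(train, k, seed, selectors, B_lambda=B)
    out = {
        "k": k,
        "seed": seed,
        "rankings": {m: r.to_dict() for m, r in rankings.items()},
    }
    if gumbel is not None:
        out["gumbel_scores"] = [s.to_dict() for s in gumbel.scores]
    return out


@dataclass
class EvaluationReport:
    """Full grid results plus anchored paired tests and importance."""

    results: list[EvalRun] = field(default_factory=list)
    rankings: dict[str, RankingResult] = field(default_factory=dict)
    paired: dict[str, PairedTestResult] = field(default_factory=dict)
    anchor: tuple[str, str] | None = None
    importance: dict | None = None

    def results_rows(self) -> list[dict]:
        return [r.result.to_dict() for r in self.results]

    def to_dict(self) -> dict:
        return {
            "results": self.results_rows(),
            "rankings": {m: r.to_dict() for m, r in self.rankings.items()},
            "anchor": list(self.anchor) if self.anchor else None,
            "paired_tests": {
                name: t.to_dict() for name, t in self.paired.items()
            },
            "permutation_importance": self.importance,
        }


def run_evaluate(
    data: FeatureTable,
    k: int = 10,
    seed: int = 42,
    selectors: tuple[str, ...] = SELECTORS,
    models: tuple[str, ...] = ("logistic", "random_forest", "gradient_boosting", "xgboost"),
    B_lambda: int = 1000,
    B_auc: int = 1000,
    n_repeats: int = 500,
    grid: int = 999,
    include_all: bool = True,
    run_importance: bool = True,
) -> EvaluationReport:
    """The full selectors-by-models grid with anchored paired comparisons.

    DeLong/McNemar tests compare the best Gumbel (selector, model) pair with
    the same model trained on each alternative feature set; permutation
    importance is computed for that anchored configuration.
    """
    split = stratified_split(data.y, derive_seed(seed, "split"))
    train = training_table(data, split)
    rankings, _ = compute_rankings(train, k, seed, selectors, B_lambda=B_lambda)

    feature_sets: dict[str, list[str]] = {}
    if include_all:
        feature_sets["all"] = list(data.feature_names)
    for sel, ranking in rankings.items():
        feature_sets[sel] = ranking.selected

    report = EvaluationReport(rankings=rankings)
    runs: dict[tuple[str, str], EvalRun] = {}
    for sel, feats in feature_sets.items():
        for fam in models:
            spec = ModelSpec(family=fam, seed=derive_seed(seed, f"model:{fam}"))
            run = run_two_stage(
                data, feats, spec, split, selector=sel, B_auc=B_auc, grid=grid,
                ci_seed=derive_seed(seed, f"auc_ci:{sel}:{fam}"),
            )
            runs[(sel, fam)] = run
            report.results.append(run)
            logger.info("evaluated %s/%s: auc=%.4f", sel, fam, run.result.auc)

    if "gumbel" in feature_sets:
        gumbel_runs = {f: r for (s, f), r in runs.items() if s == "gumbel"}
        best_fam = max(gumbel_runs, key=lambda f: gumbel_runs[f].result.auc)
        anchor_run = gumbel_runs[best_fam]
        report.anchor = ("gumbel", best_fam)
        for sel in feature_sets:
            if sel == "gumbel":
                continue
            other = runs[(sel, best_fam)]
            report.paired[f"gumbel_vs_{sel}"] = compare_runs(
                anchor_run.y_test,
                anchor_run.scores_test, other.scores_test,
                anchor_run.y_pred, other.y_pred,
            )
        if run_importance:
            mean, sd = permutation_importance(
                anchor_run.model, anchor_run.X_test, anchor_run.y_test,
                n_repeats=n_repeats, seed=derive_seed(seed, "perm_importance"),
            )
            order = np.argsort(-mean)
            report.importance = {
                "selector": "gumbel",
                "model": best_fam,
                "n_repeats": n_repeats,
                "features": [anchor_run.features[j] for j in order],
                "mean_drop": [float(mean[j]) for j in order],
                "sd": [float(sd[j]) for j in order],
            }
    return report


def run_robustness(
    data: FeatureTable,
    k: int = 10,
    seed: int = 42,
    model: str = "gradient_boosting",
    flip_frac: float = 0.05,
    noise_sigma: float = 0.10,
    mcar_levels: tuple[float, ...] = (0.10, 0.20, 0.30),
    B_lambda: int = 0,
    B_auc: int = 1000,
    grid: int = 999,
) -> list[dict]:
    """Baseline plus three stressors, same split and threshold protocol.

    Training labels (train + validation rows) may be flipped; test labels are
    never perturbed. Feature noise and MCAR masking touch both splits, with
    scales/medians fit on the training rows only.
    """
    split = stratified_split(data.y, derive_seed(seed, "split"))
    train = training_table(data, split)
    rankings, _ = compute_rankings(
        train, k, seed, selectors=("gumbel",), B_lambda=B_lambda
    )
    feats = rankings["gumbel"].selected
    spec = ModelSpec(family=model, seed=derive_seed(seed, f"model:{model}"))
    train_rows = np.sort(np.concatenate([split.train_idx, split.val_idx]))
    test_rows = split.test_idx

    def evaluate(table: FeatureTable) -> float:
        run = run_two_stage(
            table, feats, spec, split, selector="gumbel", B_auc=B_auc, grid=grid,
            ci_seed=derive_seed(seed, "auc_ci:robustness"),
        )
        return run.result.auc

    rows = [{"type": "baseline", "level": 0.0, "auc": evaluate(data)}]

    y_flip = data.y.copy()
    y_flip[train_rows] = flip_labels(
        data.y[train_rows], frac=flip_frac, seed=derive_seed(seed, "label_flip")
    )
    rows.append({
        "type": "label_flip", "level": flip_frac,
        "auc": evaluate(FeatureTable(data.X, data.feature_names, y_flip)),
    })

    Xn = data.X.copy()
    Xn[train_rows], Xn[test_rows] = add_feature_noise(
        data.X[train_rows], data.X[test_rows], sigma_frac=noise_sigma,
        seed=derive_seed(seed, "feature_noise"),
    )
    rows.append({
        "type": "feature_noise", "level": noise_sigma,
        "auc": evaluate(FeatureTable(Xn, data.feature_names, data.y)),
    })

    for frac in mcar_levels:
        Xm = data.X.copy()
        Xm[train_rows], Xm[test_rows], _ = apply_mcar_impute(
            data.X[train_rows], data.X[test_rows], frac=frac,
            seed=derive_seed(seed, f"mcar:{frac}"),
        )
        rows.append({
            "type": "mcar", "level": frac,
            "auc": evaluate(FeatureTable(Xm, data.feature_names, data.y)),
        })
    return rows
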