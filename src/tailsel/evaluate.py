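"""Two-stage split / threshold / calibrate / evaluate protocol.

The protocol mirrors a leakage-safe clinical evaluation:

* one 80/20 stratified outer split, plus a validation subset that is 20% of
  the training rows, used only to pick the decision threshold;
* Stage 1 fits on the inner training rows (with class balancing, isotonic
  calibration for tree families, train-only scaling for logistic) and picks
  the F1-maximizing threshold on the validation scores;
* Stage 2 refits identically on train+validation (re-fitting scalers and
  calibrators), scores the untouched test rows, and applies the frozen
  threshold.

Classifier families are thin adapters over established learners; the harness,
not the learners, is the contribution here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._errors import InvalidInputError, UndefinedStatisticError
from .data import FeatureTable

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("logistic", "random_forest", "gradient_boosting", "xgboost")


@dataclass
class SplitSpec:
    """Disjoint train/validation/test index sets covering all rows."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    fractions: tuple[float, float] = (0.8, 0.2)


def stratified_split(
    y: np.ndarray, seed: int, test_frac: float = 0.2, val_frac: float = 0.2
) -> SplitSpec:
    """Per-class shuffled partition: 20% test, then 20% of the rest as validation."""
    y = np.asarray(y)
    train, val, test = [], [], []
    rng = np.random.default_rng(seed)
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        if idx.size < 5:
            raise InvalidInputError(f"class {c} too small to stratify ({idx.size})")
        rng.shuffle(idx)
        n_test = int(round(test_frac * idx.size))
        test.append(idx[:n_test])
        rest = idx[n_test:]
        n_val = int(round(val_frac * rest.size))
        val.append(rest[:n_val])
        train.append(rest[n_val:])
    return SplitSpec(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        test_idx=np.sort(np.concatenate(test)),
        seed=seed,
    )


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from exact confusion-matrix arithmetic.

    Conventions for empty denominators: precision = 0 with no predicted
    positives, recall = 0 with no actual positives, F1 = 0 when
    precision + recall = 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def roc_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Pr(s+ > s-) + 1/2 Pr(s+ = s-) via midranks (O(n log n))."""
    y = np.asarray(y).astype(int)
    s = np.asarray(s, dtype=float)
    m = int(y.sum())
    n_neg = y.size - m
    if m == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC needs both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n_neg))


def auc_bootstrap_ci(
    y: np.ndarray, s: np.ndarray, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """2.5/97.5 percentile interval of AUC over row resamples of the test set.

    Single-class resamples are redrawn (their count is logged).
    """
    y = np.asarray(y).astype(int)
    s = np.asarray(s, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    aucs = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            rows = rng.integers(0, n, size=n)
            if 0 < y[rows].sum() < n:
                break
            redrawn += 1
        aucs[b] = roc_auc(y[rows], s[rows])
    if redrawn:
        logger.info("auc bootstrap: redrew %d single-class resamples", redrawn)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def select_threshold(
    s_val: np.ndarray, y_val: np.ndarray, grid: int = 999
) -> float:
    """F1-maximizing cutoff over a fine grid of score quantiles.

    Candidates are the quantiles of the validation scores at levels
    1/(grid+1) .. grid/(grid+1); predictions use ``score >= cutoff``. The
    smallest cutoff attaining the maximal F1 is returned, for determinism.
    """
    s_val = np.asarray(s_val, dtype=float)
    y_val = np.asarray(y_val).astype(int)
    levels = np.arange(1, grid + 1) / (grid + 1)
    cuts = np.unique(np.quantile(s_val, levels))
    best_f1, best_cut = -1.0, float(cuts[0])
    for cut in cuts:
        _, _, _, f1 = compute_metrics(y_val, (s_val >= cut).astype(int))
        if f1 > best_f1:  # strict: keeps the smallest cutoff at ties
            best_f1, best_cut = f1, float(cut)
    return best_cut


@dataclass
class ModelSpec:
    """Classifier family plus its balancing/calibration/scaling policy.

    Policies follow the protocol: isotonic calibration for tree families only,
    standardization for logistic only, balancing via class weights (logistic,
    random forest), normalized inverse-frequency sample weights (gradient
    boosting), or the negative/positive ratio (xgboost).
    """

    family: str
    calibrate: bool | None = None
    standardize: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise InvalidInputError(
                f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        if self.calibrate is None:
            self.calibrate = self.family != "logistic"
        if self.standardize is None:
            self.standardize = self.family == "logistic"


class ClassifierAdapter:
    """Minimal contract over a learner: ``fit(X, y)`` / ``predict_proba1(X)``.

    Preprocessing (scaling) and calibration live inside the adapter so the
    scoring path applied at predict time is exactly the one fit at train time.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self._model = None

    def _build(self, y: np.ndarray):
        spec = self.spec
        seed = spec.seed
        if spec.family == "logistic":
            est = LogisticRegression(
                class_weight="balanced", max_iter=1000, random_state=seed
            )
        elif spec.family == "random_forest":
            est = RandomForestClassifier(
                n_estimators=200, class_weight="balanced",
                random_state=seed, n_jobs=1,
            )
        elif spec.family == "gradient_boosting":
            est = GradientBoostingClassifier(random_state=seed)
        else:  # xgboost
            from xgboost import XGBClassifier

            n_pos = int(np.sum(y == 1))
            n_neg = int(np.sum(y == 0))
            est = XGBClassifier(
                scale_pos_weight=n_neg / n_pos,
                random_state=seed,
                n_jobs=1,
                eval_metric="logloss",
                tree_method="hist",
                verbosity=0,
            )
        if spec.calibrate:
            est = CalibratedClassifierCV(
                est,
                method="isotonic",
                cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
            )
        if spec.standardize:
            est = Pipeline([("scale", StandardScaler()), ("clf", est)])
        return est

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter":
        self._model = self._build(y)
        if self.spec.family == "gradient_boosting":
            # per-sample weights proportional to inverse class frequency,
            # normalized to sum to n
            n = y.size
            counts = np.bincount(y.astype(int), minlength=2)
            w = n / (2.0 * counts[y.astype(int)])
            self._model.fit(X, y, sample_weight=w)
        else:
            self._model.fit(X, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise InvalidInputError("adapter is not fitted")
        return self._model.predict_proba(X)[:, 1]


@dataclass
class EvalResult:
    """Test-set performance of one (selector, model) pair."""

    selector: str
    model: str
    threshold: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "selector": self.selector,
            "model": self.model,
            "threshold": float(self.threshold),
            "accuracy": float(self.accuracy),
            "precision": float(self.precision),
            "recall": float(self.recall),
            "f1": float(self.f1),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
        }


@dataclass
class EvalRun:
    """EvalResult plus the artifacts paired tests and importance need."""

    result: EvalResult
    model: ClassifierAdapter
    features: list[str]
    scores_test: np.ndarray
    y_test: np.ndarray
    y_pred: np.ndarray
    X_test: np.ndarray = field(repr=False, default=None)


def run_two_stage(
    data: FeatureTable,
    features: list[str],
    model: ModelSpec,
    split: SplitSpec,
    selector: str = "",
    B_auc: int = 1000,
    grid: int = 999,
    ci_seed: int = 0,
) -> EvalRun:
    """Stage-1 threshold selection, stage-2 final fit and test evaluation.

    No test-set information is used before the final scoring: the threshold
    is frozen on the validation rows and the final model is refit on
    train+validation with scalers/calibrators re-fit.
    """
    unknown = [f for f in features if f not in data.feature_names]
    if unknown:
        raise InvalidInputError(f"unknown features: {unknown}")
    cols = [data.feature_names.index(f) for f in features]
    X, y = data.X[:, cols], data.y

    # Stage 1: fit on the inner training rows, pick threshold on validation
    stage1 = ClassifierAdapter(model).fit(X[split.train_idx], y[split.train_idx])
    s_val = stage1.predict_proba1(X[split.val_idx])
    threshold = select_threshold(s_val, y[split.val_idx], grid=grid)

    # Stage 2: refit identically on train+validation, score test once
    full_idx = np.sort(np.concatenate([split.train_idx, split.val_idx]))
    final = ClassifierAdapter(model).fit(X[full_idx], y[full_idx])
    s_test = final.predict_proba1(X[split.test_idx])
    y_test = y[split.test_idx]
    y_pred = (s_test >= threshold).astype(int)
    acc, prec, rec, f1 = compute_metrics(y_test, y_pred)
    auc = roc_auc(y_test, s_test)
    ci = auc_bootstrap_ci(y_test, s_test, B=B_auc, seed=ci_seed)
    result = EvalResult(
        selector=selector, model=model.family, threshold=threshold,
        accuracy=acc, precision=prec, recall=rec, f1=f1, auc=auc, auc_ci=ci,
    )
    return EvalRun(
        result=result, model=final, features=list(features),
        scores_test=s_test, y_test=y_test, y_pred=y_pred,
        X_test=X[split.test_idx],
    )


def permutation_importance(
    model: ClassifierAdapter,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_repeats: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the AUC drop when each column is randomly permuted.

    The full fitted scoring path (preprocessing + calibration) is applied to
    the permuted inputs, so the importance reflects the deployed model.
    """
    rng = np.random.default_rng(seed)
    baseline = roc_auc(y_test, model.predict_proba1(X_test))
    n, d = X_test.shape
    mean = np.empty(d)
    sd = np.empty(d)
    for j in range(d):
        drops = np.empty(n_repeats)
        Xp = X_test.copy()
        for r in range(n_repeats):
            Xp[:, j] = X_test[rng.permutation(n), j]
            drops[r] = baseline - roc_auc(y_test, model.predict_proba1(Xp))
        mean[j], sd[j] = drops.mean(), drops.std()
    return mean, sd
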