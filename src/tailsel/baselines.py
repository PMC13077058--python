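"""Comparison selectors: mutual information, mRMR, ReliefF, elastic-net.

All four operate on the training split only and return the same
:class:`~tailsel.data.RankingResult` as the tail filter, so downstream
evaluation treats every selector identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._errors import InvalidInputError
from .data import FeatureTable, RankingResult


@dataclass
class SelectorConfig:
    """Knobs for the baseline selectors.

    Defaults mirror the reference protocol: kNN mutual-information estimator
    with 3 neighbours over continuous features, ReliefF with 10 hits/misses,
    elastic-net logistic with mixing 0.5 and unit penalty strength.
    """

    k: int = 10
    mi_neighbors: int = 3
    relieff_neighbors: int = 10
    l1en_mixing: float = 0.5
    l1en_strength: float = 1.0
    seed: int = 0


def _rank_from_scores(
    method: str, names: list[str], scores: np.ndarray, k: int
) -> RankingResult:
    """Descending-score ordering with column order as the tie-break."""
    order = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    return RankingResult(
        method=method,
        ordered_features=[names[j] for j in order],
        scores=[float(scores[j]) for j in order],
        k=k,
    )


def mi_scores(data: FeatureTable, config: SelectorConfig | None = None) -> np.ndarray:
    """Per-feature mutual information with the label, in nats.

    Uses the kNN (Kraskov-family) estimator treating every feature as
    continuous; the estimator applies its own tiny seeded jitter to break
    discrete ties, so repeated calls with the same seed are identical.
    """
    config = config or SelectorConfig()
    return mutual_info_classif(
        data.X,
        data.y,
        discrete_features=False,
        n_neighbors=config.mi_neighbors,
        random_state=config.seed,
    )


def mi_rank(data: FeatureTable, config: SelectorConfig | None = None) -> RankingResult:
    config = config or SelectorConfig()
    return _rank_from_scores("mi", data.feature_names, mi_scores(data, config), config.k)


def mrmr_select(
    data: FeatureTable, k: int | None = None, config: SelectorConfig | None = None
) -> RankingResult:
    """Greedy minimum-redundancy maximum-relevance selection.

    The first pick maximizes mutual information with the label; each later
    pick maximizes MI minus the mean absolute Pearson correlation with the
    features already chosen. Correlation against a constant column is defined
    as 0; greedy ties break by column order. The greedy run continues to
    exhaustion so the ordering is a full permutation, with ``k`` marking the
    selected prefix.
    """
    config = config or SelectorConfig()
    k = config.k if k is None else k
    d = data.d
    if not 1 <= k <= d:
        raise InvalidInputError(f"k must lie in [1, {d}], got {k}")
    relevance = mi_scores(data, config)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(data.X, rowvar=False))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)

    chosen: list[int] = []
    objective: list[float] = []
    remaining = list(range(d))
    while remaining:
        if not chosen:
            scores = [relevance[j] for j in remaining]
        else:
            scores = [
                relevance[j] - corr[j, chosen].mean() for j in remaining
            ]
        best = int(np.argmax(scores))  # argmax keeps first max: column order
        objective.append(float(scores[best]))
        chosen.append(remaining.pop(best))
    return RankingResult(
        method="mrmr",
        ordered_features=[data.feature_names[j] for j in chosen],
        scores=objective,
        k=k,
    )


def relieff_scores(
    data: FeatureTable, config: SelectorConfig | None = None
) -> np.ndarray:
    """Binary ReliefF scores over z-scored features.

    For every training instance we take the ``m`` nearest same-class
    neighbours (hits, excluding self) and ``m`` nearest other-class
    neighbours (misses) under Euclidean distance over all z-scored features
    (``m`` clipped to availability). Each feature accumulates the mean
    absolute difference to misses minus the mean absolute difference to hits,
    averaged over all instances. Positive scores mean the feature separates
    classes locally.
    """
    config = config or SelectorConfig()
    y = data.y
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise InvalidInputError(f"class {c} needs at least 2 members")
    Z = StandardScaler().fit_transform(data.X)
    # constant columns scale to 0 variance -> sklearn leaves them at 0
    n, d = Z.shape
    m = config.relieff_neighbors
    sq = (Z**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.maximum(D2, 0.0, out=D2)

    scores = np.zeros(d)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(D2[i, same], kind="stable")[: min(m, same.size)]]
        misses = other[np.argsort(D2[i, other], kind="stable")[: min(m, other.size)]]
        scores += (
            np.abs(Z[misses] - Z[i]).mean(axis=0)
            - np.abs(Z[hits] - Z[i]).mean(axis=0)
        )
    return scores / n


def relieff_rank(
    data: FeatureTable, config: SelectorConfig | None = None
) -> RankingResult:
    config = config or SelectorConfig()
    return _rank_from_scores(
        "relieff", data.feature_names, relieff_scores(data, config), config.k
    )


def l1en_rank(
    data: FeatureTable, config: SelectorConfig | None = None
) -> RankingResult:
    """Elastic-net logistic ranking by absolute coefficient magnitude.

    Features are standardized on this split, the penalized logistic model is
    fit with balanced class weights (saga solver, iteration cap 4000), and
    features are ordered by descending ``|beta_j|``. Exactly-zero coefficients
    rank after all nonzero ones, in original column order. Non-convergence at
    the cap warns and ranks with the last iterate.
    """
    config = config or SelectorConfig()
    Z = StandardScaler().fit_transform(data.X)
    model = LogisticRegression(
        solver="saga",
        l1_ratio=config.l1en_mixing,
        C=1.0 / config.l1en_strength,
        class_weight="balanced",
        max_iter=4000,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        model.fit(Z, data.y)
    coefs = np.abs(model.coef_.ravel())
    order = sorted(
        range(data.d), key=lambda j: (coefs[j] == 0.0, -coefs[j], j)
    )
    return RankingResult(
        method="l1en",
        ordered_features=[data.feature_names[j] for j in order],
        scores=[float(coefs[j]) for j in order],
        k=config.k,
    )
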