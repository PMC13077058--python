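"""The Gumbel upper-tail concordance filter, statsmodels-style.

``GumbelTailFilter(table).fit()`` scores every feature against the label,
optionally bootstraps the training rows for percentile confidence intervals,
and returns a :class:`GumbelTailResults` carrying the estimates, their
uncertainty, a ``summary()`` table, and the top-k ranking.

The selector never fits a predictive model: its cost is one rank pass for the
label plus one O(n log n) tau per feature, O(d n log n) in total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .copula import TailScore, lambda_u_from_tau, lambda_u_score
from .data import FeatureTable, RankingResult

logger = logging.getLogger(__name__)


def score_features(data: FeatureTable) -> list[TailScore]:
    """One :class:`TailScore` per feature column.

    Constant columns are flagged degenerate and scored 0 instead of aborting
    the screen; everything else goes through the full scoring chain.
    """
    return [
        lambda_u_score(data.X[:, j], data.y, feature=name)
        for j, name in enumerate(data.feature_names)
    ]


def bootstrap_lambda_ci(
    data: FeatureTable, B: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Bootstrap the rows ``B`` times and recompute lambda_U per feature.

    Plain (unstratified) row resampling with replacement; pseudo-observations
    and tau are recomputed inside every resample, since ranks change under
    resampling. A resample that draws only one class contributes lambda=0 for
    every feature and is counted. Returns ``(boot_mean, ci_low, ci_high,
    n_single_class)`` with 2.5/97.5 percentile bounds, deterministic by seed.
    """
    if B < 2:
        raise InvalidInputError("need B >= 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n, d = data.n, data.d
    lams = np.zeros((B, d))
    n_single = 0
    from scipy.stats import kendalltau  # local import keeps hot loop tight

    for b in range(B):
        rows = rng.integers(0, n, size=n)
        yb = data.y[rows]
        if yb.min() == yb.max():
            n_single += 1
            continue  # row of zeros already in place
        Xb = data.X[rows]
        for j in range(d):
            col = Xb[:, j]
            if np.ptp(col) == 0:
                continue
            tau = kendalltau(col, yb, variant="b").statistic
            lams[b, j] = lambda_u_from_tau(float(tau))
    if n_single:
        logger.info("bootstrap: %d of %d resamples were single-class", n_single, B)
    lo, hi = np.percentile(lams, [2.5, 97.5], axis=0)
    return lams.mean(axis=0), lo, hi, n_single


def rank_and_select(scores: list[TailScore], k: int) -> RankingResult:
    """Top-k ranking by descending lambda_U.

    Ties are broken by descending tau, then original column order, so the
    ranking is deterministic and reproducible.
    """
    d = len(scores)
    if not 1 <= k <= d:
        raise InvalidInputError(f"k must lie in [1, {d}], got {k}")
    order = sorted(range(d), key=lambda j: (-scores[j].lambda_u, -scores[j].tau, j))
    return RankingResult(
        method="gumbel",
        ordered_features=[scores[j].feature for j in order],
        scores=[scores[j].lambda_u for j in order],
        k=k,
    )


class GumbelTailFilter:
    """Supervised filter ranking features by Gumbel-implied lambda_U.

    Parameters
    ----------
    data
        The feature table (typically the *training split only*, so that
        selection never sees test rows).
    """

    def __init__(self, data: FeatureTable):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "label") -> "GumbelTailFilter":
        return cls(FeatureTable.from_dataframe(df, label=label))

    def fit(
        self, bootstrap: bool = True, B: int = 1000, seed: int = 0
    ) -> "GumbelTailResults":
        scores = score_features(self.data)
        n_single = 0
        if bootstrap:
            mean, lo, hi, n_single = bootstrap_lambda_ci(self.data, B=B, seed=seed)
            for j, s in enumerate(scores):
                s.boot_mean, s.ci_low, s.ci_high = float(mean[j]), float(lo[j]), float(hi[j])
        return GumbelTailResults(
            model=self, scores=scores, B=B if bootstrap else 0, seed=seed,
            n_single_class_resamples=n_single,
        )


@dataclass
class GumbelTailResults:
    """Fit output of :class:`GumbelTailFilter`."""

    model: GumbelTailFilter
    scores: list[TailScore]
    B: int = 0
    seed: int = 0
    n_single_class_resamples: int = 0
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """Per-feature estimates as a DataFrame (one row per column)."""
        if self._frame is None:
            self._frame = pd.DataFrame([s.to_dict() for s in self.scores])
        return self._frame

    def rank(self, k: int | None = None) -> RankingResult:
        return rank_and_select(self.scores, k if k is not None else len(self.scores))

    def summary(self) -> str:
        """Readable per-feature table, ordered by the selection ranking."""
        df = self.frame.sort_values(
            ["lambda_u", "tau"], ascending=False, kind="stable"
        ).reset_index(drop=True)
        lines = [
            "Gumbel upper-tail concordance filter",
            f"  n = {self.model.data.n}, d = {self.model.data.d}, "
            f"bootstrap B = {self.B}",
            "",
            f"{'feature':<28}{'tau':>9}{'theta':>9}{'lambda_U':>10}"
            f"{'ci_low':>9}{'ci_high':>9}",
        ]
        for _, r in df.iterrows():
            theta = "-" if r.theta is None or pd.isna(r.theta) else f"{r.theta:.3f}"
            lo = "-" if r.ci_low is None or pd.isna(r.ci_low) else f"{r.ci_low:.3f}"
            hi = "-" if r.ci_high is None or pd.isna(r.ci_high) else f"{r.ci_high:.3f}"
            flag = " (degenerate)" if r.degenerate else ""
            lines.append(
                f"{r.feature:<28}{r.tau:>9.4f}{theta:>9}{r.lambda_u:>10.4f}"
                f"{lo:>9}{hi:>9}{flag}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([s.to_dict() for s in self.scores], indent=2)
        )
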