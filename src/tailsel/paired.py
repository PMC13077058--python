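"""Paired comparisons of two classifiers on a shared test set.

DeLong's test compares the two correlated ROC-AUCs while accounting for the
covariance of the per-instance structural components; McNemar's test (with
continuity correction) compares the paired error profiles through the
discordant counts b and c. Both are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import InvalidInputError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class PairedTestResult:
    delta_auc: float
    delong_z: float
    delong_p: float
    mcnemar_chi2: float
    mcnemar_p: float
    discordant_counts: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "delta_auc": float(self.delta_auc),
            "delong_z": float(self.delong_z),
            "delong_p": float(self.delong_p),
            "mcnemar_chi2": float(self.mcnemar_chi2),
            "mcnemar_p": float(self.mcnemar_p),
            "discordant_counts": [int(c) for c in self.discordant_counts],
        }


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-instance structural components (V10 positives, V01 negatives).

    Midranks handle tied scores: V10_i = Pr-hat(s_i > s-) + 1/2 Pr-hat(s_i = s-)
    for positive instance i, and symmetrically for negatives.
    """
    pos = s[y == 1]
    neg = s[y == 0]
    m, n_neg = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n_neg
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(
    y: np.ndarray, sA: np.ndarray, sB: np.ndarray
) -> tuple[float, float, float]:
    """Two-sided DeLong comparison of correlated AUCs.

    Returns ``(delta_auc, z, p)`` with ``delta_auc = AUC_A - AUC_B``. Zero
    variance of the difference (e.g. identical score vectors) yields
    ``z = 0, p = 1`` by convention.
    """
    y = np.asarray(y).astype(int)
    sA = np.asarray(sA, dtype=float)
    sB = np.asarray(sB, dtype=float)
    if not (y.shape == sA.shape == sB.shape):
        raise InvalidInputError("y, sA, sB must share a shape")
    m = int(y.sum())
    n_neg = y.size - m
    if m == 0 or n_neg == 0:
        raise UndefinedStatisticError("DeLong needs both classes")

    aucA, v10A, v01A = _delong_components(y, sA)
    aucB, v10B, v01B = _delong_components(y, sB)
    v10 = np.vstack([v10A, v10B])
    v01 = np.vstack([v01A, v01B])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    S = s10 / m + s01 / n_neg
    delta = aucA - aucB
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    if var <= 0:
        logger.info("delong: zero variance of the AUC difference; p=1 by convention")
        return delta, 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return delta, float(z), float(p)


def delong_variance(y: np.ndarray, s: np.ndarray) -> float:
    """DeLong variance estimate of a single AUC (used for diagnostics)."""
    y = np.asarray(y).astype(int)
    m = int(y.sum())
    n_neg = y.size - m
    _, v10, v01 = _delong_components(y, np.asarray(s, dtype=float))
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n_neg)


def mcnemar_test(
    correctA: np.ndarray, correctB: np.ndarray
) -> tuple[float, float, tuple[int, int]]:
    """Continuity-corrected McNemar test on paired correctness vectors.

    ``b`` counts instances A got right and B got wrong; ``c`` the reverse.
    ``chi2 = (|b-c|-1)^2/(b+c)`` with an upper chi-square(1) tail; no
    discordance (b+c=0) yields ``chi2=0, p=1`` by convention.
    """
    correctA = np.asarray(correctA).astype(bool)
    correctB = np.asarray(correctB).astype(bool)
    if correctA.shape != correctB.shape:
        raise InvalidInputError("length mismatch")
    b = int(np.sum(correctA & ~correctB))
    c = int(np.sum(~correctA & correctB))
    if b + c == 0:
        return 0.0, 1.0, (b, c)
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, (b, c)


def compare_runs(y, sA, sB, predA, predB) -> PairedTestResult:
    """Bundle both paired tests for two models sharing a test split."""
    y = np.asarray(y).astype(int)
    delta, z, p = delong_test(y, sA, sB)
    chi2, mp, (b, c) = mcnemar_test(
        np.asarray(predA).astype(int) == y, np.asarray(predB).astype(int) == y
    )
    return PairedTestResult(
        delta_auc=delta, delong_z=z, delong_p=p,
        mcnemar_chi2=chi2, mcnemar_p=mp, discordant_counts=(b, c),
    )
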