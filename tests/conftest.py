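import numpy as np
import pytest

from tailsel import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table(rng):
    """n=200 table: one noisy copy of the label, one anti-concordant
    feature, one pure-noise feature."""
    n = 200
    y = rng.integers(0, 2, n)
    signal = y + 0.3 * rng.standard_normal(n)
    anti = 1 - y + 0.3 * rng.standard_normal(n)
    noise = rng.standard_normal(n)
    return FeatureTable(
        np.column_stack([signal, anti, noise]), ["signal", "anti", "noise"], y
    )


def brute_force_tau(u, v):
    """O(n^2) all-pairs tau-b with tie-corrected denominator."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    n = u.size
    num = 0
    tu = tv = 0
    for i in range(n):
        for j in range(i + 1, n):
            du, dv = u[i] - u[j], v[i] - v[j]
            num += np.sign(du) * np.sign(dv)
            if du == 0:
                tu += 1
            if dv == 0:
                tv += 1
    n0 = n * (n - 1) / 2
    return num / np.sqrt((n0 - tu) * (n0 - tv))


def make_mrmr_fixture(seed, n=4000):
    """Binary table whose greedy mRMR trace has wide decision margins.

    f0 dominates, f1 is a slightly weaker near-duplicate (heavy redundancy
    penalty), f2 is the single null, f3/f4 carry graded signal. Every greedy
    argmax is separated by far more than MI-estimator noise, so the estimator
    route and a plug-in-MI route must produce the same trace.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    deltas = [0.90, 0.85, 0.0, 0.50, 0.30]
    X = np.empty((n, len(deltas)))
    for j, delta in enumerate(deltas):
        p = 0.5 + delta * (2 * y - 1) / 2
        X[:, j] = rng.random(n) < p
    return FeatureTable(X, [f"f{j}" for j in range(len(deltas))], y)


def plugin_discrete_mi(x, y):
    """Plug-in mutual information from the empirical joint table, in nats."""
    x = np.asarray(x)
    y = np.asarray(y)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * np.log(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return mi


def greedy_mrmr_reference(X, relevance):
    """Independent greedy: relevance minus mean |Pearson corr| to chosen."""
    d = X.shape[1]
    corr = np.nan_to_num(np.abs(np.corrcoef(X, rowvar=False)), nan=0.0)
    chosen, remaining = [], list(range(d))
    while remaining:
        scores = [
            relevance[j] - (corr[j, chosen].mean() if chosen else 0.0)
            for j in remaining
        ]
        chosen.append(remaining.pop(int(np.argmax(scores))))
    return chosen


def brute_force_auc(y, s):
    """O(n^2) pair enumeration of Pr(s+ > s-) + 1/2 Pr(s+ = s-)."""
    y = np.asarray(y, int)
    s = np.asarray(s, float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)
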