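"""Seeded synthetic-data generators.

Three generators cover the testing needs of the whole package:

* :func:`sample_gumbel` — exact Gumbel-copula pairs via the positive-stable
  mixture construction, for parameter-recovery checks of the tau -> theta ->
  lambda_U chain;
* :func:`make_cdc_like` — a survey-style table (mostly binary/ordinal
  features, low prevalence) with planted risk-increasing, protective and
  null features, generated from a thresholded latent risk score so the
  planted concordance signs hold in expectation;
* :func:`make_pima_like` — a small clinical table of eight continuous
  physiological features with a glucose-like dominant signal and literal
  zeros injected into five designated columns.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DomainError, InvalidInputError
from .data import FeatureTable


@dataclass
class CopulaSample:
    """A bivariate sample with uniform marginals and known dependence."""

    u: np.ndarray
    v: np.ndarray
    theta_true: float
    seed: int


def sample_gumbel(n: int, theta: float, seed: int = 0) -> CopulaSample:
    """Exact Gumbel(theta) copula sample of size ``n``.

    Uses the Marshall–Olkin positive-stable mixture: with S a positive
    alpha-stable variate (alpha = 1/theta, Chambers–Mallows–Stuck transform)
    and E1, E2 iid Exp(1),

        U = exp(-(E1/S)**(1/theta)),  V = exp(-(E2/S)**(1/theta)).

    theta = 1 short-circuits to independent uniforms.
    """
    if theta < 1.0:
        raise DomainError(f"theta must be >= 1, got {theta}")
    rng = np.random.default_rng(seed)
    if theta == 1.0:
        return CopulaSample(rng.uniform(size=n), rng.uniform(size=n), 1.0, seed)
    alpha = 1.0 / theta
    w = rng.uniform(0.0, np.pi, size=n)
    e = rng.exponential(size=n)
    s = (
        np.sin(alpha * w) / np.sin(w) ** (1.0 / alpha)
        * (np.sin((1.0 - alpha) * w) / e) ** ((1.0 - alpha) / alpha)
    )
    e1 = rng.exponential(size=n)
    e2 = rng.exponential(size=n)
    u = np.exp(-((e1 / s) ** alpha))
    v = np.exp(-((e2 / s) ** alpha))
    return CopulaSample(u, v, float(theta), seed)


@dataclass
class FixtureSpec:
    """Blueprint for a survey-style synthetic table.

    ``frac_positive_tau`` / ``frac_negative_tau`` fix how many features are
    planted risk-increasing / protective (the rest are null).
    ``feature_kinds`` optionally assigns per-feature margins
    (binary | ordinal | continuous); by default margins are assigned
    round-robin, biased towards binary, mirroring survey data.
    """

    n: int = 5000
    d: int = 21
    frac_positive_tau: float = 8 / 21
    frac_negative_tau: float = 5 / 21
    prevalence: float = 0.14
    feature_kinds: list[str] | None = None
    seed: int = 0

    # latent weights: risk-increasing strongest first, protective modest
    positive_weight_range: tuple[float, float] = (1.0, 0.5)
    negative_weight: float = -0.25
    noise_sd: float = 1.0


@dataclass
class SyntheticFixture:
    """A generated table plus the planted ground truth for tests."""

    table: FeatureTable
    truth: dict = field(default_factory=dict)


def cdc_like_spec(n: int = 5000, seed: int = 0) -> FixtureSpec:
    """The canonical survey fixture: 8 risk, 5 protective, 8 null features."""
    return FixtureSpec(n=n, seed=seed)


def sufficiency_spec(n: int = 5000, seed: int = 0) -> FixtureSpec:
    """Strong-signal fixture: all signal is positive-concordant.

    With no protective features, the top-k positive-tail features carry the
    entire planted signal, so a model on the selected set should match a
    model on all features. Used for the sufficiency and robustness checks.
    """
    return FixtureSpec(
        n=n, seed=seed, frac_positive_tau=8 / 21, frac_negative_tau=0.0
    )


def _default_kinds(d: int, rng: np.random.Generator) -> list[str]:
    # mostly binary with some ordinal and an occasional continuous column
    kinds = []
    for j in range(d):
        if j % 7 == 0:
            kinds.append("continuous")
        elif j % 3 == 0:
            kinds.append("ordinal")
        else:
            kinds.append("binary")
    return kinds


def make_cdc_like(spec: FixtureSpec) -> SyntheticFixture:
    """Survey-style fixture from a thresholded latent risk score.

    Independent latent normals Z_j combine through planted weights into a
    risk score R = sum_j w_j Z_j + noise; the label thresholds R at the
    (1 - prevalence) quantile. Observed features are monotone cuts of the
    latents (binary / ordinal) or the latents themselves, so the planted
    concordance signs survive discretization in expectation.
    """
    if not 0.0 < spec.prevalence < 1.0:
        raise InvalidInputError("prevalence must lie strictly in (0, 1)")
    n, d = spec.n, spec.d
    n_pos = int(round(spec.frac_positive_tau * d))
    n_neg = int(round(spec.frac_negative_tau * d))
    if n_pos + n_neg > d:
        raise InvalidInputError("planted signal fractions exceed the table width")
    if n_pos < 1:
        raise InvalidInputError("need at least one risk-increasing feature")
    min_prev = 1.0 / n
    if spec.prevalence < min_prev or spec.prevalence > 1 - min_prev:
        raise InvalidInputError("prevalence infeasible at this n")

    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((n, d))
    weights = np.zeros(d)
    weights[:n_pos] = np.linspace(*spec.positive_weight_range, n_pos)
    weights[n_pos : n_pos + n_neg] = spec.negative_weight
    risk = Z @ weights + spec.noise_sd * rng.standard_normal(n)
    y = (risk > np.quantile(risk, 1.0 - spec.prevalence)).astype(int)
    if y.sum() in (0, n):
        raise InvalidInputError("prevalence infeasible: degenerate label")

    kinds = spec.feature_kinds or _default_kinds(d, rng)
    if len(kinds) != d:
        raise InvalidInputError("feature_kinds length must equal d")
    X = np.empty((n, d))
    for j in range(d):
        if kinds[j] == "continuous":
            X[:, j] = Z[:, j]
        elif kinds[j] == "binary":
            rate = rng.uniform(0.25, 0.55)
            X[:, j] = (Z[:, j] > np.quantile(Z[:, j], 1 - rate)).astype(float)
        elif kinds[j] == "ordinal":
            levels = int(rng.integers(4, 9))
            edges = np.quantile(Z[:, j], np.linspace(0, 1, levels + 1)[1:-1])
            X[:, j] = np.digitize(Z[:, j], edges).astype(float)
        else:
            raise InvalidInputError(f"unknown feature kind {kinds[j]!r}")
    names = [f"x{j + 1:02d}" for j in range(d)]
    truth = {
        "weights": weights.tolist(),
        "kinds": kinds,
        "positive_features": names[:n_pos],
        "negative_features": names[n_pos : n_pos + n_neg],
        "null_features": names[n_pos + n_neg :],
        "prevalence": float(y.mean()),
        "seed": spec.seed,
    }
    return SyntheticFixture(FeatureTable(X, names, y), truth)


#: columns of the clinical fixture that receive literal zeros, with the
#: approximate zero rates seen in the classic 768-row benchmark
PIMA_ZERO_COLUMNS = {
    "glucose": 0.007,
    "blood_pressure": 0.046,
    "skin_thickness": 0.30,
    "insulin": 0.49,
    "bmi": 0.014,
}

_PIMA_FEATURES = [
    ("pregnancies", 0.30),
    ("glucose", 1.20),
    ("blood_pressure", 0.15),
    ("skin_thickness", 0.30),
    ("insulin", 0.35),
    ("bmi", 0.50),
    ("pedigree", 0.25),
    ("age", 0.50),
]


def make_pima_like(n: int = 768, seed: int = 0) -> SyntheticFixture:
    """Clinical-style fixture: 8 continuous features, glucose dominant.

    Latent standard normals drive a thresholded risk score (prevalence
    ~0.35); observed features are affine maps of the latents onto plausible
    physiological scales. Literal zeros are then injected into the five
    designated columns at rates mirroring the classic benchmark, emulating
    the zeros-as-missing convention.
    """
    if n < 50:
        raise InvalidInputError("need n >= 50")
    rng = np.random.default_rng(seed)
    names = [f for f, _ in _PIMA_FEATURES]
    weights = np.array([w for _, w in _PIMA_FEATURES])
    d = len(names)
    Z = rng.standard_normal((n, d))
    risk = Z @ weights + rng.standard_normal(n)
    y = (risk > np.quantile(risk, 0.65)).astype(int)

    scales = {
        "pregnancies": (3.8, 3.3), "glucose": (121.0, 30.0),
        "blood_pressure": (72.0, 12.0), "skin_thickness": (29.0, 10.0),
        "insulin": (155.0, 85.0), "bmi": (32.0, 7.0),
        "pedigree": (0.47, 0.33), "age": (33.0, 11.0),
    }
    X = np.empty((n, d))
    for j, name in enumerate(names):
        mu, sd = scales[name]
        col = mu + sd * Z[:, j]
        col = np.maximum(col, 0.1)  # physiological floor; zeros only injected below
        if name == "pregnancies":
            col = np.maximum(np.round(col), 1.0)
        X[:, j] = col
    for name, rate in PIMA_ZERO_COLUMNS.items():
        j = names.index(name)
        k = int(round(rate * n))
        if k:
            X[rng.choice(n, size=k, replace=False), j] = 0.0
    truth = {
        "weights": weights.tolist(),
        "dominant_feature": "glucose",
        "zero_columns": list(PIMA_ZERO_COLUMNS),
        "prevalence": float(y.mean()),
        "seed": seed,
    }
    return SyntheticFixture(FeatureTable(X, names, y), truth)
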