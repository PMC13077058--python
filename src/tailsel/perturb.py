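"""Robustness stressors: label flips, proportional feature noise, MCAR
masking with train-median imputation, and zero-as-missing preprocessing.

All perturbations are seeded-deterministic, use exact counts
(``round(frac * n)``) rather than Bernoulli draws so perturbation sizes are
reproducible, and leave untouched entries bit-identical. Test labels are
never perturbed; medians are always fit on training rows only.
"""

from __future__ import annotations

import numpy as np

from ._errors import InvalidInputError
from .data import FeatureTable
from .evaluate import SplitSpec


def flip_labels(y: np.ndarray, frac: float = 0.05, seed: int = 0) -> np.ndarray:
    """Flip exactly ``round(frac*n)`` distinct labels, chosen uniformly."""
    if not 0.0 <= frac <= 1.0:
        raise InvalidInputError("frac must lie in [0, 1]")
    y = np.asarray(y).astype(int).copy()
    n_flip = int(round(frac * y.size))
    if n_flip == 0:
        return y
    rng = np.random.default_rng(seed)
    idx = rng.choice(y.size, size=n_flip, replace=False)
    y[idx] = 1 - y[idx]
    return y


def add_feature_noise(
    X_train: np.ndarray,
    X_test: np.ndarray,
    sigma_frac: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add N(0, (sigma_frac * SD_train(j))^2) noise to both splits.

    The per-feature scale is computed on the training split only; constant
    features (zero SD) pass through unchanged in both splits.
    """
    if sigma_frac < 0:
        raise InvalidInputError("sigma_frac must be >= 0")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if sigma_frac == 0:
        return X_train.copy(), X_test.copy()
    sd = X_train.std(axis=0)
    rng = np.random.default_rng(seed)
    noise_tr = rng.standard_normal(X_train.shape) * (sigma_frac * sd)
    noise_te = rng.standard_normal(X_test.shape) * (sigma_frac * sd)
    return X_train + noise_tr, X_test + noise_te


def apply_mcar_impute(
    X_train: np.ndarray,
    X_test: np.ndarray,
    frac: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """MCAR-mask exactly ``round(frac*n)`` entries per feature per split,
    then impute both splits with the median of the *unmasked training*
    entries of that feature. Returns the imputed splits and the boolean
    masks ``{"train": ..., "test": ...}``.
    """
    if not 0.0 <= frac < 1.0:
        raise InvalidInputError("frac must lie in [0, 1)")
    X_train = np.asarray(X_train, dtype=float).copy()
    X_test = np.asarray(X_test, dtype=float).copy()
    rng = np.random.default_rng(seed)
    mask_tr = np.zeros(X_train.shape, dtype=bool)
    mask_te = np.zeros(X_test.shape, dtype=bool)
    for j in range(X_train.shape[1]):
        k_tr = int(round(frac * X_train.shape[0]))
        k_te = int(round(frac * X_test.shape[0]))
        if k_tr:
            mask_tr[rng.choice(X_train.shape[0], size=k_tr, replace=False), j] = True
        if k_te:
            mask_te[rng.choice(X_test.shape[0], size=k_te, replace=False), j] = True
        observed = X_train[~mask_tr[:, j], j]
        if observed.size == 0:
            raise InvalidInputError(
                f"feature {j}: no observed training entries left at frac={frac}"
            )
        med = float(np.median(observed))
        X_train[mask_tr[:, j], j] = med
        X_test[mask_te[:, j], j] = med
    return X_train, X_test, {"train": mask_tr, "test": mask_te}


def zeros_as_missing(
    data: FeatureTable, columns: list[str], split: SplitSpec
) -> FeatureTable:
    """Treat literal zeros in the named columns as missing physiological
    readings: the imputation median is fit on the *nonzero training-row*
    values only and applied to every row (train, validation and test).
    """
    missing = [c for c in columns if c not in data.feature_names]
    if missing:
        raise InvalidInputError(f"unknown columns: {missing}")
    X = data.X.copy()
    train_rows = np.sort(np.concatenate([split.train_idx, split.val_idx]))
    for name in columns:
        j = data.feature_names.index(name)
        observed = X[train_rows, j]
        observed = observed[observed != 0]
        if observed.size == 0:
            raise InvalidInputError(f"column {name!r} is all-zero on train")
        med = float(np.median(observed))
        X[X[:, j] == 0, j] = med
    return FeatureTable(X, list(data.feature_names), data.y.copy())
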