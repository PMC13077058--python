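"""Tabular containers shared by every stage of the screening pipeline.

A :class:`FeatureTable` is the universal input: an ``n x d`` numeric matrix of
features (binary, ordinal or continuous) paired with a binary 0/1 label.
:class:`RankingResult` is the universal selector output: an ordered feature
list with aligned scores and the selection size ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidInputError


@dataclass
class FeatureTable:
    """An ``n x d`` feature matrix with names and a binary label vector.

    Invariants enforced at construction: ``n >= 3``, the label contains both
    classes, feature names are unique, and every feature entry is finite
    (missing values only ever exist transiently inside the perturbation
    routines, never in a FeatureTable).
    """

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.feature_names = list(self.feature_names)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 3:
            raise InvalidInputError(f"need at least 3 rows, got {n}")
        if len(self.feature_names) != d:
            raise InvalidInputError(
                f"{len(self.feature_names)} names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            raise InvalidInputError("duplicate feature names")
        if self.y.shape != (n,):
            raise InvalidInputError("label length must match row count")
        uniq = set(np.unique(self.y).tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise InvalidInputError("label must contain both classes 0 and 1")
        self.y = self.y.astype(int)
        if not np.all(np.isfinite(self.X)):
            raise InvalidInputError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def subset(self, names: list[str]) -> "FeatureTable":
        """Table restricted to ``names`` (order preserved as given)."""
        idx = [self.feature_names.index(f) for f in names]
        return FeatureTable(self.X[:, idx], list(names), self.y.copy())

    def take_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[idx], list(self.feature_names), self.y[idx])

    def to_dataframe(self, label: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label] = self.y
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "label") -> "FeatureTable":
        if label not in df.columns:
            raise InvalidInputError(
                f"label column {label!r} not found; columns are {list(df.columns)}"
            )
        feats = [c for c in df.columns if c != label]
        X = df[feats].to_numpy(dtype=float)
        return cls(X, feats, df[label].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "label") -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), label=label)

    def to_csv(self, path: str | Path, label: str = "label") -> None:
        self.to_dataframe(label).to_csv(path, index=False)


@dataclass
class RankingResult:
    """Ordered feature list produced by a selector.

    ``ordered_features`` is a permutation of all feature names; the first
    ``k`` entries define the selected set. ``scores`` are aligned with the
    ordering (non-increasing for score-based selectors).
    """

    method: str
    ordered_features: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    k: int = 0

    @property
    def selected(self) -> list[str]:
        return self.ordered_features[: self.k]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ordered_features": list(self.ordered_features),
            "scores": [float(s) for s in self.scores],
            "k": int(self.k),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
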