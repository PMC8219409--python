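"""Preprocessing: mean/mode imputation and discretization of numeric features.

Imputation replaces missing cells column-wise: numeric features get the mean
of the observed values, ordinal/binary/categorical features the mode.
Discretization maps each numeric feature to ordinal bin codes ``0..k-1``
via ascending cut points; intervals are half-open ``[a, b)`` so a value equal
to a boundary lands in the upper bin.  Three fitting methods are available:

``equal_width``
    ``bins`` equally wide intervals between the observed min and max.
``equal_frequency``
    interior quantile boundaries, deduplicated.
``mdl_entropy``
    supervised recursive binary splitting on class entropy, candidate cuts
    at class-boundary midpoints, each cut accepted only if its information
    gain clears the minimum-description-length cost of encoding it
    (Fayyad–Irani criterion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortDataset

METHODS = ("equal_frequency", "equal_width", "mdl_entropy")


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

class MeanModeImputer(BaseEstimator, TransformerMixin):
    """Column-wise mean (numeric) / mode (discrete) imputer for DataFrames.

    Parameters
    ----------
    value_kinds : dict or None
        Mapping column -> value kind; columns with kind ``"numeric"`` are
        imputed with the observed mean, all others with the mode (ties
        broken by the smallest value).  When None, numeric dtype implies
        mean imputation.
    """

    def __init__(self, value_kinds: dict | None = None):
        self.value_kinds = value_kinds

    def _is_numeric(self, X: pd.DataFrame, col) -> bool:
        if self.value_kinds is not None and col in self.value_kinds:
            return self.value_kinds[col] == "numeric"
        return pd.api.types.is_numeric_dtype(X[col])

    def fit(self, X: pd.DataFrame, y=None):
        stats: dict = {}
        for col in X.columns:
            observed = X[col].dropna()
            if observed.empty:
                raise PreprocessError(f"feature {col!r} is entirely missing")
            if self._is_numeric(X, col):
                stats[col] = float(observed.mean())
            else:
                counts = observed.value_counts()
                top = counts[counts == counts.max()]
                stats[col] = sorted(top.index)[0]
        self.statistics_ = stats
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, value in self.statistics_.items():
            if col in out.columns:
                out[col] = out[col].fillna(value)
        return out


def impute_missing(data: CohortDataset) -> CohortDataset:
    """Fill every missing cell; observed cells are never altered.

    The target column must be complete.  A column with no observed values
    at all is an error (there is nothing to average).
    """
    if data.y.isna().any():
        raise PreprocessError("target column contains missing values")
    kinds = {f.code: f.value_kind for f in data.schema}
    imputer = MeanModeImputer(value_kinds=kinds)
    filled = imputer.fit(data.frame).transform(data.frame)
    return data.with_frame(filled, imputed=True)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationMap:
    """Per-feature ascending cut points defining half-open interval codes.

    A feature with boundaries ``[b1 < b2 < ... < b_{k-1}]`` maps values to
    codes ``0..k-1`` with code ``j`` covering ``[b_j, b_{j+1})`` and open
    outer intervals, so every finite value gets exactly one code.
    """

    method: str
    bins: int
    boundaries: dict = field(default_factory=dict)

    def n_bins(self, code: str) -> int:
        return len(self.boundaries[code]) + 1

    def apply_column(self, values: pd.Series, code: str) -> pd.Series:
        cuts = np.asarray(self.boundaries[code], dtype=float)
        coded = np.searchsorted(cuts, values.to_numpy(dtype=float), side="right")
        return pd.Series(coded, index=values.index, name=values.name)

    def to_yaml(self, path) -> None:
        doc = {"method": self.method, "bins": self.bins,
               "boundaries": {k: [float(b) for b in v]
                              for k, v in self.boundaries.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DiscretizationMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(method=doc["method"], bins=int(doc["bins"]),
                   boundaries={k: list(map(float, v))
                               for k, v in doc["boundaries"].items()})


def _class_entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mdl_cuts(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Recursive entropy-based cut points accepted by the MDL criterion."""
    order = np.argsort(x, kind="mergesort")
    return sorted(_mdl_split(x[order], y[order]))


def _mdl_split(x: np.ndarray, y: np.ndarray) -> list[float]:
    n = len(x)
    if n < 2:
        return []
    ent_s = _class_entropy(y)
    if ent_s == 0.0:
        return []
    # candidate cuts: midpoints between adjacent distinct values whose
    # boundary separates differing class labels somewhere in the tie groups
    best = None  # (weighted child entropy, cut index, cut value)
    for i in range(1, n):
        if x[i] == x[i - 1]:
            continue
        left, right = y[:i], y[i:]
        ent = (i / n) * _class_entropy(left) + ((n - i) / n) * _class_entropy(right)
        if best is None or ent < best[0] - 1e-12:
            best = (ent, i, (x[i] + x[i - 1]) / 2.0)
    if best is None:
        return []
    ent_children, i, cut = best
    gain = ent_s - ent_children
    k = len(np.unique(y))
    k1 = len(np.unique(y[:i]))
    k2 = len(np.unique(y[i:]))
    delta = (math.log2(3 ** k - 2)
             - (k * ent_s - k1 * _class_entropy(y[:i]) - k2 * _class_entropy(y[i:])))
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return []
    return (_mdl_split(x[:i], y[:i]) + [cut] + _mdl_split(x[i:], y[i:]))


class IntervalDiscretizer(BaseEstimator, TransformerMixin):
    """Bin numeric DataFrame columns into ordinal interval codes.

    Parameters
    ----------
    method : {"equal_frequency", "equal_width", "mdl_entropy"}
    bins : int
        Bin count for the unsupervised methods (>= 2); ``mdl_entropy``
        chooses its own number of cuts and ignores it.
    columns : list or None
        Columns to discretize; None means every numeric-dtype column.

    Attributes
    ----------
    map_ : DiscretizationMap
        Fitted cut points per column.
    """

    def __init__(self, method: str = "mdl_entropy", bins: int = 5,
                 columns: list | None = None):
        self.method = method
        self.bins = bins
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        if self.method not in METHODS:
            raise PreprocessError(f"unknown discretization method {self.method!r}")
        if self.method != "mdl_entropy" and self.bins < 2:
            raise PreprocessError("bins must be >= 2 for unsupervised methods")
        if self.method == "mdl_entropy" and y is None:
            raise PreprocessError("mdl_entropy requires the class column y")
        cols = self.columns
        if cols is None:
            cols = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
        boundaries: dict = {}
        for col in cols:
            v = X[col].to_numpy(dtype=float)
            if np.isnan(v).any():
                raise PreprocessError(f"feature {col!r} has missing values; impute first")
            boundaries[col] = self._fit_column(col, v, y)
        self.map_ = DiscretizationMap(method=self.method, bins=self.bins,
                                      boundaries=boundaries)
        return self

    def _fit_column(self, col, v: np.ndarray, y) -> list[float]:
        distinct = np.unique(v)
        if distinct.size == 1:
            return []  # constant feature: single bin
        if self.method == "mdl_entropy":
            return _mdl_cuts(v, np.asarray(y))
        bins = self.bins
        if bins > distinct.size:
            warnings.warn(
                f"feature {col!r}: bins={bins} exceeds {distinct.size} distinct "
                f"values; clamped", stacklevel=2)
            bins = distinct.size
        if self.method == "equal_width":
            lo, hi = float(v.min()), float(v.max())
            cuts = [lo + i * (hi - lo) / bins for i in range(1, bins)]
        else:  # equal_frequency
            qs = np.quantile(v, [i / bins for i in range(1, bins)])
            cuts = sorted(set(float(q) for q in qs))
        return cuts

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col in self.map_.boundaries:
            if col in out.columns:
                out[col] = self.map_.apply_column(out[col], col)
        return out


def fit_discretizer(data: CohortDataset, method: str = "mdl_entropy",
                    bins: int = 5) -> DiscretizationMap:
    """Fit interval cut points for every numeric candidate feature."""
    cols = [f.code for f in data.schema
            if f.role == "candidate" and f.value_kind == "numeric"]
    disc = IntervalDiscretizer(method=method, bins=bins, columns=cols)
    disc.fit(data.frame, y=data.y.to_numpy())
    return disc.map_

def apply_discretizer(data: CohortDataset, dmap: DiscretizationMap) -> CohortDataset:
    """Replace numeric candidate columns by their interval codes.

    Applying a map to an already-discretized dataset is the identity (the
    dataset carries a ``discretized`` flag), so the operation is idempotent.
    """
    if data.attrs.get("discretized"):
        return data
    frame = data.frame.copy()
    for f in data.schema:
        if f.role == "candidate" and f.value_kind == "numeric":
            if f.code not in dmap.boundaries:
                raise PreprocessError(f"numeric feature {f.code!r} missing from map")
            frame[f.code] = dmap.apply_column(frame[f.code], f.code)
    return data.with_frame(frame, discretized=True)
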