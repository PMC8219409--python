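"""Entropy-gain feature selection with a range threshold over three subsets.

The filter scores every candidate feature by its information gain on the
class label,

    Gain(S, A) = Entropy(S) - sum_v (|S_v| / |S|) * Entropy(S_v),

where ``S_v`` is the subset of records with ``A = v`` and
``Entropy(S) = -sum_m p_m log2 p_m`` over the class proportions ``p_m``.
The records are partitioned into three disjoint stratified subsets; within
each subset a range threshold

    r = (max gain - min gain) / n_candidates

discards every feature whose gain falls strictly below ``r`` (ties with the
threshold are kept).  The final feature set is the union of the three
per-subset survivors, so a feature needs to clear the bar in only one
subset.  Each subset is scored independently; gains are never pooled.

Scoring is linear in the number of candidate features per subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .cohort import CohortDataset


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Entropy and gain primitives
# ---------------------------------------------------------------------------

def compute_entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count map, with 0*log2(0) = 0."""
    counts = np.asarray(list(class_counts.values())
                        if hasattr(class_counts, "values") else class_counts,
                        dtype=float)
    if (counts < 0).any():
        raise SelectionError("negative class count")
    total = counts.sum()
    if total == 0:
        raise SelectionError("entropy of an empty instance set is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_of_labels(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return compute_entropy(counts)


def gain_of_arrays(x: np.ndarray, y: np.ndarray) -> float:
    """Information gain of feature values ``x`` about labels ``y``, in bits."""
    n = len(y)
    if n == 0:
        raise SelectionError("empty instance set")
    cx, _ = pd.factorize(x)
    cy, _ = pd.factorize(y)
    table = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(table, (cx, cy), 1.0)
    ent_s = compute_entropy(table.sum(axis=0))
    row_tot = table.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(table > 0, table / row_tot, 1.0)
        child = -(np.where(table > 0, table / row_tot, 1.0)
                  * np.log2(p)).sum(axis=1)
    cond = float((row_tot[:, 0] / n) @ child)
    return ent_s - cond


def compute_gain(data: CohortDataset, feature: str) -> float:
    """Gain of one candidate feature on the cohort's class column.

    The feature must be fully observed and discrete; a column with more
    distinct values than half the rows triggers a continuous-feature
    warning (its gain is inflated by fragmentation).
    """
    if feature not in data.candidate_codes:
        raise SelectionError(f"{feature!r} is not a candidate feature")
    col = data.frame[feature]
    if col.isna().any():
        raise SelectionError(f"feature {feature!r} has missing values")
    if col.nunique() > max(1, data.n_rows // 2):
        warnings.warn(
            f"feature {feature!r} looks continuous "
            f"({col.nunique()} distinct values in {data.n_rows} rows); "
            f"discretize before scoring", stacklevel=2)
    return gain_of_arrays(col.to_numpy(), data.y.to_numpy())


def compute_threshold(gains) -> float:
    """Range threshold r = (max - min) / n over the scored candidates."""
    if not gains:
        raise SelectionError("cannot compute a threshold from no gains")
    values = np.asarray(list(gains.values()), dtype=float)
    return float((values.max() - values.min()) / len(values))


# ---------------------------------------------------------------------------
# Reports and results
# ---------------------------------------------------------------------------

@dataclass
class GainReport:
    """Per-feature gains, dataset entropy and the range threshold of one subset."""

    subset_id: int
    dataset_entropy: float
    gains: dict
    threshold: float
    n_candidates: int

    def kept(self) -> list[str]:
        return [a for a, g in self.gains.items() if g >= self.threshold]

    def removed(self) -> list[str]:
        return [a for a, g in self.gains.items() if g < self.threshold]

    def to_dict(self) -> dict:
        return {
            "subset_id": self.subset_id,
            "dataset_entropy": self.dataset_entropy,
            "threshold": self.threshold,
            "n_candidates": self.n_candidates,
            "gains": {k: float(v) for k, v in self.gains.items()},
        }


@dataclass
class SelectionResult:
    """Initial set F0, per-subset survivors F1..F3 and their union F."""

    initial_features: list
    per_subset_features: list
    selected_features: list
    gain_reports: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "initial_features": list(self.initial_features),
            "per_subset_features": [list(f) for f in self.per_subset_features],
            "selected_features": list(self.selected_features),
            "gain_reports": [r.to_dict() for r in self.gain_reports],
        }


def select_subset(data_subset: CohortDataset, initial: list[str],
                  subset_id: int = 1) -> tuple[list[str], GainReport]:
    """Score one data subset and drop features with gain strictly below r.

    A one-class subset makes every gain zero, hence r = 0 and nothing is
    removed; a warning flags the degenerate case.
    """
    if data_subset.n_rows == 0:
        raise SelectionError("empty data subset")
    y = data_subset.y.to_numpy()
    if len(np.unique(y)) < 2:
        warnings.warn(f"subset {subset_id}: single class present; "
                      f"all gains are 0 and every feature is kept", stacklevel=2)
    gains = {a: compute_gain(data_subset, a) for a in initial}
    r = compute_threshold(gains)
    report = GainReport(
        subset_id=subset_id,
        dataset_entropy=_entropy_of_labels(y),
        gains=gains,
        threshold=r,
        n_candidates=len(gains),
    )
    kept = [a for a in initial if gains[a] >= r]
    return kept, report


class EntropyGainSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn selector applying the three-subset range-threshold filter.

    Parameters
    ----------
    n_subsets : int, default 3
        Number of disjoint stratified row partitions scored independently.
    random_state : int or None
        Seed for the stratified partition of rows.

    Attributes
    ----------
    selected_features_ : list of str
        Union of the per-subset surviving features, in input column order.
    subset_features_ : list of list of str
        Survivors of each subset.
    gain_reports_ : list of GainReport
    support_ : bool ndarray of shape (n_features,)
    """

    def __init__(self, n_subsets: int = 3, random_state: int | None = None):
        self.n_subsets = n_subsets
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) < self.n_subsets:
            raise SelectionError(
                f"need at least {self.n_subsets} rows, got {len(X)}")
        if X.shape[1] == 0:
            raise SelectionError("no candidate features")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        initial = list(X.columns)

        splitter = StratifiedKFold(n_splits=self.n_subsets, shuffle=True,
                                   random_state=self.random_state)
        self.subset_features_ = []
        self.gain_reports_ = []
        selected: set = set()
        for k, (_, idx) in enumerate(splitter.split(X, y), start=1):
            sub_y = y[idx]
            if (sub_y == 1).sum() == 0:
                warnings.warn(f"subset {k} received zero minority rows",
                              stacklevel=2)
            gains = {a: gain_of_arrays(X[a].to_numpy()[idx], sub_y)
                     for a in initial}
            r = compute_threshold(gains)
            kept = [a for a in initial if gains[a] >= r]
            self.subset_features_.append(kept)
            self.gain_reports_.append(GainReport(
                subset_id=k,
                dataset_entropy=_entropy_of_labels(sub_y),
                gains=gains,
                threshold=r,
                n_candidates=len(gains),
            ))
            selected.update(kept)
        self.selected_features_ = [a for a in initial if a in selected]
        self.support_ = np.asarray([a in selected for a in initial])
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            initial_features=list(self.feature_names_in_),
            per_subset_features=[list(f) for f in self.subset_features_],
            selected_features=list(self.selected_features_),
            gain_reports=list(self.gain_reports_),
        )


def select_features(data: CohortDataset, n_subsets: int = 3,
                    seed: int | None = 0) -> SelectionResult:
    """Run the full filter on a discretized, imputed cohort.

    Rows are split into ``n_subsets`` disjoint, exhaustive, stratified
    subsets of equal size (+-1) using ``seed``; identifier and target
    columns never enter the candidate set.
    """
    candidates = data.candidate_codes
    frame = data.frame[candidates]
    if frame.isna().any().any():
        raise SelectionError("cohort has missing values; impute first")
    sel = EntropyGainSelector(n_subsets=n_subsets, random_state=seed)
    sel.fit(frame, data.y.to_numpy())
    return sel.result()
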