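"""Minority-class balancing by synthetic oversampling (SMOTE) or duplication.

The minority class (preterm, label 1) is grown until it reaches a target
share of the dataset, by default ~50%.  Synthetic rows are built by picking
a minority record, one of its k nearest minority neighbors (Euclidean
distance on the ordinal feature codes), and a uniform interpolation point
on the segment between them; interpolated coordinates are rounded half-up
back to valid ordinal codes.  A ``duplicate`` mode replicates existing
minority rows verbatim instead.  Majority rows are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .cohort import CohortDataset


class BalanceError(ValueError):
    pass


@dataclass
class BalanceConfig:
    """Balancing knobs: target minority share, neighbor count, seed."""

    target_minority_fraction: float = 0.5
    k_neighbors: int = 5
    seed: int | None = 0
    duplicate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.target_minority_fraction <= 0.5:
            raise BalanceError("target_minority_fraction must be in (0, 0.5]")
        if self.k_neighbors < 1:
            raise BalanceError("k_neighbors must be >= 1")


def _n_synthetic(n_total: int, n_minority: int, target: float) -> int:
    """Synthetic rows s so that (m + s) / (n + s) is closest to target."""
    if n_minority / n_total >= target:
        return 0
    s = (target * n_total - n_minority) / (1.0 - target)
    return int(round(s))


class SmoteOversampler(BaseEstimator):
    """k-NN interpolation oversampler for ordinal-coded feature matrices.

    ``fit_resample(X, y)`` returns ``(X_out, y_out)`` where the original
    rows are retained unchanged (in their input order) and synthetic
    minority rows are appended.  The minority class is the less frequent
    label in ``y``.
    """

    def __init__(self, target_minority_fraction: float = 0.5,
                 k_neighbors: int = 5, random_state: int | None = 0,
                 duplicate: bool = False, round_codes: bool = True):
        self.target_minority_fraction = target_minority_fraction
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.duplicate = duplicate
        self.round_codes = round_codes

    def fit_resample(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) != 2:
            raise BalanceError(f"need a binary target, got classes {labels}")
        minority = labels[np.argmin(counts)]
        m = counts.min()
        if m < 2:
            raise BalanceError("minority class needs at least 2 rows")
        n_syn = _n_synthetic(len(y), m, self.target_minority_fraction)
        self.n_synthetic_ = n_syn
        self.minority_label_ = minority
        if n_syn == 0:
            return X.copy(), y.copy()

        rng = np.random.default_rng(self.random_state)
        Xm = X[y == minority]
        if self.duplicate:
            picks = rng.integers(0, m, size=n_syn)
            synth = Xm[picks]
        else:
            k = self.k_neighbors
            if k > m - 1:
                warnings.warn(f"k_neighbors={k} exceeds minority size - 1; "
                              f"clamped to {m - 1}", stacklevel=2)
                k = m - 1
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
            _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself
            base = rng.integers(0, m, size=n_syn)
            pick = rng.integers(0, k, size=n_syn)
            partner = neigh[base, 1 + pick]
            gap = rng.uniform(0.0, 1.0, size=n_syn)[:, None]
            synth = Xm[base] + gap * (Xm[partner] - Xm[base])
            if self.round_codes:
                synth = np.floor(synth + 0.5)  # half-up to valid ordinal codes
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_syn, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_balance(data: CohortDataset, config: BalanceConfig | None = None) -> CohortDataset:
    """Balance a cohort's minority class to the configured share.

    Candidate features must be numeric/ordinal coded (run preprocessing
    first).  Identifier columns of synthetic rows get fresh labels
    ``SYN0, SYN1, ...``; a cohort already at or above the target share is
    returned unchanged.
    """
    config = config or BalanceConfig()
    candidates = data.candidate_codes
    frame = data.frame
    non_numeric = [c for c in candidates
                   if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise BalanceError(
            f"candidate features must be ordinal-coded before balancing; "
            f"non-numeric: {non_numeric}")
    sampler = SmoteOversampler(
        target_minority_fraction=config.target_minority_fraction,
        k_neighbors=config.k_neighbors,
        random_state=config.seed,
        duplicate=config.duplicate,
    )
    X, y = sampler.fit_resample(frame[candidates].to_numpy(dtype=float),
                                data.y.to_numpy())
    n_syn = sampler.n_synthetic_
    if n_syn == 0:
        return data
    new = pd.DataFrame(X[-n_syn:], columns=candidates)
    new[data.class_column] = y[-n_syn:]
    for f in data.schema:
        if f.role == "identifier":
            new[f.code] = [f"SYN{i}" for i in range(n_syn)]
    out = pd.concat([frame, new], ignore_index=True)
    return data.with_frame(out, balanced=True)
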