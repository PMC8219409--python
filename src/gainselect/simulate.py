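"""Synthetic obstetric-cohort generator with known ground truth.

The generator emulates the shape of a rural antenatal-care cohort — 1300
pregnancy records, 36 columns, roughly 24% preterm prevalence — with a
configurable set of *informative* features whose discrete value
distributions differ between the preterm and term classes, and *noise*
features drawn identically for both classes.  Because the planted
informative set is returned alongside the data, feature-selection recovery
is directly testable.  Features are produced in discrete/binned form
(matching the coded clinical variables the pipeline consumes); an optional
raw mode adds Gaussian jitter to numeric features so the discretizer has
real work to do.  No clinical realism is claimed for the default
distributions: they are fixtures with known information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset, default_schema


class SimulationError(ValueError):
    pass


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def expected_gain(dist_term: dict, dist_preterm: dict, prevalence: float) -> float:
    """Population information gain of a planted feature, in bits.

    Computed from the closed-form mixture: with class prior ``pi`` (the
    preterm prevalence) and per-class value distributions ``p0``, ``p1``,

        Gain = H(pi) - sum_v p(v) * H( pi * p1(v) / p(v) ),

    where ``p(v) = (1 - pi) p0(v) + pi p1(v)`` and H is the binary entropy.
    Sample gains on generated cohorts converge to this value.
    """
    values = sorted(set(dist_term) | set(dist_preterm))
    pi = prevalence
    h_class = _binary_entropy(pi)
    cond = 0.0
    for v in values:
        p0 = dist_term.get(v, 0.0)
        p1 = dist_preterm.get(v, 0.0)
        pv = (1 - pi) * p0 + pi * p1
        if pv == 0:
            continue
        cond += pv * _binary_entropy(pi * p1 / pv)
    return h_class - cond


@dataclass
class GeneratorConfig:
    """Cohort-generator settings.

    ``informative`` maps feature code -> (term distribution, preterm
    distribution); ``noise`` maps feature code -> one class-independent
    distribution.  Distributions are value -> probability dicts over the
    feature's discrete codes and must each sum to 1.
    """

    n_rows: int = 1300
    prevalence: float = 0.238
    informative: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    raw_mode: bool = False
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 0.5:
            raise SimulationError("prevalence must be in [0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        for code, (d0, d1) in self.informative.items():
            for d in (d0, d1):
                if abs(sum(d.values()) - 1.0) > 1e-9:
                    raise SimulationError(
                        f"distribution of {code!r} does not sum to 1")
        for code, d in self.noise.items():
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise SimulationError(f"distribution of {code!r} does not sum to 1")


# Default planted informative features: per-class distributions over coded
# levels, each carrying >= 0.1 bits of population gain at 23.8% prevalence
# (gestational-age bin, blood-pressure grade, hemoglobin bin, preeclampsia,
# hypertension, previous caesarean section).  Labels only; not estimates of
# real clinical distributions.
DEFAULT_INFORMATIVE = {
    "GA": ({0: 0.05, 1: 0.10, 2: 0.35, 3: 0.50},
           {0: 0.45, 1: 0.35, 2: 0.15, 3: 0.05}),
    "BP": ({0: 0.70, 1: 0.25, 2: 0.05},
           {0: 0.25, 1: 0.35, 2: 0.40}),
    "HB": ({0: 0.15, 1: 0.35, 2: 0.50},
           {0: 0.55, 1: 0.30, 2: 0.15}),
    "PE": ({0: 0.95, 1: 0.05}, {0: 0.45, 1: 0.55}),
    "HT": ({0: 0.90, 1: 0.10}, {0: 0.40, 1: 0.60}),
    "PCS": ({0: 0.85, 1: 0.15}, {0: 0.40, 1: 0.60}),
}


def _uniform(levels: int) -> dict:
    return {v: 1.0 / levels for v in range(levels)}


def _default_noise() -> dict:
    """Class-independent distributions for the 28 non-planted candidates."""
    schema = default_schema()
    noise = {}
    for f in schema:
        if f.role != "candidate" or f.code in DEFAULT_INFORMATIVE:
            continue
        if f.value_kind == "binary":
            noise[f.code] = {0: 0.7, 1: 0.3}
        elif f.value_kind == "ordinal":
            noise[f.code] = {0: 0.5, 1: 0.3, 2: 0.2}
        elif f.value_kind == "categorical":
            noise[f.code] = _uniform(4)  # coded quarters for date-like fields
        else:  # numeric, generated pre-binned
            noise[f.code] = _uniform(4)
    return noise


def default_config(n_rows: int = 1300, prevalence: float = 0.238,
                   missing_rate: float = 0.0, raw_mode: bool = False,
                   seed: int | None = 0) -> GeneratorConfig:
    return GeneratorConfig(
        n_rows=n_rows, prevalence=prevalence,
        informative={k: (dict(d0), dict(d1))
                     for k, (d0, d1) in DEFAULT_INFORMATIVE.items()},
        noise=_default_noise(), missing_rate=missing_rate,
        raw_mode=raw_mode, seed=seed)


def _draw(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    values = np.asarray(sorted(dist), dtype=float)
    probs = np.asarray([dist[v] for v in sorted(dist)], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(values, size=size, p=probs)


def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[CohortDataset, set]:
    """Draw a cohort per the configured class-conditional distributions.

    Returns the dataset together with the planted informative feature set
    (the ground truth for recovery tests).  Minority rows number
    ``round(prevalence * n_rows)``; missing cells are injected uniformly
    at ``missing_rate`` over candidate cells.
    """
    config = config or default_config()
    if not config.informative and not config.noise:
        raise SimulationError("no features configured")
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    n_pre = int(round(config.prevalence * n))
    y = np.zeros(n, dtype=int)
    y[:n_pre] = 1

    schema = default_schema()
    known = set(config.informative) | set(config.noise)
    schema = [f for f in schema
              if f.role != "candidate" or f.code in known]
    columns: dict = {}
    for f in schema:
        if f.role == "identifier":
            continue
        if f.role == "target":
            columns[f.code] = y
        elif f.code in config.informative:
            d0, d1 = config.informative[f.code]
            col = np.empty(n)
            col[y == 1] = _draw(rng, d1, int((y == 1).sum()))
            col[y == 0] = _draw(rng, d0, int((y == 0).sum()))
            columns[f.code] = col
        else:
            columns[f.code] = _draw(rng, config.noise[f.code], n)

    frame = pd.DataFrame(columns)
    # shuffle rows so class labels are not block-ordered
    order = rng.permutation(n)
    frame = frame.iloc[order].reset_index(drop=True)

    if config.raw_mode:
        for f in schema:
            if f.role == "candidate" and f.value_kind == "numeric":
                frame[f.code] = frame[f.code] + rng.normal(0.0, 0.25, size=n)

    if config.missing_rate > 0:
        for f in schema:
            if f.role != "candidate":
                continue
            mask = rng.random(n) < config.missing_rate
            frame.loc[mask, f.code] = np.nan

    if any(f.role == "identifier" for f in schema):
        id_code = next(f.code for f in schema if f.role == "identifier")
        frame[id_code] = [f"P{i:06d}" for i in range(n)]
        frame = frame[[f.code for f in schema]]

    data = CohortDataset(frame=frame, schema=schema,
                         attrs={} if config.raw_mode else {"discretized": True})
    return data, set(config.informative)
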