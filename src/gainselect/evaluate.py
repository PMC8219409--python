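"""Train/test split, the three reference classifiers, and confusion-matrix
metrics, plus the end-to-end risk-prediction pipeline.

The pipeline runs: mean/mode imputation -> discretization -> entropy-gain
feature selection -> stratified 70/30 split -> minority balancing (either
on the full dataset before the split, or train-only after it) -> decision
tree, logistic regression and RBF support-vector classifiers -> per-model
confusion-matrix reports.  The positive class is preterm birth (label 1)
throughout, and accuracy (CCR) is reported on the percent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import BalanceConfig, smote_balance
from .cohort import CohortDataset, FeatureSpec, read_cohort_csv, summarize
from .preprocess import apply_discretizer, fit_discretizer, impute_missing
from .selection import SelectionResult, select_features

CLASSIFIER_KINDS = ("DT", "LR", "SVM")


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise EvaluationError("train_fraction must be in (0, 1)")


def split_dataset(data: CohortDataset, spec: SplitSpec | None = None
                  ) -> tuple[CohortDataset, CohortDataset]:
    """Disjoint, exhaustive train/test split; train size = round(f * n).

    Stratification keeps the class ratio within one row per class and
    requires both classes present.
    """
    spec = spec or SplitSpec()
    y = data.y.to_numpy()
    if spec.stratified and len(np.unique(y)) < 2:
        raise EvaluationError("stratified split requires both classes present")
    n_train = int(round(spec.train_fraction * data.n_rows))
    idx = np.arange(data.n_rows)
    train_idx, test_idx = train_test_split(
        idx, train_size=n_train, random_state=spec.seed,
        stratify=y if spec.stratified else None, shuffle=True)
    train = data.with_frame(data.frame.iloc[np.sort(train_idx)].reset_index(drop=True))
    test = data.with_frame(data.frame.iloc[np.sort(test_idx)].reset_index(drop=True))
    return train, test


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted classifier plus the feature columns it was trained on."""

    kind: str
    estimator: object
    features: list

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in frame.columns]
        if missing:
            raise EvaluationError(f"test data lacks model features: {missing}")
        return np.asarray(self.estimator.predict(frame[self.features]))


def make_classifier(kind: str, seed: int | None = 0, **hyperparams):
    """Instantiate one of the three reference classifiers.

    DT: CART decision tree with impurity splitting.  LR: binary logistic
    regression fit by penalized likelihood maximization.  SVM: support
    vector classifier with an RBF kernel.
    """
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed, **hyperparams)
    if kind == "LR":
        hyperparams.setdefault("max_iter", 1000)
        return LogisticRegression(**hyperparams)
    if kind == "SVM":
        hyperparams.setdefault("kernel", "rbf")
        return SVC(random_state=seed, **hyperparams)
    raise EvaluationError(f"unknown classifier kind {kind!r}; "
                          f"expected one of {CLASSIFIER_KINDS}")


def train_classifier(kind: str, train: CohortDataset,
                     hyperparams: dict | None = None,
                     features: list | None = None,
                     seed: int | None = 0) -> FittedModel:
    """Fit one classifier on a cohort's candidate features."""
    if train.n_rows == 0:
        raise EvaluationError("empty training set")
    if train.y.nunique() < 2:
        raise EvaluationError("training data contains a single class")
    feats = list(features) if features is not None else train.candidate_codes
    est = make_classifier(kind, seed=seed, **(hyperparams or {}))
    est.fit(train.frame[feats], train.y.to_numpy())
    return FittedModel(kind=kind, estimator=est, features=feats)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        return cls(tp=int(((t == 1) & (p == 1)).sum()),
                   fn=int(((t == 1) & (p == 0)).sum()),
                   fp=int(((t == 0) & (p == 1)).sum()),
                   tn=int(((t == 0) & (p == 0)).sum()))


def _ratio(num: float, den: float):
    return num / den if den else float("nan")


@dataclass
class EvaluationReport:
    """Confusion-matrix counts and the derived performance metrics.

    CCR (accuracy) is on the percent scale; all other metrics are
    proportions in [0, 1].  A metric with a zero denominator is NaN and
    its name is listed in ``undefined_metrics`` rather than coerced to 0.
    """

    classifier_kind: str
    matrix: ConfusionMatrix
    ccr: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    precision: float
    recall: float
    f1: float
    undefined_metrics: list = field(default_factory=list)

    @classmethod
    def from_matrix(cls, kind: str, m: ConfusionMatrix) -> "EvaluationReport":
        if m.total == 0:
            raise EvaluationError("cannot evaluate on an empty test set")
        metrics = {
            "ccr": 100.0 * (m.tp + m.tn) / m.total,
            "tpr": _ratio(m.tp, m.tp + m.fn),
            "tnr": _ratio(m.tn, m.tn + m.fp),
            "fpr": _ratio(m.fp, m.tn + m.fp),
            "fnr": _ratio(m.fn, m.tp + m.fn),
            "precision": _ratio(m.tp, m.tp + m.fp),
            "recall": _ratio(m.tp, m.tp + m.fn),
            "f1": _ratio(2 * m.tp, 2 * m.tp + m.fp + m.fn),
        }
        undefined = sorted(k for k, v in metrics.items() if math.isnan(v))
        return cls(classifier_kind=kind, matrix=m,
                   undefined_metrics=undefined, **metrics)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matrix"] = asdict(self.matrix)
        return d


def evaluate(model: FittedModel, test: CohortDataset) -> EvaluationReport:
    """Score a fitted model on a held-out cohort (positive class = 1)."""
    if test.n_rows == 0:
        raise EvaluationError("cannot evaluate on an empty test set")
    pred = model.predict(test.frame)
    m = ConfusionMatrix.from_predictions(test.y.to_numpy(), pred)
    return EvaluationReport.from_matrix(model.kind, m)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with reproducible defaults."""

    seed: int = 0
    train_fraction: float = 0.70
    stratified: bool = True
    select: bool = True
    select_on_train: bool = False
    balance_mode: str = "train-only"  # {"train-only", "full", "none"}
    target_minority_fraction: float = 0.5
    k_neighbors: int = 5
    duplicate: bool = False
    discretizer_method: str = "mdl_entropy"
    bins: int = 5
    classifiers: tuple = CLASSIFIER_KINDS
    hyperparams: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifiers"] = list(self.classifiers)
        return d


@dataclass
class PipelineResult:
    selection: SelectionResult | None
    reports: dict
    manifest: dict


def stage_seed(root: int | None, label: str) -> int:
    """Derive a per-stage seed (< 2^31) from the single root seed."""
    labels = {"partition": 1, "split": 2, "balance": 3, "model": 4,
              "simulate": 5}
    root = 0 if root is None else int(root)
    ss = np.random.SeedSequence([root, labels[label]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(data, config: PipelineConfig | None = None,
                 schema: list[FeatureSpec] | None = None) -> PipelineResult:
    """Execute the full risk-prediction workflow on a cohort.

    ``data`` is a CSV path or a CohortDataset.  Every stage's row/feature
    counts and derived seeds are recorded in the returned manifest, along
    with the constant majority-class baseline accuracy on the test set.
    """
    cfg = config or PipelineConfig()
    if not isinstance(data, CohortDataset):
        data = read_cohort_csv(data, schema=schema)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    def log(stage: str, d: CohortDataset, **extra) -> None:
        manifest["stages"][stage] = {
            "n_rows": d.n_rows,
            "n_candidates": len(d.candidate_codes),
            "minority_fraction": summarize(d).minority_fraction,
            **extra,
        }

    log("input", data)
    data = impute_missing(data)
    dmap = fit_discretizer(data, method=cfg.discretizer_method, bins=cfg.bins)
    data = apply_discretizer(data, dmap)
    log("preprocess", data, discretizer=cfg.discretizer_method)

    split_spec = SplitSpec(train_fraction=cfg.train_fraction,
                           stratified=cfg.stratified,
                           seed=stage_seed(cfg.seed, "split"))

    selection = None
    if cfg.select:
        sel_data = data
        if cfg.select_on_train:
            sel_data, _ = split_dataset(data, split_spec)
        selection = select_features(sel_data,
                                    seed=stage_seed(cfg.seed, "partition"))
        features = selection.selected_features
        manifest["stages"]["select"] = {
            "n_selected": len(features),
            "selected_features": list(features),
            "on_train_only": cfg.select_on_train,
        }
    else:
        features = data.candidate_codes

    # drop unselected candidates and identifiers for modeling
    keep = [f for f in data.schema
            if f.code in features or f.role == "target"]
    data = CohortDataset(frame=data.frame[[f.code for f in keep]].copy(),
                         schema=keep, attrs=dict(data.attrs))

    balance_cfg = BalanceConfig(
        target_minority_fraction=cfg.target_minority_fraction,
        k_neighbors=cfg.k_neighbors,
        seed=stage_seed(cfg.seed, "balance"),
        duplicate=cfg.duplicate)

    if cfg.balance_mode == "full":
        data = smote_balance(data, balance_cfg)
        log("balance", data, mode="full")
        train, test = split_dataset(data, split_spec)
    elif cfg.balance_mode == "train-only":
        train, test = split_dataset(data, split_spec)
        train = smote_balance(train, balance_cfg)
        log("balance", train, mode="train-only")
    elif cfg.balance_mode == "none":
        train, test = split_dataset(data, split_spec)
    else:
        raise EvaluationError(f"unknown balance_mode {cfg.balance_mode!r}")
    log("train", train)
    log("test", test)

    majority = test.y.value_counts().max() / test.n_rows
    manifest["majority_baseline_accuracy_pct"] = 100.0 * majority

    reports = {}
    model_seed = stage_seed(cfg.seed, "model")
    for kind in cfg.classifiers:
        model = train_classifier(kind, train,
                                 hyperparams=cfg.hyperparams.get(kind),
                                 seed=model_seed)
        reports[kind] = evaluate(model, test)
        manifest["stages"][f"model_{kind}"] = {
            "params": {k: v for k, v in model.estimator.get_params().items()
                       if not callable(v)},
        }
    manifest["seeds"] = {lbl: stage_seed(cfg.seed, lbl)
                         for lbl in ("partition", "split", "balance", "model")}
    return PipelineResult(selection=selection, reports=reports,
                          manifest=manifest)


def reports_markdown(reports: dict) -> str:
    """Render per-classifier Accuracy/Sensitivity/Specificity as Markdown."""
    lines = ["| Classifier | Accuracy | Sensitivity | Specificity |",
             "|---|---|---|---|"]
    for kind, r in reports.items():
        lines.append(f"| {kind} | {r.ccr / 100:.3f} | {r.tpr:.3f} | {r.tnr:.3f} |")
    return "\n".join(lines)
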