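"""Cohort schema and dataset container with CSV read/write and validation.

A cohort is a rectangular table of pregnancy records: one row per pregnancy,
one column per maternal feature, plus a binary outcome column (1 = preterm
birth, 0 = term birth).  The schema attaches a value kind (numeric, ordinal,
binary, categorical) and a role (candidate, identifier, target) to every
column; identifier columns are never used for selection or model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VALUE_KINDS = ("numeric", "ordinal", "binary", "categorical")
ROLES = ("candidate", "identifier", "target")

#: Missing-value spellings accepted on CSV read; empty cell is written.
NA_VALUES = ("", "NA")


class SchemaError(ValueError):
    """The schema itself, or data/schema agreement, is invalid."""


class ValidationError(ValueError):
    """Cell values violate the cohort contract (e.g. non-binary target)."""


@dataclass(frozen=True)
class FeatureSpec:
    """One column of the cohort schema.

    Parameters
    ----------
    code : str
        Short unique identifier, used as the CSV header (e.g. ``"WA"``).
    name : str
        Human-readable label (e.g. ``"Woman age"``).
    value_kind : {"numeric", "ordinal", "binary", "categorical"}
        How cell values are interpreted by preprocessing and selection.
    role : {"candidate", "identifier", "target"}
        Candidates feed feature selection and model fitting; identifiers
        are carried through but never scored; exactly one target exists.
    """

    code: str
    name: str
    value_kind: str
    role: str = "candidate"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(
                f"feature {self.code!r}: unknown value_kind {self.value_kind!r}"
            )
        if self.role not in ROLES:
            raise SchemaError(f"feature {self.code!r}: unknown role {self.role!r}")


def _check_schema(schema: list[FeatureSpec]) -> None:
    codes = [f.code for f in schema]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise SchemaError(f"duplicate feature codes in schema: {dupes}")
    targets = [f for f in schema if f.role == "target"]
    if len(targets) != 1:
        raise SchemaError(f"schema must contain exactly one target, found {len(targets)}")


@dataclass
class CohortDataset:
    """A validated cohort: records plus schema plus the target column code.

    ``frame`` holds one column per schema entry, in schema order.  Missing
    cells are ``NaN``.  ``attrs`` carries processing flags (for instance
    whether numeric columns have been discretized to bin codes).
    """

    frame: pd.DataFrame
    schema: list[FeatureSpec]
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_schema(self.schema)
        schema_codes = [f.code for f in self.schema]
        missing = [c for c in schema_codes if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"schema columns absent from data: {missing}")
        extra = [c for c in self.frame.columns if c not in schema_codes]
        if extra:
            raise SchemaError(f"data columns absent from schema: {extra}")
        self.frame = self.frame[schema_codes].copy()
        self._validate_target()

    def _validate_target(self) -> None:
        y = self.frame[self.class_column]
        bad = ~y.isin([0, 1, 0.0, 1.0])
        if bad.any():
            rows = list(self.frame.index[bad][:10])
            raise ValidationError(
                f"target column {self.class_column!r} must be 0/1; "
                f"offending rows (up to 10): {rows}"
            )
        self.frame[self.class_column] = y.astype(int)

    # -- convenience accessors -------------------------------------------------
    @property
    def class_column(self) -> str:
        return next(f.code for f in self.schema if f.role == "target")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def candidate_codes(self) -> list[str]:
        return [f.code for f in self.schema if f.role == "candidate"]

    @property
    def y(self) -> pd.Series:
        return self.frame[self.class_column]

    def spec(self, code: str) -> FeatureSpec:
        for f in self.schema:
            if f.code == code:
                return f
        raise KeyError(code)

    def with_frame(self, frame: pd.DataFrame, **attrs) -> "CohortDataset":
        """New dataset sharing this schema, with updated records/flags."""
        return CohortDataset(frame=frame, schema=list(self.schema),
                             attrs={**self.attrs, **attrs})

    def equals(self, other: "CohortDataset") -> bool:
        if [f for f in self.schema] != [f for f in other.schema]:
            return False
        if self.frame.shape != other.frame.shape:
            return False
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        for col in a.columns:
            va, vb = a[col], b[col]
            both_na = va.isna() & vb.isna()
            if not ((va == vb) | both_na).all():
                return False
        return True


@dataclass(frozen=True)
class DatasetSummary:
    n_features: int
    n_classes: int
    n_rows: int
    class_counts: dict
    minority_fraction: float


def summarize(data: CohortDataset) -> DatasetSummary:
    """Class counts and minority share of a cohort.

    The minority fraction is ``min(class count) / n_rows``; a class absent
    from the data counts as zero, so a one-class cohort reports 0.
    """
    counts = data.y.value_counts().to_dict()
    for label in (0, 1):
        counts.setdefault(label, 0)
    n = data.n_rows
    return DatasetSummary(
        n_features=len(data.schema),
        n_classes=2,
        n_rows=n,
        class_counts={int(k): int(v) for k, v in sorted(counts.items())},
        minority_fraction=min(counts.values()) / n if n else float("nan"),
    )


# ---------------------------------------------------------------------------
# Default schema: the 36 maternal features recorded per pregnancy.
# ---------------------------------------------------------------------------

_DEFAULT_FIELDS = [
    ("PID", "Patient identification", "categorical", "identifier"),
    ("WA", "Woman age", "numeric", "candidate"),
    ("LMP", "Last menstrual period", "categorical", "candidate"),
    ("EDD", "Estimated delivery date", "categorical", "candidate"),
    ("G", "Gravida", "numeric", "candidate"),
    ("P", "Parity", "numeric", "candidate"),
    ("A", "Abortion", "numeric", "candidate"),
    ("L", "Living", "numeric", "candidate"),
    ("EL", "Educational level", "ordinal", "candidate"),
    ("H", "Height", "numeric", "candidate"),
    ("W", "Weight", "numeric", "candidate"),
    ("BMI", "Body mass index", "ordinal", "candidate"),
    ("BP", "Blood pressure", "ordinal", "candidate"),
    ("HB", "Hemoglobin", "numeric", "candidate"),
    ("ANC", "Antenatal care visit", "numeric", "candidate"),
    ("ADD", "Actual delivery date", "categorical", "candidate"),
    ("OH", "Obstetric history", "binary", "candidate"),
    ("PCS", "Previous caesarean section", "binary", "candidate"),
    ("GA", "Gestational age", "numeric", "candidate"),
    ("BW", "Birth weight", "numeric", "candidate"),
    ("GDM", "Gestational diabetes mellitus", "binary", "candidate"),
    ("FHR", "Fetal heart rate", "numeric", "candidate"),
    ("MG", "Multiple gestation", "binary", "candidate"),
    ("ND", "Normal delivery", "binary", "candidate"),
    ("MH", "Previous medical history", "binary", "candidate"),
    ("LBW", "Low birth weight", "binary", "candidate"),
    ("ASPX", "Asphyxia", "binary", "candidate"),
    ("HT", "Hypertension", "binary", "candidate"),
    ("PE", "Preeclampsia", "binary", "candidate"),
    ("LV", "Live birth", "binary", "candidate"),
    ("SB", "Still birth", "binary", "candidate"),
    ("OB", "Obesity", "binary", "candidate"),
    ("AN", "Anemia", "binary", "candidate"),
    ("TH", "Thyroid", "binary", "candidate"),
    ("NS", "Neonatal status", "binary", "candidate"),
    ("PTB", "Preterm birth", "binary", "target"),
]


def default_schema() -> list[FeatureSpec]:
    """The bundled 36-column obstetric schema (PID identifier, PTB target)."""
    return [FeatureSpec(*row) for row in _DEFAULT_FIELDS]


# ---------------------------------------------------------------------------
# CSV and YAML I/O
# ---------------------------------------------------------------------------

def read_cohort_csv(path, schema: list[FeatureSpec] | None = None,
                    strict: bool = True) -> CohortDataset:
    """Read a cohort CSV (header row of feature codes) into a dataset.

    If ``schema`` is omitted, one is inferred: columns named ``PTB`` become
    the target, ``PID`` an identifier, and everything else a numeric or
    categorical candidate by dtype.  Unknown columns (present in the file
    but not in a supplied schema) raise under ``strict`` and are dropped
    with a warning otherwise.  Missing cells (empty or ``NA``) are kept as
    ``NaN``, never dropped.
    """
    try:
        frame = pd.read_csv(path, na_values=list(NA_VALUES),
                            keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc

    if schema is None:
        schema = _infer_schema(frame)
    else:
        _check_schema(schema)
        known = {f.code for f in schema}
        unknown = [c for c in frame.columns if c not in known]
        if unknown:
            if strict:
                raise SchemaError(f"unknown columns in {path}: {unknown}")
            warnings.warn(f"dropping unknown columns: {unknown}", stacklevel=2)
            frame = frame.drop(columns=unknown)
        schema = [f for f in schema if f.code in frame.columns]
        _require_target(schema, path)

    target = next((f.code for f in schema if f.role == "target"), None)
    if target is None or target not in frame.columns:
        raise SchemaError(f"target column absent from {path}")
    return CohortDataset(frame=frame, schema=schema)


def _require_target(schema, path) -> None:
    if not any(f.role == "target" for f in schema):
        raise SchemaError(f"target column absent from {path}")


def _infer_schema(frame: pd.DataFrame) -> list[FeatureSpec]:
    if "PTB" not in frame.columns:
        raise SchemaError("target column 'PTB' absent and no schema given")
    specs = []
    for col in frame.columns:
        if col == "PTB":
            specs.append(FeatureSpec(col, col, "binary", "target"))
        elif col == "PID":
            specs.append(FeatureSpec(col, col, "categorical", "identifier"))
        else:
            kind = "numeric" if pd.api.types.is_numeric_dtype(frame[col]) else "categorical"
            specs.append(FeatureSpec(col, col, kind, "candidate"))
    return specs


def write_cohort_csv(data: CohortDataset, path) -> None:
    """Write a cohort as CSV; missing cells become empty fields.

    ``read_cohort_csv`` on the result yields an equal dataset, and a second
    write of that round-tripped dataset is byte-identical.
    """
    data.frame.to_csv(path, index=False, na_rep="")


def save_schema_yaml(schema: list[FeatureSpec], path) -> None:
    rows = [{"code": f.code, "name": f.name, "value_kind": f.value_kind,
             "role": f.role} for f in schema]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def load_schema_yaml(path) -> list[FeatureSpec]:
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    schema = [FeatureSpec(**row) for row in rows]
    _check_schema(schema)
    return schema
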