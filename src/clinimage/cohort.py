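"""Cohort container, file IO, proximity imputation and stratified hold-out.

A cohort is an ``n x 28`` encoded real matrix with a binary invasive-disease-
event (IDE) label per patient and a missingness mask. Missing cells are imputed
by copying values from the fully observed reference patient at minimum
Euclidean distance over the observed features (after min-max scaling on the
reference cohort). Hold-out splitting is stratified with per-class
round-half-up counts so printed cohort splits are reproduced exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import LABEL_COLUMN, FeatureSchema, SchemaError, default_schema

__all__ = [
    "ClinicalCohort",
    "SplitIndices",
    "read_cohort",
    "write_cohort",
    "impute_missing",
    "stratified_holdout",
    "ImputationError",
    "SplitError",
]


class ImputationError(ValueError):
    """Raised when no complete donor record is available."""


class SplitError(ValueError):
    """Raised when a stratified split would leave a class partition empty."""


@dataclass
class ClinicalCohort:
    """Encoded clinical cohort: values, labels, missingness and identifiers."""

    values: np.ndarray  # (n, 28) float, finite where not missing
    labels: np.ndarray  # (n,) int {0, 1}
    missing_mask: np.ndarray  # (n, 28) bool
    patient_ids: list[str] = field(default_factory=list)
    horizon: str = "5y"
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n < 2:
            raise ValueError("cohort needs at least 2 patients")
        if p != self.schema.n_features:
            raise ValueError(f"expected {self.schema.n_features} features, got {p}")
        if self.labels.shape != (n,) or self.missing_mask.shape != (n, p):
            raise ValueError("labels/missing_mask shape mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.patient_ids:
            self.patient_ids = [f"P{i:05d}" for i in range(n)]
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-missing values must be finite")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def subset(self, idx: np.ndarray | list[int]) -> "ClinicalCohort":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
            patient_ids=[self.patient_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Decode back to a readable table (levels as text, missing as NA)."""
        cols: dict[str, list] = {"patient_id": list(self.patient_ids)}
        for j, entry in enumerate(self.schema.entries):
            col = []
            for i in range(self.n_patients):
                if self.missing_mask[i, j]:
                    col.append("")
                else:
                    col.append(entry.decode(self.values[i, j]))
            cols[entry.name] = col
        cols[LABEL_COLUMN] = list(self.labels)
        return pd.DataFrame(cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "horizon": self.horizon,
            "patient_ids": self.patient_ids,
            "labels": self.labels.tolist(),
            "values": np.where(self.missing_mask, None, self.values).tolist(),
            "schema": self.schema.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClinicalCohort":
        payload = json.loads(Path(path).read_text())
        raw = payload["values"]
        mask = np.array([[v is None for v in row] for row in raw], dtype=bool)
        values = np.array(
            [[0.0 if v is None else float(v) for v in row] for row in raw], dtype=float
        )
        return cls(
            values=values,
            labels=np.asarray(payload["labels"]),
            missing_mask=mask,
            patient_ids=list(payload["patient_ids"]),
            horizon=payload.get("horizon", "5y"),
            schema=FeatureSchema.from_dict(payload["schema"]),
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test patient indices from a stratified hold-out split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_fraction: float

    def __post_init__(self) -> None:
        train = set(map(int, self.train_idx))
        test = set(map(int, self.test_idx))
        if train & test:
            raise ValueError("train and test indices overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_idx": [int(i) for i in self.train_idx],
            "test_idx": [int(i) for i in self.test_idx],
            "train_fraction": self.train_fraction,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(
            train_idx=np.asarray(d["train_idx"], dtype=int),
            test_idx=np.asarray(d["test_idx"], dtype=int),
            train_fraction=float(d["train_fraction"]),
        )


_MISSING_TOKENS = {"", "na", "nan", "none"}


def read_cohort(
    path: str | Path,
    schema: FeatureSchema | None = None,
    horizon: str = "5y",
) -> ClinicalCohort:
    """Read a cohort CSV/TSV; encode levels to codes, blanks/NA to missing.

    The header must contain every schema feature name (order-insensitive) and
    the ``ide`` label column. Unparseable or blank cells become missing.
    """
    schema = schema or default_schema()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema.validate_columns([c for c in df.columns])
    if LABEL_COLUMN not in df.columns:
        raise SchemaError(f"label column {LABEL_COLUMN!r} absent")

    n = len(df)
    values = np.zeros((n, schema.n_features))
    mask = np.zeros((n, schema.n_features), dtype=bool)
    for j, entry in enumerate(schema.entries):
        raw = df[entry.name].astype(str).str.strip()
        for i, cell in enumerate(raw):
            if cell.lower() in _MISSING_TOKENS:
                mask[i, j] = True
                continue
            try:
                values[i, j] = entry.encode(cell)
            except ValueError:
                if entry.kind == "continuous":
                    mask[i, j] = True  # unparseable numeric -> missing
                else:
                    raise ValueError(
                        f"row {i}: value {cell!r} outside level set of {entry.name!r}"
                    ) from None
    labels = df[LABEL_COLUMN].astype(int).to_numpy()
    ids = (
        df["patient_id"].tolist()
        if "patient_id" in df.columns
        else [f"P{i:05d}" for i in range(n)]
    )
    return ClinicalCohort(values, labels, mask, ids, horizon, schema)


def write_cohort(cohort: ClinicalCohort, path: str | Path) -> None:
    """Write a cohort as the standard CSV (levels as text, missing blank)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort.to_frame().to_csv(path, sep=sep, index=False)


def impute_missing(
    cohort: ClinicalCohort, reference: ClinicalCohort | None = None
) -> ClinicalCohort:
    """Proximity imputation: copy missing cells from the nearest complete donor.

    For each incomplete record, the donor is the fully observed reference
    record minimising Euclidean distance over the record's observed features,
    computed after per-feature min-max scaling fitted on the reference cohort.
    Ties break to the lowest donor row index. Complete records pass through
    unchanged; the result has an empty missing mask.
    """
    reference = reference if reference is not None else cohort
    donor_rows = ~reference.missing_mask.any(axis=1)
    if not donor_rows.any():
        raise ImputationError("reference cohort has no complete record")
    donors = reference.values[donor_rows]

    lo = donors.min(axis=0)
    span = donors.max(axis=0) - lo
    span[span == 0] = 1.0

    def scale(x: np.ndarray) -> np.ndarray:
        return (x - lo) / span

    donors_s = scale(donors)
    values = cohort.values.copy()
    for i in range(cohort.n_patients):
        miss = cohort.missing_mask[i]
        if not miss.any():
            continue
        obs = ~miss
        row_s = scale(values[i])
        d2 = ((donors_s[:, obs] - row_s[obs]) ** 2).sum(axis=1)
        donor = int(np.argmin(d2))  # argmin takes the first minimiser: lowest index
        values[i, miss] = donors[donor, miss]
    return replace(
        cohort,
        values=values,
        missing_mask=np.zeros_like(cohort.missing_mask),
        patient_ids=list(cohort.patient_ids),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_holdout(
    cohort: ClinicalCohort, train_fraction: float = 0.8, seed: int = 0
) -> SplitIndices:
    """Stratified random hold-out split with round-half-up per-class counts."""
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        members = np.flatnonzero(cohort.labels == cls)
        if members.size == 0:
            raise SplitError(f"class {cls} is empty")
        n_train = _round_half_up(train_fraction * members.size)
        if n_train == 0 or n_train == members.size:
            raise SplitError(
                f"class {cls}: train_fraction {train_fraction} leaves an empty partition"
            )
        chosen = rng.choice(members, size=n_train, replace=False)
        train_parts.append(np.sort(chosen))
        test_parts.append(np.sort(np.setdiff1d(members, chosen)))
    return SplitIndices(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        train_fraction=train_fraction,
    )
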