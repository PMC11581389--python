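"""Clinical feature schema for the breast-cancer IDE cohorts.

The cohort schema covers 28 clinical/histopathological features per patient:
demographics (age), tumour histology (type, grade, size, nodal involvement),
receptor status (ER, PgR, ki67, HER2), surgery and adjuvant-treatment
variables. Non-continuous features are encoded to real codes here; ordinal
features get consecutive integers in clinical order, nominal features get
integer codes in their catalogue order. Downstream min-max normalisation makes
any affine coding equivalent for ordinals; the nominal order is recorded so
encodings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = ["FeatureKind", "FeatureSpec", "FeatureSchema", "default_schema", "LABEL_COLUMN"]

#: Name of the binary outcome column in cohort files (1 = invasive disease event).
LABEL_COLUMN = "ide"

FeatureKind = str  # one of {"continuous", "ordinal", "nominal", "binary"}

_VALID_KINDS = frozenset({"continuous", "ordinal", "nominal", "binary"})


@dataclass(frozen=True)
class FeatureSpec:
    """One schema entry: a named feature, its kind, and its level coding."""

    name: str
    kind: FeatureKind
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous" and self.levels:
            raise ValueError(f"continuous feature {self.name!r} must not define levels")
        if self.kind != "continuous":
            if len(self.levels) < 2:
                raise ValueError(f"feature {self.name!r} needs at least 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in feature {self.name!r}")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"binary feature {self.name!r} must have 2 levels")

    @property
    def numeric_codes(self) -> dict[str, float]:
        """Level -> real code; consecutive integers in catalogue (clinical) order."""
        return {level: float(i) for i, level in enumerate(self.levels)}

    def encode(self, value: str) -> float:
        if self.kind == "continuous":
            return float(value)
        try:
            return self.numeric_codes[value]
        except KeyError:
            raise ValueError(
                f"value {value!r} not in level set of feature {self.name!r}; "
                f"admissible: {list(self.levels)}"
            ) from None

    def decode(self, code: float) -> str | float:
        if self.kind == "continuous":
            return float(code)
        idx = int(round(code))
        if not 0 <= idx < len(self.levels) or abs(code - idx) > 1e-9:
            raise ValueError(f"code {code!r} is not a level code of {self.name!r}")
        return self.levels[idx]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of exactly 28 feature specs."""

    entries: tuple[FeatureSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_features(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> FeatureSpec:
        for entry in self.entries:
            if entry.name == name:
                return entry
        raise KeyError(name)

    def __iter__(self) -> Iterable[FeatureSpec]:
        return iter(self.entries)

    def validate_columns(self, columns: Iterable[str]) -> None:
        """Check a file's feature columns cover the schema (order-insensitive)."""
        cols = set(columns)
        missing = [n for n in self.names if n not in cols]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        unknown = sorted(cols - set(self.names) - {LABEL_COLUMN, "patient_id"})
        if unknown:
            raise SchemaError(f"unknown columns: {unknown}")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "entries": [
                {"name": e.name, "kind": e.kind, "levels": list(e.levels)}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureSchema":
        entries = tuple(
            FeatureSpec(d["name"], d["kind"], tuple(d.get("levels", ())))
            for d in payload["entries"]
        )
        return cls(entries)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class SchemaError(ValueError):
    """A cohort file does not match the feature schema."""


def _spec(name: str, kind: str, *levels: str) -> FeatureSpec:
    return FeatureSpec(name, kind, tuple(levels))


# The 28-feature catalogue. Ordinal level order is clinical severity order;
# nominal level order is the catalogue order used for coding.
_ENTRIES = (
    _spec("age", "continuous"),
    _spec("previous_tumors", "binary", "absent", "present"),
    _spec("breast", "binary", "right", "left"),
    _spec("histological_type", "nominal", "ductal", "lobular", "others"),
    _spec("intraductal_component", "ordinal", "absent", "not typed", "G1", "G2", "G3"),
    _spec("multifocality", "binary", "absent", "present"),
    _spec("angioinvasion", "nominal", "absent", "focal", "extensive", "not typed"),
    _spec("er", "continuous"),
    _spec("pgr", "continuous"),
    _spec("ki67", "continuous"),
    _spec("her2_neu_score", "ordinal", "0", "1", "2", "3"),
    _spec("her2", "binary", "negative", "positive"),
    _spec("grading", "ordinal", "G1", "G2", "G3"),
    _spec("diameter", "ordinal", "T1a", "T1b", "T1c", "T2", "T3", "T4"),
    _spec("lymph_node_status", "ordinal", "N0", "N1", "N2", "N3"),
    _spec("slnb", "nominal", "not performed", "negative", "positive"),
    _spec("alnd", "binary", "not performed", "performed"),
    _spec("eradicated_lymph_nodes", "continuous"),
    _spec("metastatic_lymph_nodes", "continuous"),
    _spec("surgery", "binary", "mastectomy", "conserving-surgery"),
    _spec("chemotherapy", "binary", "no", "yes"),
    _spec("chemotherapy_scheme", "nominal", "not received", "C1", "C2", "C3", "C4", "C5"),
    _spec("chemotherapy_completion", "binary", "yes", "no"),
    _spec("trastuzumab", "binary", "no", "yes"),
    _spec("trastuzumab_completion", "binary", "yes", "no"),
    _spec("hormone_therapy", "binary", "no", "yes"),
    _spec("hormone_therapy_scheme", "nominal",
          "not received", "H1", "H2", "H3", "H4", "H5", "H6", "H7"),
    _spec("hormone_therapy_completion", "binary", "yes", "no"),
)


def default_schema() -> FeatureSchema:
    """The canonical 28-feature breast-cancer IDE schema."""
    schema = FeatureSchema(_ENTRIES)
    assert schema.n_features == 28
    return schema
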