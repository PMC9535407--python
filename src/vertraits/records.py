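"""Measurement-event data model, CSV template I/O, and standardization.

The template is a long-format CSV (one measurement event per row) with
camelCase Darwin Core-style headers. Identifiers chain the measurement
event (``diagnosticID``) to the specimen (``materialSampleID``) to the
organism (``individualID``). ``verbatimValue``/``verbatimUnit`` always
preserve what the provider reported; standardization only ever touches
the canonical fields.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "TraitRecord",
    "TraitTermMap",
    "DatasetManifest",
    "ValidationReport",
    "UnitRegistry",
    "TemplateError",
    "RequiredColumnError",
    "DuplicateIDError",
    "UnknownTraitColumnError",
    "DEFAULT_REQUIRED_COLUMNS",
    "read_template",
    "write_template",
    "records_to_frame",
    "frame_to_records",
    "validate_required",
    "wide_to_long",
    "standardize_terms",
    "canonicalize_units",
    "normalize_life_stage",
    "normalize_binomial",
]

LIFE_STAGES = ("adult", "juvenile", "unknown")
SEXES = ("male", "female", "unknown")
EPOCH_TAGS = ("modern", "zooarchaeological", "paleontological", "")

UNIT_UNRESOLVED = "unit unresolved"

#: Missing-value spellings treated as NA in measurement cells.
NA_STRINGS = frozenset({"", "na", "n/a", "nan", "null", "none", "."})


class TemplateError(ValueError):
    """Malformed template input."""


class RequiredColumnError(TemplateError):
    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            "missing required column(s): " + ", ".join(self.missing)
        )


class DuplicateIDError(TemplateError):
    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(
            "duplicate diagnosticID(s): " + ", ".join(self.duplicates)
        )


class UnknownTraitColumnError(TemplateError):
    def __init__(self, column: str, suggestions: Sequence[str]):
        self.column = column
        self.suggestions = list(suggestions)
        hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
        super().__init__(f"unresolvable trait column {column!r}{hint}")


@dataclass
class TraitRecord:
    """One measurement event on one specimen."""

    diagnostic_id: str
    material_sample_id: str
    scientific_name: str
    trait_term: str
    measurement_value: float | None
    measurement_unit: str
    verbatim_value: str
    verbatim_unit: str
    verbatim_trait_term: str = ""
    trait_iri: str = ""
    individual_id: str = ""
    life_stage: str = "unknown"
    sex: str = "unknown"
    year_collected: int | None = None
    locality: str = ""
    country: str = ""
    material_sample_type: str = ""
    basis_of_record: str = ""
    measurement_status: str = ""
    normality: str = ""
    lower_limit: float | None = None
    upper_limit: float | None = None
    lower_limit_method: str = ""
    upper_limit_method: str = ""
    unit_status: str = ""

    def __post_init__(self) -> None:
        if not self.diagnostic_id:
            raise TemplateError("diagnosticID must be non-empty")
        if self.measurement_value is not None:
            v = float(self.measurement_value)
            if not (v == v) or v in (float("inf"), float("-inf")):
                raise TemplateError(
                    f"measurementValue must be finite ({self.diagnostic_id})"
                )


#: attribute name -> camelCase CSV header, in template column order
COLUMN_MAP: dict[str, str] = {
    "diagnostic_id": "diagnosticID",
    "material_sample_id": "materialSampleID",
    "individual_id": "individualID",
    "scientific_name": "scientificName",
    "trait_term": "traitTerm",
    "trait_iri": "traitIRI",
    "measurement_value": "measurementValue",
    "measurement_unit": "measurementUnit",
    "verbatim_value": "verbatimValue",
    "verbatim_unit": "verbatimUnit",
    "verbatim_trait_term": "verbatimTraitTerm",
    "life_stage": "lifeStage",
    "sex": "sex",
    "year_collected": "yearCollected",
    "locality": "locality",
    "country": "country",
    "material_sample_type": "materialSampleType",
    "basis_of_record": "basisOfRecord",
    "measurement_status": "measurementStatus",
    "normality": "normality",
    "lower_limit": "lowerLimit",
    "upper_limit": "upperLimit",
    "lower_limit_method": "lowerLimitMethod",
    "upper_limit_method": "upperLimitMethod",
    "unit_status": "unitStatus",
}
HEADER_MAP = {v: k for k, v in COLUMN_MAP.items()}
TEMPLATE_COLUMNS = list(COLUMN_MAP.values())

_FLOAT_ATTRS = {"measurement_value", "lower_limit", "upper_limit"}
_INT_ATTRS = {"year_collected"}

DEFAULT_REQUIRED_COLUMNS = (
    "diagnosticID",
    "materialSampleID",
    "scientificName",
    "traitTerm",
    "measurementValue",
    "measurementUnit",
    "lifeStage",
    "yearCollected",
)

#: case-insensitive prefix table for provider life-stage vocabularies;
#: "subadult" deliberately folds into juvenile (conservative).
LIFE_STAGE_PREFIXES = {
    "ad": "adult",
    "juv": "juvenile",
    "imm": "juvenile",
    "sub": "juvenile",
    "yearling": "juvenile",
    "neonate": "juvenile",
}


def normalize_life_stage(value: str | None, table: Mapping[str, str] | None = None) -> str:
    if value is None:
        return "unknown"
    text = str(value).strip().lower()
    if text in LIFE_STAGES:
        return text
    for prefix, stage in (table or LIFE_STAGE_PREFIXES).items():
        if text.startswith(prefix):
            return stage
    return "unknown"


def normalize_binomial(name: str) -> str:
    """Whitespace-collapse a scientific name; genus capitalized, epithet lower."""
    parts = str(name).split()
    if not parts:
        return ""
    parts[0] = parts[0].capitalize()
    return " ".join(parts[:1] + [p.lower() for p in parts[1:]])


class TraitTermMap:
    """Synonym -> (canonical trait label, CURIE, measurement kind).

    Lookup is case-insensitive and whitespace-normalized. Every canonical
    label has exactly one CURIE.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, str]]):
        self._entries: dict[str, tuple[str, str, str]] = {}
        iri_by_label: dict[str, str] = {}
        for synonym, label, iri, kind in entries:
            key = self._key(synonym)
            self._entries[key] = (label, iri, kind)
            prior = iri_by_label.setdefault(label, iri)
            if prior != iri:
                raise TemplateError(
                    f"canonical label {label!r} mapped to two CURIEs ({prior}, {iri})"
                )

    @staticmethod
    def _key(term: str) -> str:
        return " ".join(str(term).split()).lower()

    def __contains__(self, term: str) -> bool:
        return self._key(term) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def resolve(self, term: str) -> tuple[str, str, str] | None:
        """Return (canonical label, CURIE, kind) or None if unmapped."""
        return self._entries.get(self._key(term))

    def suggestions(self, term: str, n: int = 3) -> list[str]:
        return difflib.get_close_matches(self._key(term), list(self._entries), n=n)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTermMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        return cls(
            (r.synonym, r.canonicalLabel, r.traitIRI, r.kind)
            for r in df.itertuples()
        )

    @classmethod
    def default(cls) -> "TraitTermMap":
        with resources.as_file(
            resources.files("vertraits.data") / "trait_terms.csv"
        ) as p:
            return cls.from_csv(p)


class UnitRegistry:
    """Verbatim unit spelling -> (canonical unit, multiplicative factor)."""

    def __init__(self, table: Mapping[str, tuple[str, float]]):
        self._table = {self._key(k): (c, float(f)) for k, (c, f) in table.items()}

    @staticmethod
    def _key(unit: str) -> str:
        return str(unit).strip().strip(".").lower()

    def resolve(self, unit: str) -> tuple[str, float] | None:
        return self._table.get(self._key(unit))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: (v["canonical"], v["factor"]) for k, v in raw.items()})

    @classmethod
    def default(cls) -> "UnitRegistry":
        with resources.as_file(resources.files("vertraits.data") / "units.yaml") as p:
            return cls.from_yaml(p)


@dataclass
class DatasetManifest:
    title: str = ""
    description: str = ""
    license: str = ""
    required_columns: tuple[str, ...] = DEFAULT_REQUIRED_COLUMNS
    row_count: int = 0
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def rows_missing_value(self) -> int:
        return self.missing_counts.get("measurementValue", 0)


@dataclass
class ValidationReport:
    valid: bool
    row_count: int
    missing_counts: dict[str, int]

    def to_text(self) -> str:
        lines = [f"rows: {self.row_count}", f"valid: {self.valid}"]
        for col, n in self.missing_counts.items():
            lines.append(f"missing {col}: {n}")
        return "\n".join(lines)


def _is_na(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and cell != cell:
        return True
    return str(cell).strip().lower() in NA_STRINGS


def _parse_float(text: str, where: str) -> float | None:
    if _is_na(text):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise TemplateError(f"non-numeric measurementValue {text!r} ({where})") from exc


def read_template(
    path: str | Path,
    required_columns: Sequence[str] = DEFAULT_REQUIRED_COLUMNS,
    title: str = "",
    description: str = "",
    license: str = "",
) -> tuple[list[TraitRecord], DatasetManifest]:
    """Read a long-format template CSV into records plus a manifest.

    Rows with an empty ``measurementValue`` are retained (the manifest
    counts them); verbatim fields are populated before any normalization.
    Raises :class:`RequiredColumnError` / :class:`DuplicateIDError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    observed = list(df.columns)
    missing_cols = [c for c in required_columns if c not in observed]
    if missing_cols:
        raise RequiredColumnError(missing_cols)

    dup = df["diagnosticID"][df["diagnosticID"].duplicated()].unique().tolist()
    if dup:
        raise DuplicateIDError(dup)

    records: list[TraitRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        kwargs: dict[str, object] = {}
        for header, value in row.items():
            attr = HEADER_MAP.get(header)
            if attr is None:
                continue
            if attr in _FLOAT_ATTRS:
                kwargs[attr] = _parse_float(value, f"row {i + 2}")
            elif attr in _INT_ATTRS:
                kwargs[attr] = None if _is_na(value) else int(float(value))
            else:
                kwargs[attr] = value
        if "verbatim_value" in HEADER_MAP.values() and not kwargs.get("verbatim_value"):
            kwargs["verbatim_value"] = row.get("measurementValue", "")
        if not kwargs.get("verbatim_unit"):
            kwargs["verbatim_unit"] = row.get("measurementUnit", "")
        kwargs["life_stage"] = normalize_life_stage(kwargs.get("life_stage", ""))
        records.append(TraitRecord(**kwargs))  # type: ignore[arg-type]

    missing_counts = {
        col: int(sum(_is_na(v) for v in df[col])) if col in df else len(df)
        for col in required_columns
    }
    manifest = DatasetManifest(
        title=title,
        description=description,
        license=license,
        required_columns=tuple(required_columns),
        row_count=len(df),
        missing_counts=missing_counts,
    )
    return records, manifest


def _format_cell(attr: str, value: object) -> str:
    if value is None:
        return ""
    if attr in _FLOAT_ATTRS:
        return repr(float(value))  # shortest round-trippable form
    return str(value)


def write_template(records: Iterable[TraitRecord], path: str | Path) -> None:
    """Emit the CSV dialect ``read_template`` consumes (stable column order)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TEMPLATE_COLUMNS)
        for rec in records:
            writer.writerow(
                _format_cell(attr, getattr(rec, attr)) for attr in COLUMN_MAP
            )


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    """Records as a DataFrame with template (camelCase) headers."""
    rows = [
        {COLUMN_MAP[attr]: getattr(rec, attr) for attr in COLUMN_MAP}
        for rec in records
    ]
    return pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TraitRecord]:
    out = []
    for row in df.to_dict("records"):
        kwargs = {HEADER_MAP[h]: v for h, v in row.items() if h in HEADER_MAP}
        for attr in _FLOAT_ATTRS:
            if attr in kwargs and _is_na(kwargs[attr]):
                kwargs[attr] = None
        if "year_collected" in kwargs and _is_na(kwargs["year_collected"]):
            kwargs["year_collected"] = None
        out.append(TraitRecord(**kwargs))
    return out


def validate_required(
    records: Sequence[TraitRecord],
    required_columns: Sequence[str] = DEFAULT_REQUIRED_COLUMNS,
) -> ValidationReport:
    """Per required column, count missing values; valid iff none missing."""
    missing = {}
    for col in required_columns:
        attr = HEADER_MAP.get(col)
        if attr is None:
            missing[col] = len(records)
            continue
        missing[col] = sum(
            1
            for rec in records
            if getattr(rec, attr) in (None, "")
            or (col == "lifeStage" and rec.life_stage == "unknown")
        )
    valid = len(records) > 0 and all(n == 0 for n in missing.values())
    return ValidationReport(valid=valid, row_count=len(records), missing_counts=missing)


def wide_to_long(
    table: pd.DataFrame,
    trait_columns: Sequence[str],
    term_map: TraitTermMap | None = None,
    units: Mapping[str, str] | None = None,
    sample_id_column: str = "materialSampleID",
    metadata_columns: Mapping[str, str] | None = None,
) -> list[TraitRecord]:
    """Melt a column-per-trait table into one record per non-missing cell.

    ``diagnosticID`` is minted deterministically as
    ``materialSampleID + "_" + canonical trait label``; cells that are NA
    are dropped. ``units`` maps trait column -> verbatim unit string.

    Raises :class:`UnknownTraitColumnError` for a column no synonym resolves.
    """
    term_map = term_map or TraitTermMap.default()
    units = dict(units or {})
    meta = dict(metadata_columns or {})
    meta.setdefault("scientificName", "scientificName")
    meta.setdefault("lifeStage", "lifeStage")
    meta.setdefault("yearCollected", "yearCollected")

    resolved: dict[str, tuple[str, str, str]] = {}
    for col in trait_columns:
        hit = term_map.resolve(col)
        if hit is None:
            raise UnknownTraitColumnError(col, term_map.suggestions(col))
        resolved[col] = hit

    records: list[TraitRecord] = []
    for row in table.to_dict("records"):
        sample_id = str(row.get(sample_id_column, "")).strip()
        for col in trait_columns:
            cell = row.get(col)
            if _is_na(cell):
                continue
            label, iri, _kind = resolved[col]
            unit = str(units.get(col, ""))
            year_raw = row.get(meta["yearCollected"])
            records.append(
                TraitRecord(
                    diagnostic_id=f"{sample_id}_{label}",
                    material_sample_id=sample_id,
                    scientific_name=normalize_binomial(
                        str(row.get(meta["scientificName"], ""))
                    ),
                    trait_term=label,
                    trait_iri=iri,
                    verbatim_trait_term=col,
                    measurement_value=float(cell),
                    measurement_unit=unit,
                    verbatim_value=str(cell),
                    verbatim_unit=unit,
                    life_stage=normalize_life_stage(row.get(meta["lifeStage"])),
                    year_collected=None if _is_na(year_raw) else int(float(year_raw)),
                )
            )
    return records


def standardize_terms(
    records: Sequence[TraitRecord],
    term_map: TraitTermMap | None = None,
) -> tuple[list[TraitRecord], list[str]]:
    """Rewrite traitTerm/traitIRI to canonical values; idempotent.

    The incoming term is preserved in ``verbatimTraitTerm`` (set once).
    Unmapped terms are reported, never dropped.
    """
    term_map = term_map or TraitTermMap.default()
    unmapped: list[str] = []
    out: list[TraitRecord] = []
    for rec in records:
        hit = term_map.resolve(rec.trait_term)
        if hit is None:
            if rec.trait_term not in unmapped:
                unmapped.append(rec.trait_term)
            out.append(rec)
            continue
        label, iri, _kind = hit
        out.append(
            replace(
                rec,
                trait_term=label,
                trait_iri=iri,
                verbatim_trait_term=rec.verbatim_trait_term or rec.trait_term,
            )
        )
    return out, unmapped


def canonicalize_units(
    records: Sequence[TraitRecord],
    registry: UnitRegistry | None = None,
) -> list[TraitRecord]:
    """Rescale measurementValue to canonical units (g / mm); idempotent.

    A record whose unit the registry cannot resolve is flagged
    ``unitStatus="unit unresolved"`` and is excluded from downstream
    statistics; verbatim fields are untouched either way.
    """
    registry = registry or UnitRegistry.default()
    out: list[TraitRecord] = []
    for rec in records:
        if rec.measurement_value is None:
            out.append(rec)
            continue
        hit = registry.resolve(rec.measurement_unit or rec.verbatim_unit)
        if hit is None:
            out.append(replace(rec, unit_status=UNIT_UNRESOLVED))
            continue
        canonical, factor = hit
        out.append(
            replace(
                rec,
                measurement_value=rec.measurement_value * factor,
                measurement_unit=canonical,
                unit_status="",
            )
        )
    return out
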