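"""Household survey data model, category vocabularies and delimited-file I/O.

One record per surveyed household: head demographics, family composition,
community-based health insurance (CBHI) enrollment, health-profile
indicators, a binary asset inventory, and annual expenditure components
(all sharing a 12-month recall window, in an unspecified local currency
treated as a unitless positive real).

Missing-data policy: ``referral_history`` is the only field allowed to be
missing, encoded by the explicit sentinel label ``"missing"`` (never an
empty cell) so that listwise behaviour downstream is auditable.  Any other
missing or out-of-vocabulary value is an error, not a silent recode.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ExpenditureProfile",
    "HouseholdRecord",
    "SurveyReadResult",
    "SchemaError",
    "VocabularyError",
    "SurveyParseError",
    "VOCABULARY",
    "MISSING",
    "derive_age_group",
    "read_survey",
    "write_survey",
    "load_schema",
    "records_to_frame",
]

MISSING = "missing"

SEX = ("male", "female")
AGE_GROUPS = ("<=30", "31-45", "46-60", ">60")
MARITAL = ("single", "married", "separated", "divorced", "widowed")
OCCUPATION = ("self_employed", "government", "private_sector")
OWNERSHIP = ("private", "rent")
INSURANCE = ("insured", "non_insured")
YESNO = ("yes", "no")
WEALTH_LABELS = ("poorest", "poorer", "middle", "richer", "richest")

#: Declared label vocabulary per categorical field; observed labels after a
#: successful read are always a subset of these.
VOCABULARY: dict[str, tuple[str, ...]] = {
    "head_sex": SEX,
    "head_age_group": AGE_GROUPS,
    "marital_status": MARITAL,
    "occupation": OCCUPATION,
    "ownership": OWNERSHIP,
    "insurance": INSURANCE,
    "u5_present": YESNO,
    "chronic_condition": YESNO,
    "traditional_medicine": YESNO,
    "referral_history": YESNO + (MISSING,),
}

#: Numeric code map used when categories must be numeric (design matrices,
#: provenance sidecars).  Insured is coded 0 and non-insured 1; the
#: non-insured stratum is the comparison group throughout.
CODE_MAP: dict[str, dict[str, int]] = {
    name: {label: i for i, label in enumerate(levels)}
    for name, levels in VOCABULARY.items()
}

_EXPENDITURE_FIELDS = (
    "food",
    "nonfood_nonhealth",
    "direct_medical",
    "direct_nonmedical",
    "lost_days",
    "daily_valuation",
)

_BASE_COLUMNS = (
    "household_id",
    "kebele",
    "head_sex",
    "head_age",
    "marital_status",
    "occupation",
    "family_size",
    "u5_present",
    "ownership",
    "insurance",
    "chronic_condition",
    "traditional_medicine",
    "referral_history",
) + _EXPENDITURE_FIELDS

ASSET_PREFIX = "asset_"


class SchemaError(ValueError):
    """A mandatory column is absent or the schema document is malformed."""


class VocabularyError(ValueError):
    """A categorical cell holds a label outside the declared vocabulary."""


class SurveyParseError(ValueError):
    """A numeric cell could not be parsed; carries the offending row number."""


def derive_age_group(age: int) -> str:
    """Band a household-head age into the four reporting groups.

    Bands are <=30, 31-45, 46-60 and >60, with each boundary inclusive on
    the lower band.  Heads younger than 18 are outside the survey domain.
    """
    if age < 18:
        raise ValueError(f"household head age must be >= 18, got {age}")
    if age <= 30:
        return "<=30"
    if age <= 45:
        return "31-45"
    if age <= 60:
        return "46-60"
    return ">60"


@dataclass(frozen=True)
class ExpenditureProfile:
    """Annual household expenditure components (12-month recall window).

    ``lost_days`` counts productivity-loss days for patients and caregivers
    combined; ``daily_valuation`` is the per-day monetisation used by the
    human-capital approach (pre-monetised losses such as premature death are
    folded into days x valuation by the data provider).
    """

    food: float
    nonfood_nonhealth: float
    direct_medical: float
    direct_nonmedical: float
    lost_days: float = 0.0
    daily_valuation: float = 0.0

    def validate(self) -> list[str]:
        problems = []
        for name in _EXPENDITURE_FIELDS:
            v = getattr(self, name)
            if not (v >= 0.0) or v != v or v in (float("inf"),):
                problems.append(f"{name} must be finite and >= 0, got {v}")
        return problems


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household."""

    household_id: str
    kebele: str
    head_sex: str
    head_age: int
    marital_status: str
    occupation: str
    family_size: int
    u5_present: str
    ownership: str
    insurance: str
    chronic_condition: str
    traditional_medicine: str
    expenditure: ExpenditureProfile
    referral_history: str = MISSING
    assets: Mapping[str, bool] = field(default_factory=dict)

    @property
    def head_age_group(self) -> str:
        return derive_age_group(self.head_age)

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        problems = []
        for name in VOCABULARY:
            if name == "head_age_group":
                continue
            label = getattr(self, name)
            if label not in VOCABULARY[name]:
                problems.append(f"{name}: label {label!r} outside vocabulary")
        if self.head_age < 18:
            problems.append(f"head_age must be >= 18, got {self.head_age}")
        if self.family_size < 1:
            problems.append(f"family_size must be >= 1, got {self.family_size}")
        problems.extend(self.expenditure.validate())
        return problems


@dataclass
class SurveyReadResult(Sequence):
    """Validated records plus row-indexed diagnostics for rejected rows."""

    records: list[HouseholdRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[HouseholdRecord]:
        return iter(self.records)


def load_schema(path: str | Path) -> dict:
    """Load a column-mapping schema document (YAML or JSON).

    Keys: ``columns`` maps canonical field names to file column names;
    ``labels`` maps, per field, file labels to vocabulary labels.
    """
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"schema document {path} is not a mapping")
    for key in doc:
        if key not in ("columns", "labels"):
            raise SchemaError(f"unknown schema key {key!r}")
    return doc


def _parse_float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SurveyParseError(
            f"row {row}: non-numeric value {raw!r} in column {column!r}"
        ) from None


def _parse_int(raw: str, column: str, row: int) -> int:
    try:
        return int(float(raw))
    except ValueError:
        raise SurveyParseError(
            f"row {row}: non-integer value {raw!r} in column {column!r}"
        ) from None


def read_survey(path: str | Path, schema: dict | None = None) -> SurveyReadResult:
    """Read a delimited survey file into validated household records.

    Rows violating numeric invariants (negative expenditure, family size
    < 1, head age < 18) are rejected with row-indexed diagnostics.  Labels
    outside the category vocabulary raise :class:`VocabularyError`; a
    missing mandatory column raises :class:`SchemaError`; non-numeric
    numeric cells raise :class:`SurveyParseError` naming the row.
    """
    schema = schema or {}
    colmap: Mapping[str, str] = schema.get("columns", {})
    labelmap: Mapping[str, Mapping[str, str]] = schema.get("labels", {})

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in _BASE_COLUMNS:
            if colmap.get(canonical, canonical) not in header:
                raise SchemaError(f"mandatory column {canonical!r} missing from header")
        asset_columns = [c for c in header if c.startswith(ASSET_PREFIX)]

        records: list[HouseholdRecord] = []
        rejected: list[tuple[int, str]] = []
        for row_index, row in enumerate(reader, start=1):
            def cell(canonical: str) -> str:
                raw = row.get(colmap.get(canonical, canonical), "")
                if raw is None or raw == "":
                    raise SurveyParseError(
                        f"row {row_index}: empty cell in column {canonical!r}"
                    )
                return labelmap.get(canonical, {}).get(raw, raw)

            for name in VOCABULARY:
                if name == "head_age_group":
                    continue
                label = cell(name)
                if label not in VOCABULARY[name]:
                    raise VocabularyError(
                        f"row {row_index}: label {label!r} outside the "
                        f"vocabulary of {name!r}"
                    )

            profile = ExpenditureProfile(
                **{
                    f: _parse_float(cell(f), f, row_index)
                    for f in _EXPENDITURE_FIELDS
                }
            )
            record = HouseholdRecord(
                household_id=cell("household_id"),
                kebele=cell("kebele"),
                head_sex=cell("head_sex"),
                head_age=_parse_int(cell("head_age"), "head_age", row_index),
                marital_status=cell("marital_status"),
                occupation=cell("occupation"),
                family_size=_parse_int(cell("family_size"), "family_size", row_index),
                u5_present=cell("u5_present"),
                ownership=cell("ownership"),
                insurance=cell("insurance"),
                chronic_condition=cell("chronic_condition"),
                traditional_medicine=cell("traditional_medicine"),
                referral_history=cell("referral_history"),
                expenditure=profile,
                assets={
                    c[len(ASSET_PREFIX):]: row[c] in ("1", "yes", "true", "True")
                    for c in asset_columns
                },
            )
            problems = record.validate()
            if problems:
                rejected.append((row_index, "; ".join(problems)))
            else:
                records.append(record)
    return SurveyReadResult(records=records, rejected=rejected)


def write_survey(
    records: Sequence[HouseholdRecord],
    path: str | Path,
    write_code_map: bool = False,
) -> None:
    """Write records as UTF-8 CSV readable back by :func:`read_survey`.

    Category labels are written as-is (lossless round trip).  Asset columns
    are taken from the first record; all records must share asset names.
    When ``write_code_map`` is set, the numeric code map is emitted alongside
    as ``<path>.codes.json`` for provenance.
    """
    asset_names = sorted(records[0].assets) if records else []
    columns = list(_BASE_COLUMNS) + [ASSET_PREFIX + a for a in asset_names]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            if sorted(rec.assets) != asset_names:
                raise ValueError(
                    f"record {rec.household_id}: asset names differ from first record"
                )
            row = [
                rec.household_id,
                rec.kebele,
                rec.head_sex,
                rec.head_age,
                rec.marital_status,
                rec.occupation,
                rec.family_size,
                rec.u5_present,
                rec.ownership,
                rec.insurance,
                rec.chronic_condition,
                rec.traditional_medicine,
                rec.referral_history,
            ]
            row += [repr(getattr(rec.expenditure, f)) for f in _EXPENDITURE_FIELDS]
            row += ["1" if rec.assets[a] else "0" for a in asset_names]
            writer.writerow(row)
    if write_code_map:
        Path(str(path) + ".codes.json").write_text(
            json.dumps(CODE_MAP, indent=1), encoding="utf-8"
        )


def records_to_frame(records: Sequence[HouseholdRecord]) -> pd.DataFrame:
    """Tabulate the categorical analysis variables of a record collection.

    Family size is banded as in the descriptive tables (<=4 vs >4).  The
    expenditure profile is not carried; CHE flags and wealth quintiles are
    appended by the measurement and wealth stages.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "household_id": rec.household_id,
                "insurance": rec.insurance,
                "head_sex": rec.head_sex,
                "head_age_group": rec.head_age_group,
                "marital_status": rec.marital_status,
                "occupation": rec.occupation,
                "family_size_group": "<=4" if rec.family_size <= 4 else ">4",
                "u5_present": rec.u5_present,
                "ownership": rec.ownership,
                "chronic_condition": rec.chronic_condition,
                "traditional_medicine": rec.traditional_medicine,
                "referral_history": rec.referral_history,
            }
        )
    return pd.DataFrame(rows)


def with_assets(record: HouseholdRecord, assets: Mapping[str, bool]) -> HouseholdRecord:
    """Return a copy of ``record`` with its asset inventory replaced."""
    return replace(record, assets=dict(assets))
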