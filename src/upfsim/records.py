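"""Core record types and flat-table I/O for Day-1 dietary recall data.

The pipeline consumes two tables: an item-level food table (one row per
recalled food, keyed by participant and an 8-digit USDA-style food code)
and a participant table carrying demographics, SNAP participation,
socioeconomic fields, and the complex-survey design fields (weight,
stratum, PSU).  This module defines the in-memory records, validated
readers/writers for both tables, per-participant aggregation of item
nutrients, and the derived socioeconomic categories (poverty-income-ratio
bands and the 10-item adult food-security classification).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NovaGroup",
    "FoodRecord",
    "ParticipantRecord",
    "NutrientTotals",
    "ParticipantIntake",
    "SchemaError",
    "RowError",
    "normalize_description",
    "read_food_table",
    "write_food_table",
    "read_participant_table",
    "write_participant_table",
    "aggregate_intake",
    "derive_pir_category",
    "derive_food_security",
    "FOOD_COLUMNS",
    "PARTICIPANT_COLUMNS",
]


class NovaGroup(enum.IntEnum):
    """NOVA processing groups; UNCLASSIFIED is a value, not an error."""

    UNCLASSIFIED = 0
    MINIMALLY_PROCESSED = 1
    CULINARY_INGREDIENT = 2
    PROCESSED = 3
    ULTRA_PROCESSED = 4

    def __str__(self) -> str:  # CSV representation
        return "UNCLASSIFIED" if self is NovaGroup.UNCLASSIFIED else str(int(self))

    @classmethod
    def parse(cls, value: object) -> "NovaGroup":
        if isinstance(value, NovaGroup):
            return value
        text = str(value).strip().upper()
        if text in ("", "UNCLASSIFIED", "NAN", "NONE"):
            return cls.UNCLASSIFIED
        return cls(int(float(text)))


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise malformed."""


class RowError(ValueError):
    """One or more rows violate field invariants; carries row indices."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


_PUNCT_RE = re.compile(r"[^A-Z0-9%]+")


def normalize_description(text: str) -> str:
    """Uppercase a food description and collapse punctuation to single spaces.

    Matches the style of FNDDS description strings so the keyword classifier
    sees a canonical token stream (``"Soft drink, cola"`` -> ``"SOFT DRINK COLA"``).
    """
    return _PUNCT_RE.sub(" ", str(text).upper()).strip()


@dataclass
class NutrientTotals:
    """Daily totals: energy (kcal/d), sodium (mg/d), added sugar (g/d), fiber (g/d)."""

    energy: float = 0.0
    sodium: float = 0.0
    added_sugar: float = 0.0
    fiber: float = 0.0

    def __post_init__(self) -> None:
        for name in ("energy", "sodium", "added_sugar", "fiber"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def __add__(self, other: "NutrientTotals") -> "NutrientTotals":
        return NutrientTotals(
            self.energy + other.energy,
            self.sodium + other.sodium,
            self.added_sugar + other.added_sugar,
            self.fiber + other.fiber,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "sodium": self.sodium,
            "added_sugar": self.added_sugar,
            "fiber": self.fiber,
        }


@dataclass
class FoodRecord:
    """One recalled food item linked to its USDA-style food code."""

    participant_id: str
    food_code: int
    description: str
    energy: float
    sodium: float
    added_sugar: float
    fiber: float
    nova_group: NovaGroup = NovaGroup.UNCLASSIFIED

    def __post_init__(self) -> None:
        self.participant_id = str(self.participant_id)
        self.description = normalize_description(self.description)
        for name in ("energy", "sodium", "added_sugar", "fiber"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"food item {self.participant_id}/{self.food_code}: "
                    f"{name} must be finite and >= 0, got {v!r}"
                )
            setattr(self, name, v)
        self.nova_group = NovaGroup.parse(self.nova_group)


@dataclass
class ParticipantRecord:
    """Demographics, SNAP status and survey-design fields for one adult."""

    participant_id: str
    age: float
    sex: str
    race_ethnicity: str
    snap: bool
    pir: float
    food_security_score: int
    education: str
    household_size: int
    survey_weight: float
    stratum: str
    psu: str

    def __post_init__(self) -> None:
        self.participant_id = str(self.participant_id)
        if self.pir < 0:
            raise ValueError(f"pir must be >= 0, got {self.pir}")
        if not 0 <= int(self.food_security_score) <= 10:
            raise ValueError(
                f"food_security_score must be in [0, 10], got {self.food_security_score}"
            )
        if self.survey_weight <= 0:
            raise ValueError(f"survey_weight must be > 0, got {self.survey_weight}")
        if int(self.household_size) < 1:
            raise ValueError(f"household_size must be >= 1, got {self.household_size}")
        self.food_security_score = int(self.food_security_score)
        self.household_size = int(self.household_size)
        self.stratum = str(self.stratum)
        self.psu = str(self.psu)


@dataclass
class ParticipantIntake:
    """Per-participant daily totals over all foods and over NOVA-4 foods only.

    Invariant: the UPF-attributable totals never exceed the all-food totals
    componentwise, so the UPF energy share lies in [0, 1] whenever total
    energy is positive.
    """

    participant_id: str
    total: NutrientTotals
    upf: NutrientTotals
    zero_energy: bool = field(default=False)

    def __post_init__(self) -> None:
        for name in ("energy", "sodium", "added_sugar", "fiber"):
            u, t = getattr(self.upf, name), getattr(self.total, name)
            if u > t + 1e-9 * max(1.0, t):
                raise ValueError(
                    f"participant {self.participant_id}: UPF {name} ({u}) "
                    f"exceeds total ({t})"
                )
        self.zero_energy = self.total.energy == 0.0


FOOD_COLUMNS = [
    "participant_id",
    "food_code",
    "description",
    "energy_kcal",
    "sodium_mg",
    "added_sugar_g",
    "fiber_g",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "race_ethnicity",
    "snap",
    "pir",
    "food_security_score",
    "education",
    "household_size",
    "weight",
    "stratum",
    "psu",
]

_FOOD_NUTRIENTS = {
    "energy_kcal": "energy",
    "sodium_mg": "sodium",
    "added_sugar_g": "added_sugar",
    "fiber_g": "fiber",
}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_food_table(path: str | Path) -> list[FoodRecord]:
    """Read an item-level food CSV into validated :class:`FoodRecord` s.

    Rows with missing, non-numeric or negative nutrient values are rejected
    with a :class:`RowError` listing the offending line numbers (header is
    line 1, first data row line 2).  Missing added sugar is an error, not an
    implicit zero: silently zeroing it would bias substitution deltas.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "description": str},
        float_precision="round_trip",
    )
    _require_columns(df, FOOD_COLUMNS, path)

    bad_rows: list[int] = []
    reasons: list[str] = []
    for col in _FOOD_NUTRIENTS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | ~np.isfinite(values.fillna(0.0))
        for idx in df.index[bad]:
            bad_rows.append(int(idx) + 2)
            reasons.append(f"line {int(idx) + 2}: invalid {col}={df.at[idx, col]!r}")
        df[col] = values
    codes = pd.to_numeric(df["food_code"], errors="coerce")
    for idx in df.index[codes.isna()]:
        bad_rows.append(int(idx) + 2)
        reasons.append(f"line {int(idx) + 2}: unparseable food_code={df.at[idx, 'food_code']!r}")
    if bad_rows:
        raise RowError(
            f"{path}: {len(set(bad_rows))} invalid row(s): " + "; ".join(reasons),
            sorted(set(bad_rows)),
        )

    records = []
    for row in df.itertuples(index=False):
        kwargs = {
            "participant_id": row.participant_id,
            "food_code": int(row.food_code),
            "description": row.description,
            **{attr: getattr(row, col) for col, attr in _FOOD_NUTRIENTS.items()},
        }
        if "nova_group" in df.columns:
            kwargs["nova_group"] = NovaGroup.parse(row.nova_group)
        records.append(FoodRecord(**kwargs))
    return records


def write_food_table(records: Sequence[FoodRecord], path: str | Path) -> None:
    """Write food records back to CSV, appending the nova_group column."""
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "food_code": [r.food_code for r in records],
            "description": [r.description for r in records],
            "energy_kcal": [r.energy for r in records],
            "sodium_mg": [r.sodium for r in records],
            "added_sugar_g": [r.added_sugar for r in records],
            "fiber_g": [r.fiber for r in records],
            "nova_group": [str(r.nova_group) for r in records],
        }
    )
    # repr-style floats + round_trip parsing keep numeric fields bit-exact
    df.to_csv(path, index=False)


def read_participant_table(path: str | Path) -> list[ParticipantRecord]:
    """Read the participant CSV into validated :class:`ParticipantRecord` s."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "stratum": str, "psu": str, "sex": str},
        float_precision="round_trip",
    )
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    records = []
    errors = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ParticipantRecord(
                    participant_id=row.participant_id,
                    age=float(row.age),
                    sex=str(row.sex),
                    race_ethnicity=str(row.race_ethnicity),
                    snap=_parse_bool(row.snap),
                    pir=float(row.pir),
                    food_security_score=int(row.food_security_score),
                    education=str(row.education),
                    household_size=int(row.household_size),
                    survey_weight=float(row.weight),
                    stratum=str(row.stratum),
                    psu=str(row.psu),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((i + 2, str(exc)))
    if errors:
        raise RowError(
            f"{path}: invalid participant row(s): "
            + "; ".join(f"line {ln}: {msg}" for ln, msg in errors),
            [ln for ln, _ in errors],
        )
    return records


def write_participant_table(
    records: Sequence[ParticipantRecord], path: str | Path, derived: bool = True
) -> None:
    """Write participants to CSV; optionally append derived category columns."""
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "race_ethnicity": [r.race_ethnicity for r in records],
            "snap": [r.snap for r in records],
            "pir": [r.pir for r in records],
            "food_security_score": [r.food_security_score for r in records],
            "education": [r.education for r in records],
            "household_size": [r.household_size for r in records],
            "weight": [r.survey_weight for r in records],
            "stratum": [r.stratum for r in records],
            "psu": [r.psu for r in records],
        }
    )
    if derived:
        df["pir_category"] = [derive_pir_category(r.pir) for r in records]
        levels = [derive_food_security(r.food_security_score) for r in records]
        df["food_security_level"] = [lv for lv, _ in levels]
        df["food_insecure"] = [ins for _, ins in levels]
    df.to_csv(path, index=False)


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "snap"):
        return True
    if text in ("false", "0", "no", "nonsnap", "non-snap"):
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def aggregate_intake(foods: Sequence[FoodRecord]) -> list[ParticipantIntake]:
    """Sum item nutrients to per-participant totals, splitting out NOVA-4.

    Every item must carry a final NOVA assignment; an UNCLASSIFIED item is an
    error naming the item, because aggregating over vocabulary gaps would
    silently shrink the UPF-attributable pool.  Participants appear in first-
    occurrence order; a participant whose items sum to zero energy is flagged
    rather than dropped.
    """
    unclassified = [
        f"{f.participant_id}/{f.food_code} ({f.description!r})"
        for f in foods
        if f.nova_group is NovaGroup.UNCLASSIFIED
    ]
    if unclassified:
        raise ValueError(
            "cannot aggregate: UNCLASSIFIED item(s) remain "
            f"(classification must run first): {', '.join(unclassified[:5])}"
            + ("..." if len(unclassified) > 5 else "")
        )
    totals: dict[str, NutrientTotals] = {}
    upfs: dict[str, NutrientTotals] = {}
    for f in foods:
        item = NutrientTotals(f.energy, f.sodium, f.added_sugar, f.fiber)
        totals[f.participant_id] = totals.get(f.participant_id, NutrientTotals()) + item
        base = upfs.get(f.participant_id, NutrientTotals())
        upfs[f.participant_id] = (
            base + item if f.nova_group is NovaGroup.ULTRA_PROCESSED else base
        )
    return [
        ParticipantIntake(pid, total=totals[pid], upf=upfs[pid]) for pid in totals
    ]


#: PIR bands used by SNAP eligibility analyses; both cutpoints 1.30 and 1.85
#: are assigned to the middle band (the source ranges are inclusive-style).
PIR_CATEGORIES = ("low", "near_poverty", "higher")

FOOD_SECURITY_LEVELS = ("high", "marginal", "low", "very_low")


def derive_pir_category(pir: float) -> str:
    """Categorize a poverty-income ratio: [0,1.30) low, [1.30,1.85] near_poverty, (1.85,inf) higher."""
    if not np.isfinite(pir) or pir < 0:
        raise ValueError(f"pir must be finite and >= 0, got {pir!r}")
    if pir < 1.30:
        return "low"
    if pir <= 1.85:
        return "near_poverty"
    return "higher"


def derive_food_security(score: int) -> tuple[str, bool]:
    """Map a 0-10 adult food-security raw score to its level and binary indicator.

    Levels: high (0), marginal (1-2), low (3-5), very_low (6-10).  The binary
    food-insecurity indicator is True for scores >= 3 (low or very low).
    """
    score = int(score)
    if not 0 <= score <= 10:
        raise ValueError(f"food security score must be in [0, 10], got {score}")
    if score == 0:
        level = "high"
    elif score <= 2:
        level = "marginal"
    elif score <= 5:
        level = "low"
    else:
        level = "very_low"
    return level, score >= 3
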