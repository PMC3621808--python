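"""Coding of raw child/parent survey responses into analysis variables.

Raw responses arrive as a delimited table with one row per child.  Each
instrument has a fixed response grid; the functions here map labels (or
numeric codes already on the grid) to the analysis scale, reject anything
off-grid, and assemble the complete-case analytic table.

Coding conventions
------------------
* sports participation: the two favourite-sport durations (each on the grid
  0, 0.5, ..., 5.0 hours/week) are summed; the binary participation outcome
  is 1 iff the summed duration is at least 30 minutes/week.
* equipment score: count of eight physical-activity equipment items at home
  (bike, racket, ball, sporting shoes, skipping rope, skates, skis,
  skateboard), range 0-8.
* parental support items (financial, logistic, emotional, reinforcement):
  always=4, often=3, sometimes=2, not often=1, never=0.
* co-participation: never=0, less than once a week=0.5, once a week=1,
  2-4 days a week=3, 5-6 days a week=5.5, every day=7.
* parental modelling: weekday and weekend leisure-time activity, each on
  none=0, 30 min=0.5, 1h=1, 2h=2, 3h=3, 4h=4, >=5h=5; summed to 0-10.
* cognitions (attitude, belief, enjoyment, pbc): five-point items recoded
  from positions 1..5 to -2..2, higher = more positive.
* sex: girl=0, boy=1 (a reporting convention only).
* parental education: three ordered bands "<12", "12-13", ">=14" years,
  with "<12" the reference level in models.

Label matching is case-insensitive after whitespace trimming.  Missing
values are represented as NaN (empty cells in CSV), never as silent zeros.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CodingError",
    "EQUIPMENT_ITEMS",
    "SPORT_GRID",
    "code_sports",
    "score_equipment",
    "code_support",
    "code_coparticipation",
    "code_modelling",
    "code_cognition",
    "code_sex",
    "code_education",
    "code_table",
    "assemble_analytic_table",
    "ExclusionReport",
    "ANALYSIS_COLUMNS",
]


class CodingError(ValueError):
    """A raw response is off its instrument's grid or label set."""


EQUIPMENT_ITEMS = (
    "bike",
    "racket",
    "ball",
    "shoes",
    "rope",
    "skates",
    "skis",
    "skateboard",
)

#: legal responses for a single sport's weekly duration (hours)
SPORT_GRID = tuple(np.arange(0.0, 5.01, 0.5))

SUPPORT_LABELS = {
    "always": 4.0,
    "often": 3.0,
    "sometimes": 2.0,
    "not often": 1.0,
    "never": 0.0,
}

COPARTICIPATION_LABELS = {
    "never": 0.0,
    "less than once a week": 0.5,
    "<once/week": 0.5,
    "once a week": 1.0,
    "2-4 days a week": 3.0,
    "5-6 days a week": 5.5,
    "every day": 7.0,
}

MODELLING_LABELS = {
    "none": 0.0,
    "none at all": 0.0,
    "30min": 0.5,
    "30 min/wk": 0.5,
    "1h": 1.0,
    "1 hr/week": 1.0,
    "2h": 2.0,
    "2 hr/week": 2.0,
    "3h": 3.0,
    "3 hr/week": 3.0,
    "4h": 4.0,
    "4 hr/week": 4.0,
    ">=5h": 5.0,
    "5h or more": 5.0,
    "5 hr/week or more": 5.0,
}

SEX_LABELS = {"girl": 0, "boy": 1}

EDUCATION_LABELS = {
    "<12": "<12",
    "< 12 years": "<12",
    "<12 years": "<12",
    "12-13": "12-13",
    "12-13 years": "12-13",
    ">=14": ">=14",
    ">= 14 years": ">=14",
    ">=14 years": ">=14",
}

#: columns of the coded analytic table (besides the three identifiers)
ANALYSIS_COLUMNS = (
    "sex",
    "age_years",
    "parent_education",
    "equipment",
    "financial",
    "logistic",
    "emotional",
    "reinforcement",
    "coparticipation",
    "modelling",
    "attitude",
    "belief",
    "enjoyment",
    "pbc",
    "sport_hours",
    "sport_participant",
)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return value is pd.NA


def _lookup(value, labels: dict, *, grid=None, what: str = "response"):
    """Map a label or on-grid numeric code to its analysis code.

    ``labels`` maps normalized labels to codes; ``grid`` is the set of
    numeric codes accepted directly (defaults to the values of ``labels``).
    """
    if _is_missing(value):
        return np.nan
    if isinstance(value, str):
        key = value.strip().lower()
        if key in labels:
            return labels[key]
        try:
            value = float(key)
        except ValueError:
            raise CodingError(f"unknown {what} label: {value!r}") from None
    value = float(value)
    legal = set(grid) if grid is not None else set(labels.values())
    if value not in legal:
        raise CodingError(f"{what} code {value!r} is not on the grid {sorted(legal)}")
    return value


def code_sports(sport1_duration, sport2_duration):
    """Sum the two favourite-sport durations and dichotomize participation.

    Returns ``(sport_hours, sport_participant)``; both NaN if either input
    is missing.  Participation is 1 iff the total is >= 0.5 h/week (the
    smallest non-zero response).
    """
    if _is_missing(sport1_duration) or _is_missing(sport2_duration):
        return np.nan, np.nan
    vals = []
    for v in (sport1_duration, sport2_duration):
        v = float(v)
        if v not in set(SPORT_GRID):
            raise CodingError(
                f"sport duration {v!r} is not on the response grid 0, 0.5, ..., 5.0"
            )
        vals.append(v)
    hours = vals[0] + vals[1]
    return hours, int(hours >= 0.5)


def score_equipment(indicators) -> float:
    """Count owned equipment items from the eight binary indicators.

    ``indicators`` is a sequence of eight values in {0, 1}; returns NaN if
    any is missing.
    """
    vals = list(indicators)
    if len(vals) != len(EQUIPMENT_ITEMS):
        raise CodingError(
            f"expected {len(EQUIPMENT_ITEMS)} equipment indicators, got {len(vals)}"
        )
    if any(_is_missing(v) for v in vals):
        return np.nan
    total = 0
    for item, v in zip(EQUIPMENT_ITEMS, vals):
        v = float(v)
        if v not in (0.0, 1.0):
            raise CodingError(f"equipment indicator {item!r} must be 0/1, got {v!r}")
        total += int(v)
    return float(total)


def code_support(label) -> float:
    """Code a parental-support item (always=4 ... never=0)."""
    return _lookup(label, SUPPORT_LABELS, what="support")


def code_coparticipation(label) -> float:
    """Code parent-child co-participation frequency onto 0-7 days/week."""
    return _lookup(label, COPARTICIPATION_LABELS, what="co-participation")


def code_modelling(weekday_label, weekend_label) -> float:
    """Sum weekday and weekend parental leisure-time activity (0-10 h/week)."""
    wd = _lookup(weekday_label, MODELLING_LABELS, what="modelling")
    we = _lookup(weekend_label, MODELLING_LABELS, what="modelling")
    if math.isnan(wd) or math.isnan(we):
        return np.nan
    return wd + we


def code_cognition(response) -> float:
    """Recode a five-point cognition item (positions 1..5) to -2..2."""
    if _is_missing(response):
        return np.nan
    value = float(response)
    if value not in (1.0, 2.0, 3.0, 4.0, 5.0):
        raise CodingError(f"cognition response {response!r} must be in 1..5")
    return value - 3.0


def code_sex(label):
    """Code sex, girl=0 / boy=1."""
    return _lookup(label, SEX_LABELS, grid=(0, 1), what="sex")


def code_education(label):
    """Normalize parental education to the three bands '<12', '12-13', '>=14'."""
    if _is_missing(label):
        return np.nan
    key = str(label).strip().lower()
    if key in EDUCATION_LABELS:
        return EDUCATION_LABELS[key]
    raise CodingError(f"unknown education label: {label!r}")


def code_table(raw: pd.DataFrame, codebook: dict | None = None) -> pd.DataFrame:
    """Code a raw survey table into the analytic-variable layout.

    Expected raw columns: ``child_id, school_id, country_id, sex,
    age_years, parent_education, sport1_duration, sport2_duration,
    equipment_<item>`` (eight items), ``financial_support,
    logistic_support, emotional_support, reinforcement, coparticipation,
    modelling_weekday, modelling_weekend, attitude, belief, enjoyment,
    pbc``.  A ``codebook`` dict (e.g. loaded from JSON/YAML) may override
    any label->code map: keys ``support``, ``coparticipation``,
    ``modelling``, ``sex``, ``education``.

    Off-grid values raise :class:`CodingError` naming the row and column.
    """
    codebook = codebook or {}
    support_map = {k.lower(): v for k, v in codebook.get("support", SUPPORT_LABELS).items()}
    copart_map = {
        k.lower(): v for k, v in codebook.get("coparticipation", COPARTICIPATION_LABELS).items()
    }
    modelling_map = {k.lower(): v for k, v in codebook.get("modelling", MODELLING_LABELS).items()}
    sex_map = {k.lower(): v for k, v in codebook.get("sex", SEX_LABELS).items()}

    required = ["child_id", "school_id", "country_id"]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise CodingError(f"raw table lacks identifier columns: {missing_cols}")

    out = {}
    out["child_id"] = raw["child_id"].astype(str)
    out["school_id"] = raw["school_id"].astype(str)
    out["country_id"] = raw["country_id"].astype(str)

    def coded(column, fn):
        try:
            return [fn(v) for v in raw[column]]
        except KeyError:
            raise CodingError(f"raw table lacks column {column!r}") from None

    out["sex"] = coded("sex", lambda v: _lookup(v, sex_map, grid=(0, 1), what="sex"))
    out["age_years"] = coded("age_years", lambda v: np.nan if _is_missing(v) else float(v))
    out["parent_education"] = coded("parent_education", code_education)

    eq_cols = [f"equipment_{item}" for item in EQUIPMENT_ITEMS]
    for c in eq_cols:
        if c not in raw.columns:
            raise CodingError(f"raw table lacks equipment column {c!r}")
    out["equipment"] = [
        score_equipment(row) for row in raw[eq_cols].itertuples(index=False)
    ]

    for target, column in [
        ("financial", "financial_support"),
        ("logistic", "logistic_support"),
        ("emotional", "emotional_support"),
        ("reinforcement", "reinforcement"),
    ]:
        out[target] = coded(column, lambda v: _lookup(v, support_map, what="support"))
    out["coparticipation"] = coded(
        "coparticipation", lambda v: _lookup(v, copart_map, what="co-participation")
    )

    wd = coded("modelling_weekday", lambda v: _lookup(v, modelling_map, what="modelling"))
    we = coded("modelling_weekend", lambda v: _lookup(v, modelling_map, what="modelling"))
    out["modelling"] = [
        np.nan if (math.isnan(a) or math.isnan(b)) else a + b for a, b in zip(wd, we)
    ]

    for med in ("attitude", "belief", "enjoyment", "pbc"):
        out[med] = coded(med, code_cognition)

    sports = [
        code_sports(s1, s2)
        for s1, s2 in zip(raw["sport1_duration"], raw["sport2_duration"])
    ]
    out["sport_hours"] = [s[0] for s in sports]
    out["sport_participant"] = [s[1] for s in sports]

    return pd.DataFrame(out, index=raw.index)


@dataclass
class ExclusionReport:
    """Complete-case exclusion accounting for the analytic table."""

    n_input: int
    n_kept: int
    n_excluded: int
    by_column: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": self.n_kept,
                "n_excluded": self.n_excluded,
                "by_column": self.by_column,
            },
            indent=2,
        )


def assemble_analytic_table(
    table: pd.DataFrame, required_columns: list[str]
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Restrict to complete cases on ``required_columns``.

    Returns the kept rows (order preserved) and an :class:`ExclusionReport`.
    ``by_column`` counts, per required column, the excluded rows missing
    that column; a row missing several columns is counted under each, so
    the per-column counts can exceed ``n_excluded``.

    Raises :class:`CodingError` if a required column is absent or if no
    complete cases remain.
    """
    missing_cols = [c for c in required_columns if c not in table.columns]
    if missing_cols:
        raise CodingError(f"required columns absent from table: {missing_cols}")
    isna = table[required_columns].isna()
    keep = ~isna.any(axis=1)
    kept = table.loc[keep].copy()
    if len(kept) == 0:
        raise CodingError("no complete cases remain after exclusions")
    by_column = {
        c: int(isna.loc[~keep, c].sum()) for c in required_columns if isna[c].any()
    }
    report = ExclusionReport(
        n_input=len(table),
        n_kept=len(kept),
        n_excluded=int((~keep).sum()),
        by_column=by_column,
    )
    return kept, report
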