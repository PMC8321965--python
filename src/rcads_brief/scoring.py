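"""Score and classify respondents on the brief 11-item screen.

The screen is six anxiety items + five depression items from the RCADS,
optionally extended by two symptom-impact items.  Cut-offs are informant-
and gender-specific integer thresholds; a respondent screens positive when
their score is greater than or equal to the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank, default_item_bank
from .cohort import META_COLUMNS, ResponseMatrix

__all__ = [
    "ScreenDefinition",
    "ScreenResult",
    "FormatError",
    "ThresholdingError",
    "default_screen",
    "score_screen",
    "score_frame",
    "read_responses",
    "write_results",
    "RISK_ADVISORY",
]

UNDEFINED = None

SCALES = ("anxiety", "depression", "total", "total_plus_impact")

RISK_ADVISORY = (
    "Depression score at or above threshold: carry out a thorough risk "
    "assessment. Suicidal-ideation items are not part of this screen and a "
    "positive depression score alone says nothing about risk of self-harm."
)


class FormatError(ValueError):
    pass


class ThresholdingError(KeyError):
    pass


@dataclass(frozen=True)
class ScreenDefinition:
    """Item composition and the (informant, gender, scale) cut-off table."""

    anxiety_items: tuple[str, ...]
    depression_items: tuple[str, ...]
    impact_items: tuple[str, ...]
    cutoffs: Mapping[tuple[str, str, str], int]
    name: str = "custom"

    @property
    def total_items(self) -> tuple[str, ...]:
        return self.anxiety_items + self.depression_items

    def cutoff(self, informant: str, gender: str, scale: str) -> int:
        key = (informant, gender, scale)
        if key not in self.cutoffs:
            raise ThresholdingError(
                f"no cut-off for informant={informant!r}, gender={gender!r}, "
                f"scale={scale!r}; supply threshold_gender explicitly for "
                "respondents outside the published table")
        return self.cutoffs[key]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "anxiety_items": list(self.anxiety_items),
            "depression_items": list(self.depression_items),
            "impact_items": list(self.impact_items),
            "cutoffs": [
                {"informant": k[0], "gender": k[1], "scale": k[2], "threshold": v}
                for k, v in self.cutoffs.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreenDefinition":
        payload = json.loads(Path(path).read_text())
        return cls(
            name=payload.get("name", "custom"),
            anxiety_items=tuple(payload["anxiety_items"]),
            depression_items=tuple(payload["depression_items"]),
            impact_items=tuple(payload["impact_items"]),
            cutoffs={
                (c["informant"], c["gender"], c["scale"]): int(c["threshold"])
                for c in payload["cutoffs"]
            },
        )


# Published cut-off table: score >= threshold screens positive.
_DEFAULT_CUTOFFS: dict[tuple[str, str, str], int] = {
    ("adolescent", "male", "anxiety"): 5,
    ("adolescent", "female", "anxiety"): 9,
    ("adolescent", "male", "depression"): 8,
    ("adolescent", "female", "depression"): 9,
    ("adolescent", "male", "total"): 9,
    ("adolescent", "female", "total"): 14,
    ("adolescent", "male", "total_plus_impact"): 14,
    ("adolescent", "female", "total_plus_impact"): 18,
    ("parent", "male", "anxiety"): 5,
    ("parent", "female", "anxiety"): 7,
    ("parent", "male", "depression"): 6,
    ("parent", "female", "depression"): 7,
    ("parent", "male", "total"): 8,
    ("parent", "female", "total"): 11,
    ("parent", "male", "total_plus_impact"): 13,
    ("parent", "female", "total_plus_impact"): 15,
}


def default_screen() -> ScreenDefinition:
    """The published 11-item screen with its recommended cut-offs.

    Anxiety: RCADS 18, 45, 35, 34, 24, 20 (range 0-18); depression: RCADS
    19, 6, 29, 2, 21 (0-15); total 0-33; optional impact items (distress and
    school interference) extend the total to 0-39.
    """
    return ScreenDefinition(
        name="rcads-11",
        anxiety_items=("RCADS18", "RCADS45", "RCADS35", "RCADS34", "RCADS24", "RCADS20"),
        depression_items=("RCADS19", "RCADS6", "RCADS29", "RCADS2", "RCADS21"),
        impact_items=("IMP_DISTRESS", "IMP_SCHOOL"),
        cutoffs=dict(_DEFAULT_CUTOFFS),
    )


@dataclass(frozen=True)
class ScreenResult:
    person_id: str
    informant: str
    gender_used: str
    anxiety_score: int | None
    depression_score: int | None
    total_score: int | None
    total_plus_impact_score: int | None
    anxiety_positive: bool | None
    depression_positive: bool | None
    total_positive: bool | None
    total_plus_impact_positive: bool | None
    risk_advisory: str | None

    def to_dict(self) -> dict:
        return asdict(self)


def _subscore(responses: Mapping[str, float], items: Sequence[str],
              bank: ItemBank) -> int | None:
    total = 0
    for item_id in items:
        v = responses.get(item_id)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return UNDEFINED
        it = bank.get(item_id)
        if not it.min_score <= v <= it.max_score:
            raise FormatError(
                f"value {v} out of range [{it.min_score}, {it.max_score}] "
                f"for item {item_id}")
        if float(v) != int(v):
            raise FormatError(f"non-integer response {v} for item {item_id}")
        total += int(v)
    return total


def score_screen(
    responses: Mapping[str, float],
    screen: ScreenDefinition | None = None,
    *,
    gender: str,
    informant: str,
    person_id: str = "",
    bank: ItemBank | None = None,
    threshold_gender: str | None = None,
) -> ScreenResult:
    """Score one respondent and classify against the cut-off table.

    Any missing constituent item leaves that scale's score and flag
    undefined (no proration).  Respondents whose gender is outside the
    published table are refused unless ``threshold_gender`` names which
    threshold row to apply.
    """
    screen = screen if screen is not None else default_screen()
    bank = bank if bank is not None else default_item_bank()
    g = threshold_gender if threshold_gender is not None else gender
    if g not in ("male", "female"):
        raise ThresholdingError(
            f"no published thresholds for gender {gender!r}; pass "
            "threshold_gender='male' or 'female' to choose a row explicitly")
    if informant not in ("adolescent", "parent"):
        raise ThresholdingError(f"unknown informant {informant!r}")

    anx = _subscore(responses, screen.anxiety_items, bank)
    dep = _subscore(responses, screen.depression_items, bank)
    total = anx + dep if anx is not None and dep is not None else UNDEFINED
    imp = _subscore(responses, screen.impact_items, bank)
    tpi = total + imp if total is not None and imp is not None else UNDEFINED

    def classify(score: int | None, scale: str) -> bool | None:
        if score is None:
            return None
        return bool(score >= screen.cutoff(informant, g, scale))

    dep_pos = classify(dep, "depression")
    return ScreenResult(
        person_id=person_id,
        informant=informant,
        gender_used=g,
        anxiety_score=anx,
        depression_score=dep,
        total_score=total,
        total_plus_impact_score=tpi,
        anxiety_positive=classify(anx, "anxiety"),
        depression_positive=dep_pos,
        total_positive=classify(total, "total"),
        total_plus_impact_positive=classify(tpi, "total_plus_impact"),
        risk_advisory=RISK_ADVISORY if dep_pos else None,
    )


def score_frame(
    data: ResponseMatrix,
    screen: ScreenDefinition | None = None,
    *,
    informant: str | None = None,
) -> list[ScreenResult]:
    """Score every row of a response matrix (optionally one informant)."""
    screen = screen if screen is not None else default_screen()
    frame = data.data if informant is None else data.informant_frame(informant)
    items = set(data.item_columns)
    results = []
    for _, row in frame.iterrows():
        responses = {c: row[c] for c in items}
        results.append(score_screen(
            responses, screen,
            gender=row["gender"], informant=row["informant"],
            person_id=row["person_id"], bank=data.bank,
        ))
    return results


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_CSV_META = {
    "person_id": "person_id", "dyad_id": "dyad_id", "informant": "informant",
    "group": "group", "anx_dx": "anx_dx", "dep_dx": "dep_dx",
    "gender": "gender", "age_group": "age_group",
}


def write_responses(data: ResponseMatrix, path: str | Path) -> None:
    """Write a cohort as CSV, one row per person x informant, blank = missing."""
    df = data.data.copy()
    df.to_csv(path, index=False)


def read_responses(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a response CSV back into a ResponseMatrix.

    Unknown item columns are preserved (and ignored by scoring); malformed
    values are reported with their row number and column.
    """
    bank = bank if bank is not None else default_item_bank()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    absent = [c for c in META_COLUMNS if c not in df.columns]
    if absent:
        raise FormatError(f"{path}: missing mandatory metadata columns {absent}")
    for col in ("anx_dx", "dep_dx"):
        df[col] = df[col].astype(bool)
    for item in bank:
        if item.item_id not in df.columns:
            continue
        col = pd.to_numeric(df[item.item_id], errors="coerce")
        bad = col.notna() & ((col < item.min_score) | (col > item.max_score))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based plus header
            raise FormatError(
                f"{path}: value {df.loc[bad, item.item_id].iloc[0]!r} out of "
                f"range for item {item.item_id} at line {row}")
        raw_bad = df[item.item_id].notna() & col.isna()
        if raw_bad.any():
            row = int(df.index[raw_bad][0]) + 2
            raise FormatError(
                f"{path}: non-numeric value for item {item.item_id} at line {row}")
        df[item.item_id] = col
    return ResponseMatrix(data=df, bank=bank)


def write_results(results: Sequence[ScreenResult], path: str | Path) -> None:
    """Write screen results as CSV or JSON (by file extension)."""
    path = Path(path)
    rows = [r.to_dict() for r in results]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
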