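"""Codification and scoring of the CAMDEX-DS Part 2 informant interview.

Part 2 of the CAMDEX-DS records cognitive and functional decline from a
person's best level of functioning across 54 items in four sections:
Section A (everyday skills, 7 items), Section B (memory and orientation,
11 items), Section C1 (other cognitive skills, 15 items) and Section C2
(personality, behaviour and self-care, 21 items).  Each item is codified
on a three-level ordinal scale -- 0 (no deterioration), 1 (slight
deterioration), 2 (great deterioration) -- giving section maxima of
14/22/30/42 and a total maximum of 108.  A high score indicates decline.

The default codification table carries placeholder item labels with the
correct section structure; the verbatim instrument text is copyrighted
and deliberately not reproduced.  A user-supplied table (CSV or JSON)
with real item identifiers can be loaded with :func:`load_codification`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Section(str, enum.Enum):
    """The four Part 2 sections."""

    A = "A"
    B = "B"
    C1 = "C1"
    C2 = "C2"


#: Number of items per section in the default codification.
SECTION_SIZES: dict[Section, int] = {
    Section.A: 7,
    Section.B: 11,
    Section.C1: 15,
    Section.C2: 21,
}

#: Maximum attainable score per section (two points per item).
SECTION_MAXIMA: dict[Section, int] = {s: 2 * n for s, n in SECTION_SIZES.items()}

TOTAL_MAXIMUM: int = sum(SECTION_MAXIMA.values())  # 108

VALID_RESPONSE_LEVELS = (0, 1, 2)

#: Diagnostic group labels, in order of expected severity.
DIAGNOSTIC_GROUPS = ("asymptomatic", "mentalhealth", "prodromal", "dementia")

SEX_LEVELS = ("female", "male")
ID_LEVELS = ("mild", "moderate", "severe")

#: Score columns produced by scoring, in reporting order.
SCORE_FIELDS = ("total", "section_a", "section_b", "section_c1", "section_c2")

_SECTION_FIELD = {
    Section.A: "section_a",
    Section.B: "section_b",
    Section.C1: "section_c1",
    Section.C2: "section_c2",
}

_SECTION_LABEL = {
    Section.A: "everyday skills",
    Section.B: "memory and orientation",
    Section.C1: "other cognitive skills",
    Section.C2: "personality, behaviour and self-care",
}


class CodificationError(ValueError):
    """Raised for an invalid codification table or threshold rule."""


class IncompleteInterviewError(ValueError):
    """Raised when a record lacks responses for required items."""

    def __init__(self, participant_id: str, missing: Sequence[str]):
        self.participant_id = participant_id
        self.missing = tuple(missing)
        super().__init__(
            f"incomplete interview for participant {participant_id!r}: "
            f"missing responses for items {', '.join(self.missing)}"
        )


class InvalidResponseError(ValueError):
    """Raised when a response is outside the scored 0/1/2 levels."""


@dataclass(frozen=True)
class ItemDefinition:
    """One scored interview item: identifier, section, free-text label."""

    item_id: str
    section: Section
    label: str = ""


def default_codification() -> list[ItemDefinition]:
    """Return the default 54-item codification table.

    Item identifiers are ``a01``..``a07``, ``b01``..``b11``,
    ``c1_01``..``c1_15`` and ``c2_01``..``c2_21``; labels are placeholders
    naming only the section content domain.
    """
    items: list[ItemDefinition] = []
    prefixes = {Section.A: "a", Section.B: "b", Section.C1: "c1_", Section.C2: "c2_"}
    for section, n in SECTION_SIZES.items():
        prefix = prefixes[section]
        for i in range(1, n + 1):
            items.append(
                ItemDefinition(
                    item_id=f"{prefix}{i:02d}",
                    section=section,
                    label=f"{_SECTION_LABEL[section]} item {i}",
                )
            )
    return items


def validate_codification(
    items: Sequence[ItemDefinition], require_default_shape: bool = False
) -> None:
    """Check uniqueness of item ids and, optionally, the 7/11/15/21 shape."""
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CodificationError(f"duplicate item_ids in codification: {dupes}")
    if require_default_shape:
        counts = {s: 0 for s in Section}
        for it in items:
            counts[Section(it.section)] += 1
        if counts != SECTION_SIZES:
            raise CodificationError(
                f"expected section cardinalities {SECTION_SIZES}, got {counts}"
            )


def load_codification(path: str | Path) -> list[ItemDefinition]:
    """Load a codification table from CSV or JSON.

    CSV needs columns ``item_id``, ``section``, ``label`` (label optional);
    JSON is a list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        rows = [(r["item_id"], r["section"], r.get("label", "")) for r in raw]
    else:
        df = pd.read_csv(path, dtype=str).fillna("")
        for col in ("item_id", "section"):
            if col not in df.columns:
                raise CodificationError(f"codification table lacks column {col!r}")
        if "label" not in df.columns:
            df["label"] = ""
        rows = list(df[["item_id", "section", "label"]].itertuples(index=False))
    try:
        items = [ItemDefinition(i, Section(s), lbl) for i, s, lbl in rows]
    except ValueError as exc:
        raise CodificationError(f"invalid section in codification table: {exc}") from exc
    validate_codification(items)
    return items


@dataclass
class InterviewRecord:
    """One participant: demographics, diagnostic label and item responses."""

    participant_id: str
    age: int
    sex: str
    id_level: str
    mental_health_flag: bool
    diagnostic_group: str
    responses: dict[str, int] = field(default_factory=dict)

    def validate(self, age_range: tuple[int, int] = (18, 80)) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValueError(
                f"participant {self.participant_id!r}: sex must be one of "
                f"{SEX_LEVELS}, got {self.sex!r}"
            )
        if self.id_level not in ID_LEVELS:
            raise ValueError(
                f"participant {self.participant_id!r}: id_level must be one of "
                f"{ID_LEVELS}, got {self.id_level!r}"
            )
        if self.diagnostic_group not in DIAGNOSTIC_GROUPS:
            raise ValueError(
                f"participant {self.participant_id!r}: diagnostic_group must be "
                f"one of {DIAGNOSTIC_GROUPS}, got {self.diagnostic_group!r}"
            )
        lo, hi = age_range
        if not lo <= self.age <= hi:
            raise ValueError(
                f"participant {self.participant_id!r}: age {self.age} outside "
                f"plausible range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class ScoreProfile:
    """Section subscores and total for one interview.

    Invariant: ``total`` equals the sum of the four subscores and every
    subscore stays within its printed maximum (14/22/30/42; total 108).
    """

    section_a: int
    section_b: int
    section_c1: int
    section_c2: int
    total: int

    def __post_init__(self) -> None:
        parts = (self.section_a, self.section_b, self.section_c1, self.section_c2)
        if self.total != sum(parts):
            raise ValueError(
                f"total {self.total} != sum of subscores {sum(parts)}"
            )
        maxima = [SECTION_MAXIMA[s] for s in (Section.A, Section.B, Section.C1, Section.C2)]
        for value, cap, name in zip(parts, maxima, ("A", "B", "C1", "C2")):
            if not 0 <= value <= cap:
                raise ValueError(f"section {name} score {value} outside [0, {cap}]")

    @classmethod
    def from_sections(cls, a: int, b: int, c1: int, c2: int) -> "ScoreProfile":
        return cls(a, b, c1, c2, a + b + c1 + c2)

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "section_a": self.section_a,
            "section_b": self.section_b,
            "section_c1": self.section_c1,
            "section_c2": self.section_c2,
        }

    def __getitem__(self, score_field: str) -> int:
        d = self.as_dict()
        if score_field not in d:
            raise CodificationError(
                f"unknown score field {score_field!r}; expected one of {SCORE_FIELDS}"
            )
        return d[score_field]


def score_interview(
    record: InterviewRecord,
    codification: Sequence[ItemDefinition] | None = None,
    missing_policy: str = "error",
) -> ScoreProfile:
    """Score one interview against a codification table.

    Subscores are sums of the 0/1/2 response levels within each section;
    the total is the sum of the subscores.

    Parameters
    ----------
    record
        The participant's interview record.
    codification
        Item table; defaults to the built-in 54-item table.
    missing_policy
        ``"error"`` (default) raises :class:`IncompleteInterviewError` on
        any missing item; ``"zero"`` scores missing items as 0 (no
        deterioration).  No other imputation is offered.
    """
    if codification is None:
        codification = default_codification()
    if missing_policy not in ("error", "zero"):
        raise ValueError(f"missing_policy must be 'error' or 'zero', got {missing_policy!r}")
    missing = [it.item_id for it in codification if it.item_id not in record.responses]
    if missing and missing_policy == "error":
        raise IncompleteInterviewError(record.participant_id, missing)
    sums = {s: 0 for s in Section}
    for it in codification:
        value = record.responses.get(it.item_id, 0)
        if value not in VALID_RESPONSE_LEVELS:
            raise InvalidResponseError(
                f"participant {record.participant_id!r}, item {it.item_id!r}: "
                f"response {value!r} is not a valid level (0, 1 or 2)"
            )
        sums[Section(it.section)] += value
    return ScoreProfile.from_sections(
        sums[Section.A], sums[Section.B], sums[Section.C1], sums[Section.C2]
    )


@dataclass(frozen=True)
class ThresholdRule:
    """A diagnostic cut-off: ``score_field`` strictly greater than ``cutoff``.

    The strict ">" convention matches the half-integer cut-offs the method
    derives (e.g. total > 7.5); on integer scores it is equivalent to
    ">= next integer" (total >= 8).
    """

    score_field: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.score_field not in SCORE_FIELDS:
            raise CodificationError(
                f"unknown score field {self.score_field!r}; expected one of {SCORE_FIELDS}"
            )


def classify_by_threshold(profile: ScoreProfile, rule: ThresholdRule) -> str:
    """Return ``"positive"`` iff the selected score strictly exceeds the cut-off."""
    return "positive" if profile[rule.score_field] > rule.cutoff else "negative"


# ---------------------------------------------------------------------------
# Cohort I/O

_DEMOGRAPHIC_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "id_level",
    "mental_health_flag",
    "diagnostic_group",
)


def records_to_frame(
    records: Iterable[InterviewRecord],
    codification: Sequence[ItemDefinition] | None = None,
) -> pd.DataFrame:
    """One row per participant: demographics then one column per item."""
    if codification is None:
        codification = default_codification()
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "age": r.age,
            "sex": r.sex,
            "id_level": r.id_level,
            "mental_health_flag": r.mental_health_flag,
            "diagnostic_group": r.diagnostic_group,
        }
        for it in codification:
            row[it.item_id] = r.responses.get(it.item_id, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(
    records: Iterable[InterviewRecord],
    path: str | Path,
    codification: Sequence[ItemDefinition] | None = None,
) -> None:
    records_to_frame(records, codification).to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
    codification: Sequence[ItemDefinition] | None = None,
    age_range: tuple[int, int] = (18, 80),
) -> list[InterviewRecord]:
    """Read a cohort CSV and validate every record.

    Expected columns: participant_id, age, sex, id_level,
    mental_health_flag, diagnostic_group, then one column per item_id with
    values 0/1/2.  Schema violations are reported with row and column.
    """
    if codification is None:
        codification = default_codification()
    df = pd.read_csv(path)
    problems = []
    for col in _DEMOGRAPHIC_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        raise ValueError(f"cohort CSV {path}: " + "; ".join(problems))
    item_ids = [it.item_id for it in codification]
    records = []
    for idx, row in df.iterrows():
        responses: dict[str, int] = {}
        for item_id in item_ids:
            if item_id not in df.columns or pd.isna(row[item_id]):
                continue
            value = row[item_id]
            try:
                value = int(value)
            except (TypeError, ValueError):
                problems.append(f"row {idx}, column {item_id!r}: non-integer response {value!r}")
                continue
            if value not in VALID_RESPONSE_LEVELS:
                problems.append(f"row {idx}, column {item_id!r}: response {value} not in 0/1/2")
                continue
            responses[item_id] = value
        mh = row["mental_health_flag"]
        if isinstance(mh, str):
            mh = mh.strip().lower() in ("true", "1", "yes")
        record = InterviewRecord(
            participant_id=str(row["participant_id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            id_level=str(row["id_level"]),
            mental_health_flag=bool(mh),
            diagnostic_group=str(row["diagnostic_group"]),
            responses=responses,
        )
        try:
            record.validate(age_range=age_range)
        except ValueError as exc:
            problems.append(f"row {idx}: {exc}")
        records.append(record)
    if problems:
        raise ValueError(f"cohort CSV {path}: " + "; ".join(problems))
    return records


def score_cohort(
    records: Sequence[InterviewRecord],
    codification: Sequence[ItemDefinition] | None = None,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Score every record; returns demographics plus the five score columns."""
    rows = []
    for r in records:
        profile = score_interview(r, codification, missing_policy=missing_policy)
        rows.append(
            {
                "participant_id": r.participant_id,
                "age": r.age,
                "sex": r.sex,
                "id_level": r.id_level,
                "mental_health_flag": r.mental_health_flag,
                "diagnostic_group": r.diagnostic_group,
                **profile.as_dict(),
            }
        )
    return pd.DataFrame(rows)
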