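"""Survey instrument definition and response-table ingestion.

The Subjective Evidence Evaluation Survey (SEES) asks each analysis team in
a many-analysts study to rate, on a 4-point Likert scale, the subjective
evidence for the hypothesis (8 items) and the methodological appropriateness
of the study (10 items), plus one pre-analysis prior-plausibility item.
Every scored item offers a "not applicable/I do not know" escape option.

This module loads the packaged (or a user-supplied) instrument schema,
validates it, and recodes raw label responses into integer matrices ready
for the consensus model: categories run 1..C with C always the most
favourable endorsement, counter-indicative items are reverse-coded
(``x -> C+1-x``), and NA responses become missing values.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurveyItem",
    "Instrument",
    "ResponseTable",
    "ValidationReport",
    "SchemaError",
    "RecodeError",
    "load_instrument",
    "recode_responses",
    "validate_responses",
    "read_response_csv",
]

SUBSCALES = ("prior", "subjective_evidence", "methodological_appropriateness")

#: id prefix expected for each subscale
_PREFIX = {
    "prior": "PRIOR",
    "subjective_evidence": "SE",
    "methodological_appropriateness": "MA",
}

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


class SchemaError(ValueError):
    """Raised when an instrument definition violates the schema."""


class RecodeError(ValueError):
    """Raised when a raw response cannot be mapped to a category code."""


def _normalize_label(label: str) -> str:
    """Lowercase, strip punctuation and collapse whitespace.

    Tolerates export dialects ("Yes, definitely", "yes definitely ").
    """
    s = str(label).lower().translate(_PUNCT_TABLE)
    return re.sub(r"\s+", " ", s).strip()


@dataclass(frozen=True)
class SurveyItem:
    """A single survey item.

    ``response_labels`` are ordered from the least to the most favourable
    endorsement *as presented to the respondent*; for counter-indicative
    (``reverse_coded``) items the numeric code is flipped on ingest so that
    higher always means stronger belief / fewer concerns.
    """

    id: str
    subscale: str
    label: str
    text: str
    example: str
    reverse_coded: bool
    allows_na: bool
    response_labels: tuple[str, ...]

    @property
    def n_categories(self) -> int:
        return len(self.response_labels)

    def coded_labels(self) -> tuple[str, ...]:
        """Response labels in coded (post-reversal) order, low -> high."""
        if self.reverse_coded:
            return tuple(reversed(self.response_labels))
        return self.response_labels


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of survey items sharing C response categories."""

    items: tuple[SurveyItem, ...]
    C: int = 4
    name: str = "SEES"
    na_label: str = "not applicable/I do not know"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.id in seen:
                raise SchemaError(f"duplicate item id {it.id!r}")
            seen.add(it.id)
            if it.subscale not in SUBSCALES:
                raise SchemaError(
                    f"item {it.id!r}: unknown subscale {it.subscale!r}"
                )
            if not it.id.startswith(_PREFIX[it.subscale]):
                raise SchemaError(
                    f"item {it.id!r}: id prefix inconsistent with subscale "
                    f"{it.subscale!r}"
                )
            if it.n_categories != self.C:
                raise SchemaError(
                    f"item {it.id!r}: {it.n_categories} response labels, "
                    f"expected C={self.C}"
                )

    def __iter__(self) -> Iterable[SurveyItem]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> SurveyItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def subscale_items(self, subscale: str) -> list[SurveyItem]:
        if subscale not in SUBSCALES:
            raise KeyError(f"unknown subscale {subscale!r}")
        return [it for it in self.items if it.subscale == subscale]

    @property
    def scored_items(self) -> list[SurveyItem]:
        """All items except the pre-analysis prior-belief item."""
        return [it for it in self.items if it.subscale != "prior"]

    @property
    def reverse_coded_ids(self) -> set[str]:
        return {it.id for it in self.items if it.reverse_coded}


@dataclass
class ResponseTable:
    """Teams x items matrix of ordinal codes with explicit missingness.

    ``values`` is a float matrix holding integer codes in ``1..C`` or NaN
    for a not-applicable / missing response. ``reversed_applied`` records
    that counter-indicative items have been flipped exactly once; the
    consensus model requires it.
    """

    team_ids: list[str]
    item_ids: list[str]
    values: np.ndarray
    C: int = 4
    reversed_applied: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.team_ids), len(self.item_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.team_ids)} teams x {len(self.item_ids)} items"
            )
        # well-formed tables hold integer codes in [1, C]; screening for
        # violations is validate_responses' job, so construction stays lenient

    @property
    def n_teams(self) -> int:
        return len(self.team_ids)

    @property
    def na_counts(self) -> dict[str, int]:
        """Per-item count of missing (NA) cells."""
        miss = np.isnan(self.values).sum(axis=0)
        return {iid: int(m) for iid, m in zip(self.item_ids, miss)}

    def subset(self, item_ids: Sequence[str]) -> "ResponseTable":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseTable(
            team_ids=list(self.team_ids),
            item_ids=list(item_ids),
            values=self.values[:, idx].copy(),
            C=self.C,
            reversed_applied=self.reversed_applied,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids).astype("Int64")
        df.insert(0, "team_id", self.team_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_responses`; reporting only, never raises."""

    range_violations: list[tuple[str, str, float]] = field(default_factory=list)
    all_missing_items: list[str] = field(default_factory=list)
    all_missing_teams: list[str] = field(default_factory=list)
    na_fraction: dict[str, float] = field(default_factory=dict)
    high_na_items: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.range_violations
            or self.all_missing_items
            or self.all_missing_teams
        )


def _items_from_mapping(raw: dict) -> Instrument:
    try:
        c = int(raw.get("categories", 4))
        items = tuple(
            SurveyItem(
                id=str(d["id"]),
                subscale=str(d["subscale"]),
                label=str(d.get("label", d["id"])),
                text=str(d.get("text", "")).strip(),
                example=str(d.get("example", "")).strip(),
                reverse_coded=bool(d.get("reverse_coded", False)),
                allows_na=bool(d.get("allows_na", True)),
                response_labels=tuple(d["response_labels"]),
            )
            for d in raw["items"]
        )
    except KeyError as exc:  # missing mandatory field
        raise SchemaError(f"instrument definition missing field {exc}") from exc
    return Instrument(
        items=items,
        C=c,
        name=str(raw.get("name", "instrument")),
        na_label=str(raw.get("na_label", "not applicable/I do not know")),
    )


def load_instrument(path: str | Path | None = None) -> Instrument:
    """Load and validate an instrument definition.

    With ``path=None`` the packaged SEES is returned: 18 scored items
    (8 subjective-evidence, of which SE_4..SE_7 are reverse-coded, and 10
    methodological-appropriateness) plus the prior-plausibility item.
    User files may be YAML or JSON (JSON is a YAML subset).
    """
    if path is None:
        src = resources.files("sees.data").joinpath("sees.yaml")
        raw = yaml.safe_load(src.read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "items" not in raw:
        raise SchemaError("instrument definition must be a mapping with 'items'")
    return _items_from_mapping(raw)


def _code_one(cell, item: SurveyItem, na_norm: str, label_map: dict[str, int],
              C: int) -> tuple[float, bool]:
    """Map one raw cell to ``(code, from_label)``.

    ``code`` is in 1..C or NaN; ``from_label`` marks cells decoded from a
    response label, which still need reverse coding. Integer input is
    accepted as an *already-coded* value and is never re-reversed.
    """
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan, False
    if isinstance(cell, (int, np.integer)) or (
        isinstance(cell, float) and float(cell).is_integer()
    ):
        code = int(cell)
        if 1 <= code <= C:
            return code, False
        raise RecodeError(
            f"integer code {code} out of range 1..{C} for item {item.id}"
        )
    # numeric strings ("3", "3.0") are already-coded values
    try:
        f = float(cell)
    except (TypeError, ValueError):
        pass
    else:
        if np.isnan(f):
            return np.nan, False
        if f.is_integer() and 1 <= int(f) <= C:
            return int(f), False
        raise RecodeError(
            f"numeric code {cell!r} out of range 1..{C} for item {item.id}"
        )
    norm = _normalize_label(cell)
    if norm == "" or norm == na_norm:
        return np.nan, False
    if norm in label_map:
        return label_map[norm], True
    # numeric strings ("3")
    try:
        code = int(norm)
    except ValueError:
        raise RecodeError(
            f"unrecognized label {cell!r} for item {item.id}"
        ) from None
    if 1 <= code <= C:
        return code, False
    raise RecodeError(f"integer code {code} out of range 1..{C} for item {item.id}")


def recode_responses(raw: pd.DataFrame, instrument: Instrument) -> ResponseTable:
    """Turn a wide label table into a model-ready :class:`ResponseTable`.

    ``raw`` holds one row per team; the first column (or the index, if the
    first column is not named ``team_id``) identifies the team and the
    remaining columns are item ids. Cells may contain response labels
    (matched case/punctuation-insensitively), integer codes already in
    ``1..C``, the NA label, or empty values. Counter-indicative items are
    reverse-coded here, exactly once.
    """
    df = raw.copy()
    if df.columns[0].lower() in ("team_id", "team", "id"):
        team_ids = [str(t) for t in df.iloc[:, 0]]
        df = df.iloc[:, 1:]
    else:
        team_ids = [str(t) for t in df.index]

    known = set(instrument.item_ids)
    item_ids = [c for c in df.columns if c in known]
    unknown = [c for c in df.columns if c not in known]
    if not item_ids:
        raise RecodeError("no columns match the instrument's item ids")
    if unknown:
        # silently retained out of the matrix; validate_responses reports shape
        pass

    na_norm = _normalize_label(instrument.na_label)
    C = instrument.C
    values = np.full((len(team_ids), len(item_ids)), np.nan)
    for j, iid in enumerate(item_ids):
        item = instrument[iid]
        label_map = {
            _normalize_label(lab): k + 1
            for k, lab in enumerate(item.response_labels)
        }
        for i, cell in enumerate(df[iid]):
            try:
                code, from_label = _code_one(cell, item, na_norm, label_map, C)
            except RecodeError as exc:
                raise RecodeError(
                    f"row {i} (team {team_ids[i]}), column {iid}: {exc}"
                ) from None
            if from_label and item.reverse_coded and not np.isnan(code):
                code = C + 1 - code
            values[i, j] = code
    return ResponseTable(
        team_ids=team_ids, item_ids=item_ids, values=values, C=C,
        reversed_applied=True,
    )


def read_response_csv(path: str | Path, instrument: Instrument) -> ResponseTable:
    """Read a wide-format response CSV (first column team id) and recode it."""
    raw = pd.read_csv(path, dtype=object)
    return recode_responses(raw, instrument)


def validate_responses(
    table: ResponseTable,
    instrument: Instrument,
    high_na_threshold: float = 0.5,
) -> ValidationReport:
    """Screen a response table; returns a report and never raises.

    Flags out-of-range codes, all-missing rows/columns and items whose NA
    fraction exceeds ``high_na_threshold`` (items with mostly-NA responses
    yield very uncertain consensus estimates and deserve attention before
    modelling).
    """
    report = ValidationReport()
    vals = table.values
    C = instrument.C
    for i, tid in enumerate(table.team_ids):
        row = vals[i]
        if np.all(np.isnan(row)):
            report.all_missing_teams.append(tid)
    n = table.n_teams
    for j, iid in enumerate(table.item_ids):
        col = vals[:, j]
        bad = np.isfinite(col) & ((col < 1) | (col > C) | (col != np.round(col)))
        for i in np.flatnonzero(bad):
            report.range_violations.append((table.team_ids[i], iid, col[i]))
        n_missing = int(np.isnan(col).sum())
        frac = n_missing / n if n else float("nan")
        report.na_fraction[iid] = frac
        if n_missing == n:
            report.all_missing_items.append(iid)
        if frac > high_na_threshold:
            report.high_na_items.append(iid)
    return report
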