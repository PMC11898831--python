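"""Set-valued rater panels and the slash-notation codec.

A *panel* is a cases × raters grid in which every cell is a
:class:`Recommendation`: an ordered, duplicate-free list of management-option
codes written in slash notation (``"1/2/4"``). The first-listed code is the
rater's *primary* option; the unordered view of the cell is its *option set*.
Raters are partitioned into a *candidate* roster (the systems under
evaluation) and a *reference* roster (the expert standard).

Panels are read from and written to plain delimited text (CSV or TSV) with a
header row naming a case-id column and one column per rater.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .options import VALID_CODES, OptionCode, get_option


class PanelError(ValueError):
    """A structural problem with a panel or one of its cells."""


class RecommendationParseError(PanelError):
    """A cell could not be parsed as slash-notation codes."""


@dataclass(frozen=True)
class Recommendation:
    """An ordered, duplicate-free sequence of option codes; first = primary."""

    options: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.options:
            raise PanelError("a recommendation must contain at least one option")
        if len(set(self.options)) != len(self.options):
            raise PanelError(
                f"duplicate option codes in recommendation {self.options!r}"
            )
        for code in self.options:
            if code not in VALID_CODES:
                raise PanelError(
                    f"option code {code!r} outside the valid range 1..11"
                )

    @property
    def primary(self) -> int:
        """The first-listed option code."""
        return self.options[0]

    @property
    def option_set(self) -> frozenset[int]:
        """Unordered view of the recommended options."""
        return frozenset(self.options)

    @property
    def option_codes(self) -> tuple[OptionCode, ...]:
        return tuple(get_option(c) for c in self.options)

    def __len__(self) -> int:
        return len(self.options)

    def __str__(self) -> str:
        return "/".join(str(c) for c in self.options)


def parse_recommendation(text: str, context: str = "") -> Recommendation:
    """Parse a slash-delimited code string such as ``"1/2/4"``.

    Order is preserved, so the primary (first-listed) option is recoverable.
    ``context`` (e.g. ``"case 3, rater gemini"``) is included in error
    messages to locate the offending cell.
    """
    where = f" ({context})" if context else ""
    if text is None or not str(text).strip():
        raise RecommendationParseError(f"blank recommendation cell{where}")
    tokens = [t.strip() for t in str(text).strip().split("/")]
    codes: list[int] = []
    for tok in tokens:
        if not tok:
            raise RecommendationParseError(
                f"empty token in recommendation {text!r}{where}"
            )
        try:
            code = int(tok)
        except ValueError:
            raise RecommendationParseError(
                f"non-integer token {tok!r} in recommendation {text!r}{where}"
            ) from None
        codes.append(code)
    try:
        return Recommendation(tuple(codes))
    except PanelError as exc:
        raise RecommendationParseError(f"{exc}{where}") from None


@dataclass(frozen=True)
class CaseRecord:
    """One clinical case with its full set of ratings."""

    case_id: int
    ratings: Mapping[str, Recommendation]
    description: str | None = None

    def recommendation(self, rater_id: str) -> Recommendation:
        try:
            return self.ratings[rater_id]
        except KeyError:
            raise PanelError(
                f"case {self.case_id} has no rating from {rater_id!r}"
            ) from None


@dataclass(frozen=True)
class Panel:
    """Cases × raters grid of set-valued ratings with a two-part roster.

    Invariants enforced on construction: case ids are unique, the candidate
    and reference rosters are disjoint, and every case carries exactly one
    rating for every rostered rater (no more, no fewer).
    """

    cases: tuple[CaseRecord, ...]
    candidate_raters: tuple[str, ...]
    reference_raters: tuple[str, ...]
    display_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        object.__setattr__(self, "candidate_raters", tuple(self.candidate_raters))
        object.__setattr__(self, "reference_raters", tuple(self.reference_raters))
        overlap = set(self.candidate_raters) & set(self.reference_raters)
        if overlap:
            raise PanelError(f"raters in both rosters: {sorted(overlap)}")
        roster = set(self.raters)
        if len(roster) != len(self.raters):
            raise PanelError("duplicate rater ids in roster")
        seen_ids: set[int] = set()
        for case in self.cases:
            if case.case_id in seen_ids:
                raise PanelError(f"duplicate case id {case.case_id}")
            seen_ids.add(case.case_id)
            keys = set(case.ratings)
            if keys != roster:
                missing = sorted(roster - keys)
                extra = sorted(keys - roster)
                detail = []
                if missing:
                    detail.append(f"missing ratings from {missing}")
                if extra:
                    detail.append(f"unrostered ratings from {extra}")
                raise PanelError(f"case {case.case_id}: " + "; ".join(detail))

    @property
    def raters(self) -> tuple[str, ...]:
        return self.candidate_raters + self.reference_raters

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def case_ids(self) -> tuple[int, ...]:
        return tuple(c.case_id for c in self.cases)

    def case(self, case_id: int) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise PanelError(f"no case with id {case_id}")

    def column(self, rater_id: str) -> list[Recommendation]:
        """All of one rater's recommendations, in case order."""
        if rater_id not in self.raters:
            raise PanelError(f"unknown rater id {rater_id!r}")
        return [c.ratings[rater_id] for c in self.cases]

    def display_name(self, rater_id: str) -> str:
        return dict(self.display_names).get(rater_id, rater_id)

    def to_frame(self, include_descriptions: bool = False) -> pd.DataFrame:
        """Slash-notation string grid, one row per case, one column per rater."""
        data: dict[str, list] = {"case": list(self.case_ids)}
        if include_descriptions:
            data["description"] = [c.description or "" for c in self.cases]
        for rater in self.raters:
            data[rater] = [str(c.ratings[rater]) for c in self.cases]
        return pd.DataFrame(data)

    def to_csv(self, path_or_buf=None, sep: str = ",") -> str | None:
        return self.to_frame().to_csv(path_or_buf, sep=sep, index=False)


def load_panel(
    source,
    candidate_raters: Sequence[str],
    reference_raters: Sequence[str],
    *,
    sep: str | None = None,
    case_column: str = "case",
    description_column: str | None = None,
) -> Panel:
    """Load a panel from delimited text (path, file object, or literal string).

    The header must name ``case_column`` and one column per rostered rater.
    ``sep=None`` sniffs comma vs tab. Errors name the offending row/column.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(
        source, sep=sep, engine="python", dtype=str, keep_default_na=False
    )
    if case_column not in df.columns:
        raise PanelError(f"missing case-id column {case_column!r}")
    roster = list(candidate_raters) + list(reference_raters)
    for rater in roster:
        if rater not in df.columns:
            raise PanelError(f"missing rater column {rater!r}")
    cases: list[CaseRecord] = []
    for row_idx, row in df.iterrows():
        raw_id = str(row[case_column]).strip()
        try:
            case_id = int(raw_id)
        except ValueError:
            raise PanelError(
                f"row {row_idx + 1}: case id {raw_id!r} is not an integer"
            ) from None
        ratings = {
            rater: parse_recommendation(
                row[rater], context=f"case {case_id}, rater {rater}"
            )
            for rater in roster
        }
        description = None
        if description_column is not None and description_column in df.columns:
            description = str(row[description_column]) or None
        cases.append(CaseRecord(case_id, ratings, description))
    return Panel(tuple(cases), tuple(candidate_raters), tuple(reference_raters))
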