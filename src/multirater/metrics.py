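"""Set-overlap concordance primitives.

All proportions are carried as exact rationals (numerator over the number of
cases, or the stratum size) and converted to floats or display percentages
only at the edge. The core rule set:

* **union accuracy** — a candidate scores a hit on a case when its option
  set shares at least one code with the *union* of the reference raters'
  option sets for that case;
* **reference agreement** — same overlap test against a single reference
  rater's set (``rule="intersection"``); set equality and coverage of the
  reference's primary option are available as sensitivity variants;
* **precision/recall/F1** — per-case set precision and recall of the
  candidate set against the reference union, macro-averaged over cases;
* **consensus stratification** — cases split by whether the reference
  raters were unanimous, under an explicit unanimity definition;
* **overlap agreement matrix** — for rater pairs, the fraction of cases
  whose option sets intersect.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .panel import CaseRecord, Panel, PanelError, Recommendation

AGREEMENT_RULES = ("intersection", "equality", "primary")
CONSENSUS_DEFINITIONS = ("strict_set", "primary_match", "any_pairwise_overlap")


@dataclass(frozen=True)
class Proportion:
    """An exact count-over-total proportion."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    def display(self, digits: int = 1) -> str:
        """Percentage rounded for display, e.g. ``'81.8'``."""
        return f"{self.percent:.{digits}f}"

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def union_reference(
    case: CaseRecord, reference_raters: Sequence[str]
) -> frozenset[int]:
    """Union of the reference raters' option sets for one case."""
    if not reference_raters:
        raise PanelError("reference roster is empty")
    out: set[int] = set()
    for rater in reference_raters:
        out |= case.recommendation(rater).option_set
    return frozenset(out)


def case_hit(candidate: Recommendation, reference_set: frozenset[int]) -> bool:
    """True iff the candidate's option set intersects ``reference_set``."""
    return bool(candidate.option_set & reference_set)


def union_accuracy(panel: Panel, candidate_rater: str) -> Proportion:
    """Fraction of cases where the candidate overlaps the reference union."""
    column = panel.column(candidate_rater)
    hits = sum(
        case_hit(rec, union_reference(case, panel.reference_raters))
        for rec, case in zip(column, panel.cases)
    )
    return Proportion(hits, panel.n_cases)


def _agrees(candidate: Recommendation, reference: Recommendation, rule: str) -> bool:
    if rule == "intersection":
        return bool(candidate.option_set & reference.option_set)
    if rule == "equality":
        return candidate.option_set == reference.option_set
    if rule == "primary":
        # candidate covers the reference rater's leading choice
        return reference.primary in candidate.option_set
    raise ValueError(f"unknown agreement rule {rule!r}; choose from {AGREEMENT_RULES}")


def reference_agreement(
    panel: Panel,
    candidate_rater: str,
    reference_rater: str,
    rule: str = "intersection",
) -> Proportion:
    """Fraction of cases where the candidate agrees with one reference rater.

    The default ``intersection`` rule counts a case when the two option sets
    share at least one code.
    """
    cand = panel.column(candidate_rater)
    ref = panel.column(reference_rater)
    hits = sum(_agrees(c, r, rule) for c, r in zip(cand, ref))
    return Proportion(hits, panel.n_cases)


def mean_options_count(panel: Panel, rater: str) -> Fraction:
    """Mean number of options recommended per case, as an exact rational."""
    column = panel.column(rater)
    return Fraction(sum(len(rec) for rec in column), panel.n_cases)


def case_prf(
    candidate: Recommendation, reference_set: frozenset[int]
) -> tuple[Fraction, Fraction, Fraction]:
    """Set precision, recall and F1 of one recommendation against a reference.

    Precision = |∩| / |candidate|, recall = |∩| / |reference|, F1 their
    harmonic mean (0 when both are 0, so a disjoint pair scores (0, 0, 0)).
    """
    if not reference_set:
        raise PanelError("reference set is empty")
    inter = len(candidate.option_set & reference_set)
    precision = Fraction(inter, len(candidate.option_set))
    recall = Fraction(inter, len(reference_set))
    if precision + recall == 0:
        f1 = Fraction(0)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def macro_prf(
    panel: Panel, candidate_rater: str, *, average: str = "macro"
) -> tuple[Fraction, Fraction, Fraction]:
    """Precision/recall/F1 of a candidate against the per-case reference union.

    ``macro`` (default) takes the unweighted mean of the per-case values;
    ``micro`` pools intersection and set sizes over cases before dividing.
    """
    column = panel.column(candidate_rater)
    unions = [union_reference(case, panel.reference_raters) for case in panel.cases]
    if average == "macro":
        n = panel.n_cases
        triples = [case_prf(rec, u) for rec, u in zip(column, unions)]
        precision = sum(t[0] for t in triples) / n
        recall = sum(t[1] for t in triples) / n
        f1 = sum(t[2] for t in triples) / n
        return precision, recall, f1
    if average == "micro":
        inter = sum(len(rec.option_set & u) for rec, u in zip(column, unions))
        n_cand = sum(len(rec.option_set) for rec in column)
        n_ref = sum(len(u) for u in unions)
        precision = Fraction(inter, n_cand)
        recall = Fraction(inter, n_ref)
        f1 = (
            Fraction(0)
            if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        return precision, recall, f1
    raise ValueError(f"unknown averaging mode {average!r}; choose macro or micro")


def per_case_detail(panel: Panel, candidate_rater: str) -> pd.DataFrame:
    """Per-case hit flags, intersection sizes and P/R/F1 for one candidate."""
    rows = []
    for case, rec in zip(panel.cases, panel.column(candidate_rater)):
        u = union_reference(case, panel.reference_raters)
        p, r, f = case_prf(rec, u)
        rows.append(
            {
                "case": case.case_id,
                "recommendation": str(rec),
                "reference_union": "/".join(str(c) for c in sorted(u)),
                "hit": case_hit(rec, u),
                "intersection_size": len(rec.option_set & u),
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
            }
        )
    return pd.DataFrame(rows)


def _unanimous(case: CaseRecord, reference_raters: Sequence[str], definition: str) -> bool:
    recs = [case.recommendation(r) for r in reference_raters]
    if definition == "strict_set":
        return all(r.option_set == recs[0].option_set for r in recs[1:])
    if definition == "primary_match":
        return all(r.primary == recs[0].primary for r in recs[1:])
    if definition == "any_pairwise_overlap":
        return all(
            bool(a.option_set & b.option_set)
            for i, a in enumerate(recs)
            for b in recs[i + 1 :]
        )
    raise ValueError(
        f"unknown consensus definition {definition!r}; choose from {CONSENSUS_DEFINITIONS}"
    )


@dataclass(frozen=True)
class ConsensusStratification:
    """Cases partitioned by reference-rater unanimity, with per-stratum accuracy."""

    definition: str
    unanimous_case_ids: tuple[int, ...]
    non_unanimous_case_ids: tuple[int, ...]
    #: candidate -> {"unanimous": Proportion | None, "non_unanimous": ...}
    accuracy: dict[str, dict[str, Proportion | None]]


def stratify_by_consensus(
    panel: Panel, definition: str = "strict_set"
) -> ConsensusStratification:
    """Split cases by reference unanimity and score each candidate per stratum.

    Accuracy within a stratum is the union-hit rate restricted to its cases;
    an empty stratum yields ``None`` rather than a 0/0 proportion.
    """
    unanimous: list[CaseRecord] = []
    divided: list[CaseRecord] = []
    for case in panel.cases:
        (unanimous if _unanimous(case, panel.reference_raters, definition) else divided).append(case)

    def stratum_accuracy(cases: list[CaseRecord], candidate: str) -> Proportion | None:
        if not cases:
            return None
        hits = sum(
            case_hit(
                case.recommendation(candidate),
                union_reference(case, panel.reference_raters),
            )
            for case in cases
        )
        return Proportion(hits, len(cases))

    accuracy = {
        candidate: {
            "unanimous": stratum_accuracy(unanimous, candidate),
            "non_unanimous": stratum_accuracy(divided, candidate),
        }
        for candidate in panel.candidate_raters
    }
    return ConsensusStratification(
        definition,
        tuple(c.case_id for c in unanimous),
        tuple(c.case_id for c in divided),
        accuracy,
    )


@dataclass(frozen=True)
class OverlapAgreementMatrix:
    """Symmetric pairwise fraction of cases with intersecting option sets."""

    raters: tuple[str, ...]
    values: dict[frozenset[str], Proportion]
    n_cases: int

    def get(self, rater_a: str, rater_b: str) -> Proportion:
        if rater_a == rater_b:
            return Proportion(self.n_cases, self.n_cases)
        return self.values[frozenset((rater_a, rater_b))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.get(a, b).value for b in self.raters] for a in self.raters],
            index=list(self.raters),
            columns=list(self.raters),
        )

    def pairs(self) -> list[tuple[str, str, Proportion]]:
        out = []
        for i, a in enumerate(self.raters):
            for b in self.raters[i + 1 :]:
                out.append((a, b, self.get(a, b)))
        return out


def overlap_agreement_matrix(
    panel: Panel, raters: Sequence[str] | None = None
) -> OverlapAgreementMatrix:
    """Pairwise share-at-least-one-option agreement among ``raters``.

    Defaults to the candidate roster (inter-candidate agreement).
    """
    raters = tuple(raters if raters is not None else panel.candidate_raters)
    if len(raters) < 2:
        raise PanelError("overlap agreement needs at least 2 raters")
    columns = {r: panel.column(r) for r in raters}
    values: dict[frozenset[str], Proportion] = {}
    for i, a in enumerate(raters):
        for b in raters[i + 1 :]:
            hits = sum(
                bool(x.option_set & y.option_set)
                for x, y in zip(columns[a], columns[b])
            )
            values[frozenset((a, b))] = Proportion(hits, panel.n_cases)
    return OverlapAgreementMatrix(raters, values, panel.n_cases)
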