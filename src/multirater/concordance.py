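"""Concordance analysis of candidate raters against a reference roster.

`ConcordanceModel` is the statsmodels-style front door: construct it from a
:class:`~multirater.panel.Panel` (or a DataFrame of slash-notation strings),
call :meth:`~ConcordanceModel.fit`, and read the estimates off the returned
:class:`ConcordanceResults` — per-candidate union accuracy, per-reference
agreement, mean option counts, macro precision/recall/F1, a consensus
stratification, and the inter-candidate overlap matrix.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from . import metrics
from .metrics import (
    ConsensusStratification,
    OverlapAgreementMatrix,
    Proportion,
)
from .panel import Panel, PanelError, load_panel


@dataclass(frozen=True)
class CandidateConcordance:
    """Metric bundle for one candidate rater."""

    rater: str
    union_accuracy: Proportion
    per_reference_agreement: dict[str, Proportion]
    average_reference_agreement: Fraction
    mean_options_count: Fraction
    macro_precision: Fraction
    macro_recall: Fraction
    macro_f1: Fraction
    case_detail: pd.DataFrame


class ConcordanceModel:
    """Set-overlap concordance of candidates against references.

    Parameters
    ----------
    panel : Panel
        Cases × raters grid with candidate/reference rosters.
    agreement_rule : {"intersection", "equality", "primary"}
        How a candidate's set is compared against a single reference
        rater's set. ``intersection`` (share at least one option) is the
        default; the others are sensitivity variants.
    consensus_definition : {"strict_set", "primary_match", "any_pairwise_overlap"}
        Unanimity rule for the consensus stratification.
    prf_average : {"macro", "micro"}
        Averaging mode for precision/recall/F1 against the reference union.
    """

    def __init__(
        self,
        panel: Panel,
        agreement_rule: str = "intersection",
        consensus_definition: str = "strict_set",
        prf_average: str = "macro",
    ) -> None:
        if agreement_rule not in metrics.AGREEMENT_RULES:
            raise ValueError(f"unknown agreement rule {agreement_rule!r}")
        if consensus_definition not in metrics.CONSENSUS_DEFINITIONS:
            raise ValueError(f"unknown consensus definition {consensus_definition!r}")
        if prf_average not in ("macro", "micro"):
            raise ValueError(f"unknown averaging mode {prf_average!r}")
        if not panel.reference_raters:
            raise PanelError("panel has no reference raters")
        if not panel.candidate_raters:
            raise PanelError("panel has no candidate raters")
        self.panel = panel
        self.agreement_rule = agreement_rule
        self.consensus_definition = consensus_definition
        self.prf_average = prf_average

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        candidate_raters: Sequence[str],
        reference_raters: Sequence[str],
        case_column: str = "case",
        **kwargs,
    ) -> "ConcordanceModel":
        """Build from a DataFrame of slash-notation strings (one column per rater)."""
        panel = load_panel(
            frame.to_csv(index=False),
            candidate_raters,
            reference_raters,
            case_column=case_column,
        )
        return cls(panel, **kwargs)

    def fit(self) -> "ConcordanceResults":
        panel = self.panel
        per_candidate: dict[str, CandidateConcordance] = {}
        for cand in panel.candidate_raters:
            per_ref = {
                ref: metrics.reference_agreement(panel, cand, ref, self.agreement_rule)
                for ref in panel.reference_raters
            }
            avg = sum(p.fraction for p in per_ref.values()) / len(per_ref)
            precision, recall, f1 = metrics.macro_prf(
                panel, cand, average=self.prf_average
            )
            per_candidate[cand] = CandidateConcordance(
                rater=cand,
                union_accuracy=metrics.union_accuracy(panel, cand),
                per_reference_agreement=per_ref,
                average_reference_agreement=avg,
                mean_options_count=metrics.mean_options_count(panel, cand),
                macro_precision=precision,
                macro_recall=recall,
                macro_f1=f1,
                case_detail=metrics.per_case_detail(panel, cand),
            )
        stratification = metrics.stratify_by_consensus(panel, self.consensus_definition)
        overlap = (
            metrics.overlap_agreement_matrix(panel, panel.candidate_raters)
            if len(panel.candidate_raters) >= 2
            else None
        )
        return ConcordanceResults(self, per_candidate, stratification, overlap)


class ConcordanceResults:
    """Fitted concordance report for every candidate rater."""

    def __init__(
        self,
        model: ConcordanceModel,
        per_candidate: dict[str, CandidateConcordance],
        stratification: ConsensusStratification,
        overlap: OverlapAgreementMatrix | None,
    ) -> None:
        self.model = model
        self.per_candidate = per_candidate
        self.stratification = stratification
        self.overlap = overlap

    @property
    def panel(self) -> Panel:
        return self.model.panel

    def candidate(self, rater: str) -> CandidateConcordance:
        return self.per_candidate[rater]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: rater, metric, numerator, denominator, value, display."""
        rows: list[dict] = []

        def add(rater: str, metric: str, value, display: str, num=None, den=None):
            rows.append(
                {
                    "rater": rater,
                    "metric": metric,
                    "numerator": num,
                    "denominator": den,
                    "value": float(value),
                    "display_value": display,
                }
            )

        for cand, cc in self.per_candidate.items():
            ua = cc.union_accuracy
            add(cand, "union_accuracy", ua.value, ua.display(), ua.numerator, ua.denominator)
            for ref, p in cc.per_reference_agreement.items():
                add(cand, f"{ref}_agreement", p.value, p.display(), p.numerator, p.denominator)
            avg = cc.average_reference_agreement
            add(
                cand, "average_reference_agreement", float(avg),
                f"{100 * float(avg):.1f}", avg.numerator, avg.denominator,
            )
            moc = cc.mean_options_count
            add(cand, "mean_options_count", float(moc), f"{float(moc):.1f}",
                moc.numerator, moc.denominator)
            for name, frac in (
                ("macro_precision", cc.macro_precision),
                ("macro_recall", cc.macro_recall),
                ("macro_f1", cc.macro_f1),
            ):
                add(cand, name, float(frac), f"{100 * float(frac):.1f}",
                    frac.numerator, frac.denominator)
            for stratum in ("unanimous", "non_unanimous"):
                p = self.stratification.accuracy[cand][stratum]
                if p is not None:
                    add(cand, f"{stratum}_accuracy", p.value, p.display(),
                        p.numerator, p.denominator)
        if self.overlap is not None:
            for a, b, p in self.overlap.pairs():
                add(f"{a}|{b}", "overlap_agreement", p.value, p.display(),
                    p.numerator, p.denominator)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out: dict = {
            "report_type": "concordance",
            "agreement_rule": self.model.agreement_rule,
            "consensus_definition": self.model.consensus_definition,
            "prf_average": self.model.prf_average,
            "n_cases": self.panel.n_cases,
            "candidates": {},
            "stratification": {
                "definition": self.stratification.definition,
                "unanimous_case_ids": list(self.stratification.unanimous_case_ids),
                "non_unanimous_case_ids": list(self.stratification.non_unanimous_case_ids),
            },
        }

        def frac(x) -> list[int]:
            f = x.fraction if isinstance(x, Proportion) else Fraction(x)
            return [f.numerator, f.denominator]

        for cand, cc in self.per_candidate.items():
            out["candidates"][cand] = {
                "union_accuracy": frac(cc.union_accuracy),
                "per_reference_agreement": {
                    ref: frac(p) for ref, p in cc.per_reference_agreement.items()
                },
                "average_reference_agreement": frac(cc.average_reference_agreement),
                "mean_options_count": frac(cc.mean_options_count),
                "macro_precision": frac(cc.macro_precision),
                "macro_recall": frac(cc.macro_recall),
                "macro_f1": frac(cc.macro_f1),
                "stratified_accuracy": {
                    stratum: (None if p is None else frac(p))
                    for stratum, p in self.stratification.accuracy[cand].items()
                },
            }
        if self.overlap is not None:
            out["overlap_agreement"] = [
                {"rater_a": a, "rater_b": b, "proportion": frac(p)}
                for a, b, p in self.overlap.pairs()
            ]
        return out

    def summary(self) -> str:
        panel = self.panel
        name = panel.display_name
        lines = [
            f"Concordance analysis: {panel.n_cases} cases, "
            f"{len(panel.candidate_raters)} candidates vs "
            f"{len(panel.reference_raters)} references",
            f"  agreement rule: {self.model.agreement_rule}; "
            f"consensus: {self.model.consensus_definition}; "
            f"P/R/F1 averaging: {self.model.prf_average}",
            "",
        ]
        header = (
            f"  {'candidate':<12} {'union acc':>12} "
            + "".join(f"{name(r)[:10]:>12}" for r in panel.reference_raters)
            + f"{'avg agree':>12} {'opts':>6} {'P%':>6} {'R%':>6} {'F1%':>6}"
        )
        lines.append(header)
        for cand in panel.candidate_raters:
            cc = self.per_candidate[cand]
            ua = cc.union_accuracy
            cells = "".join(
                f"{p.display() + '%':>12}"
                for p in cc.per_reference_agreement.values()
            )
            lines.append(
                f"  {name(cand):<12} {str(ua) + ' ' + ua.display() + '%':>12} "
                + cells
                + f"{100 * float(cc.average_reference_agreement):>11.1f}%"
                + f"{float(cc.mean_options_count):>6.2f}"
                + f"{100 * float(cc.macro_precision):>6.1f}"
                + f"{100 * float(cc.macro_recall):>6.1f}"
                + f"{100 * float(cc.macro_f1):>6.1f}"
            )
        s = self.stratification
        lines += [
            "",
            f"  consensus stratification ({s.definition}): "
            f"{len(s.unanimous_case_ids)} unanimous "
            f"{list(s.unanimous_case_ids)}, "
            f"{len(s.non_unanimous_case_ids)} non-unanimous",
        ]
        if self.overlap is not None:
            lines.append("")
            lines.append("  pairwise overlap agreement (candidates):")
            for a, b, p in self.overlap.pairs():
                lines.append(
                    f"    {name(a)} – {name(b)}: {p} = {p.display()}%"
                )
        return "\n".join(lines)
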