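"""Chance-corrected inter-rater reliability on reduced single labels.

Cohen's and Fleiss' kappa are defined for one categorical label per rater
and case, so set-valued recommendations are first *reduced* to a single
label. The default reduction takes the primary (first-listed) option —
the rater's leading choice. A ``random`` reduction (uniform over the cell's
options, seeded) is available for sensitivity analysis.

Both statistics carry exact rational observed/expected agreement components:

* Cohen:  po = fraction of cases with equal labels, pe = Σ_k pA(k)·pB(k)
  over the observed category marginals, κ = (po − pe)/(1 − pe);
* Fleiss: P̄o = mean per-case pairwise agreement Σ_j n_ij(n_ij − 1)/(n(n − 1)),
  P̄e = Σ_j p_j², κ = (P̄o − P̄e)/(1 − P̄e).

When pe (or P̄e) equals 1 — every rater constant on the same label — kappa
is undefined; the result is returned flagged ``degenerate`` with κ = NaN
rather than raising.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .panel import Panel, PanelError, Recommendation

REDUCTIONS = ("primary", "random")


def primary_reduction(rec: Recommendation) -> int:
    """Reduce a set-valued recommendation to its primary (first-listed) code."""
    return rec.primary


def reduce_labels(
    panel: Panel,
    raters: Sequence[str],
    reduction: str = "primary",
    seed: int | None = None,
) -> dict[str, list[int]]:
    """One label per case per rater under the chosen reduction rule."""
    if reduction == "primary":
        return {r: [rec.primary for rec in panel.column(r)] for r in raters}
    if reduction == "random":
        rng = np.random.default_rng(seed)
        return {
            r: [rec.options[rng.integers(len(rec.options))] for rec in panel.column(r)]
            for r in raters
        }
    raise ValueError(f"unknown reduction {reduction!r}; choose from {REDUCTIONS}")


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its exact agreement components."""

    rater_a: str
    rater_b: str
    kappa: float
    po: Fraction
    pe: Fraction
    degenerate: bool = False

    @property
    def display(self) -> str:
        return "undefined" if self.degenerate else f"{self.kappa:.3f}"


@dataclass(frozen=True)
class FleissResult:
    """Fleiss' kappa with exact mean observed/expected agreement."""

    raters: tuple[str, ...]
    kappa: float
    p_bar_o: Fraction
    p_bar_e: Fraction
    category_proportions: dict[int, Fraction]
    degenerate: bool = False

    @property
    def display(self) -> str:
        return "undefined" if self.degenerate else f"{self.kappa:.3f}"


def cohen_kappa(
    panel: Panel,
    rater_a: str,
    rater_b: str,
    reduction: str = "primary",
    seed: int | None = None,
) -> KappaResult:
    """Pairwise Cohen's kappa between two raters after label reduction."""
    labels = reduce_labels(panel, (rater_a, rater_b), reduction, seed)
    la, lb = labels[rater_a], labels[rater_b]
    n = len(la)
    if n < 1:
        raise PanelError("kappa needs at least one case")
    po = Fraction(sum(a == b for a, b in zip(la, lb)), n)
    categories = set(la) | set(lb)
    pe = sum(
        Fraction(la.count(k), n) * Fraction(lb.count(k), n) for k in categories
    )
    if pe == 1:
        return KappaResult(rater_a, rater_b, math.nan, po, pe, degenerate=True)
    kappa = float((po - pe) / (1 - pe))
    return KappaResult(rater_a, rater_b, kappa, po, pe)


def fleiss_kappa(
    panel: Panel,
    raters: Sequence[str] | None = None,
    reduction: str = "primary",
    seed: int | None = None,
) -> FleissResult:
    """Fleiss' kappa across ``raters`` (default: the reference roster)."""
    raters = tuple(raters if raters is not None else panel.reference_raters)
    if len(raters) < 2:
        raise PanelError("Fleiss' kappa needs at least 2 raters")
    labels = reduce_labels(panel, raters, reduction, seed)
    n_cases = panel.n_cases
    if n_cases < 1:
        raise PanelError("Fleiss' kappa needs at least one case")
    m = len(raters)
    per_case = [[labels[r][i] for r in raters] for i in range(n_cases)]
    categories = sorted({lab for row in per_case for lab in row})
    counts = [[row.count(k) for k in categories] for row in per_case]
    p_bar_o = Fraction(
        sum(c * (c - 1) for row in counts for c in row), n_cases * m * (m - 1)
    )
    proportions = {
        k: Fraction(sum(row[j] for row in counts), n_cases * m)
        for j, k in enumerate(categories)
    }
    p_bar_e = sum(p * p for p in proportions.values())
    if p_bar_e == 1:
        return FleissResult(
            raters, math.nan, p_bar_o, p_bar_e, proportions, degenerate=True
        )
    kappa = float((p_bar_o - p_bar_e) / (1 - p_bar_e))
    return FleissResult(raters, kappa, p_bar_o, p_bar_e, proportions)


class ReliabilityModel:
    """Inter-rater reliability analysis of a panel's rater subset.

    Parameters
    ----------
    panel : Panel
    raters : sequence of rater ids, optional
        Defaults to the panel's reference roster (the expert raters whose
        internal consistency is under study).
    reduction : {"primary", "random"}
        How set-valued cells become single labels before kappa.
    seed : int, optional
        Only consulted by the ``random`` reduction.
    """

    def __init__(
        self,
        panel: Panel,
        raters: Sequence[str] | None = None,
        reduction: str = "primary",
        seed: int | None = None,
    ) -> None:
        self.panel = panel
        self.raters = tuple(raters if raters is not None else panel.reference_raters)
        if len(self.raters) < 2:
            raise PanelError("reliability analysis needs at least 2 raters")
        if reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {reduction!r}")
        self.reduction = reduction
        self.seed = seed

    def fit(self) -> "ReliabilityResults":
        pairwise: dict[frozenset[str], KappaResult] = {}
        for i, a in enumerate(self.raters):
            for b in self.raters[i + 1 :]:
                pairwise[frozenset((a, b))] = cohen_kappa(
                    self.panel, a, b, self.reduction, self.seed
                )
        fleiss = fleiss_kappa(self.panel, self.raters, self.reduction, self.seed)
        return ReliabilityResults(self, pairwise, fleiss)


class ReliabilityResults:
    """Fitted reliability report: pairwise Cohen kappas plus Fleiss' kappa."""

    def __init__(
        self,
        model: ReliabilityModel,
        pairwise: dict[frozenset[str], KappaResult],
        fleiss: FleissResult,
    ) -> None:
        self.model = model
        self.pairwise = pairwise
        self.fleiss = fleiss

    @property
    def reduction(self) -> str:
        return self.model.reduction

    def pair(self, rater_a: str, rater_b: str) -> KappaResult:
        """Symmetric lookup of one pairwise kappa."""
        return self.pairwise[frozenset((rater_a, rater_b))]

    def to_dict(self) -> dict:
        pairs = []
        raters = self.model.raters
        for i, a in enumerate(raters):
            for b in raters[i + 1 :]:
                k = self.pair(a, b)
                pairs.append(
                    {
                        "rater_a": a,
                        "rater_b": b,
                        "kappa": None if k.degenerate else k.kappa,
                        "po": [k.po.numerator, k.po.denominator],
                        "pe": [k.pe.numerator, k.pe.denominator],
                        "degenerate": k.degenerate,
                        "display": k.display,
                    }
                )
        f = self.fleiss
        return {
            "report_type": "reliability",
            "reduction": self.reduction,
            "raters": list(raters),
            "pairwise": pairs,
            "fleiss": {
                "kappa": None if f.degenerate else f.kappa,
                "p_bar_o": [f.p_bar_o.numerator, f.p_bar_o.denominator],
                "p_bar_e": [f.p_bar_e.numerator, f.p_bar_e.denominator],
                "category_proportions": {
                    str(k): [v.numerator, v.denominator]
                    for k, v in f.category_proportions.items()
                },
                "degenerate": f.degenerate,
                "display": f.display,
            },
        }

    def summary(self) -> str:
        panel = self.model.panel
        lines = [
            "Inter-rater reliability",
            f"  reduction: {self.reduction}; raters: "
            + ", ".join(panel.display_name(r) for r in self.model.raters),
            "",
            f"  {'pair':<28} {'kappa':>8} {'po':>10} {'pe':>12}",
        ]
        raters = self.model.raters
        for i, a in enumerate(raters):
            for b in raters[i + 1 :]:
                k = self.pair(a, b)
                name = f"{panel.display_name(a)} – {panel.display_name(b)}"
                lines.append(
                    f"  {name:<28} {k.display:>8} {str(k.po):>10} {str(k.pe):>12}"
                )
        f = self.fleiss
        lines += [
            "",
            f"  Fleiss' kappa: {f.display}   "
            f"(P̄o = {f.p_bar_o}, P̄e = {f.p_bar_e})",
        ]
        return "\n".join(lines)
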