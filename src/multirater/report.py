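"""Report serialization: CSV, JSON and markdown renderings of fitted results.

JSON keeps every statistic at full precision as an exact ``[numerator,
denominator]`` pair plus the field's conventional display rounding
(percentages to one decimal, kappa to three); CSV uses the long format ``rater, metric,
numerator, denominator, value, display_value``. Markdown is display-only.
"""
from __future__ import annotations

import json
from fractions import Fraction

import pandas as pd

from .concordance import ConcordanceResults
from .datasets import PUBLISHED
from .reliability import ReliabilityResults

FORMATS = ("csv", "json", "markdown")


def format_percent(value, digits: int = 1) -> str:
    """Display a proportion in [0, 1] as a percentage string, e.g. '81.8'."""
    return f"{100 * float(value):.{digits}f}"


def format_kappa(value: float, digits: int = 3) -> str:
    return f"{float(value):.{digits}f}"


def _reliability_frame(results: ReliabilityResults) -> pd.DataFrame:
    rows = []
    raters = results.model.raters
    for i, a in enumerate(raters):
        for b in raters[i + 1 :]:
            k = results.pair(a, b)
            rows.append(
                {
                    "rater": f"{a}|{b}",
                    "metric": "cohen_kappa",
                    "numerator": None,
                    "denominator": None,
                    "value": k.kappa,
                    "display_value": k.display,
                }
            )
            for name, frac in (("po", k.po), ("pe", k.pe)):
                rows.append(
                    {
                        "rater": f"{a}|{b}",
                        "metric": name,
                        "numerator": frac.numerator,
                        "denominator": frac.denominator,
                        "value": float(frac),
                        "display_value": f"{float(frac):.4f}",
                    }
                )
    f = results.fleiss
    rows.append(
        {
            "rater": "|".join(raters),
            "metric": "fleiss_kappa",
            "numerator": None,
            "denominator": None,
            "value": f.kappa,
            "display_value": f.display,
        }
    )
    return pd.DataFrame(rows)


def _markdown_table(frame: pd.DataFrame) -> str:
    columns = [str(c) for c in frame.columns]
    widths = [
        max(len(col), *(len(str(v)) for v in frame[col])) if len(frame) else len(col)
        for col in columns
    ]
    header = "| " + " | ".join(c.ljust(w) for c, w in zip(columns, widths)) + " |"
    rule = "| " + " | ".join("-" * w for w in widths) + " |"
    body = [
        "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
        for row in frame.itertuples(index=False)
    ]
    return "\n".join([header, rule, *body])


def write_report(results, format: str = "json") -> str:
    """Serialize a fitted concordance or reliability result.

    ``csv``/``json`` are round-trippable (exact rational components kept);
    ``markdown`` renders the long-format table for humans.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    if isinstance(results, ConcordanceResults):
        frame = results.to_frame()
        payload = results.to_dict()
    elif isinstance(results, ReliabilityResults):
        frame = _reliability_frame(results)
        payload = results.to_dict()
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}")
    if format == "json":
        return json.dumps(payload, indent=2)
    if format == "csv":
        return frame.to_csv(index=False)
    return _markdown_table(frame)


def read_report_json(text: str) -> dict:
    """Parse a JSON report back to its dictionary form (values exact)."""
    return json.loads(text)


def reproduction_table(
    concordance: ConcordanceResults, reliability: ReliabilityResults
) -> pd.DataFrame:
    """Side-by-side comparison with the originally published statistics.

    Each row carries the published value, the value recomputed here from
    the coded panel, and a status: ``match`` when the recomputed display
    rounding equals the published number, ``differs`` otherwise. Several
    published numbers are known not to be recoverable from the coded grid
    (see the dataset documentation); they are reported, not hidden.

    Only meaningful for the built-in study panel's rosters.
    """
    rows = []

    def add(metric: str, who: str, published: float, computed_display: str,
            computed_exact: str):
        rows.append(
            {
                "metric": metric,
                "rater": who,
                "published": published,
                "recomputed": computed_display,
                "exact": computed_exact,
                "status": "match"
                if f"{published:g}" == f"{float(computed_display):g}"
                else "differs",
            }
        )

    per = concordance.per_candidate
    surgeon_keys = {
        "surgeon1_agreement": "surgeon1",
        "surgeon2_agreement": "surgeon2",
        "surgeon3_agreement": "surgeon3",
    }
    for cand in concordance.panel.candidate_raters:
        cc = per[cand]
        add("union_accuracy", cand, PUBLISHED["union_accuracy"][cand],
            cc.union_accuracy.display(), str(cc.union_accuracy))
        for metric, ref in surgeon_keys.items():
            p = cc.per_reference_agreement[ref]
            add(metric, cand, PUBLISHED[metric][cand], p.display(), str(p))
        avg = cc.average_reference_agreement
        add("average_surgeon_agreement", cand,
            PUBLISHED["average_surgeon_agreement"][cand],
            format_percent(avg), str(avg))
        moc = cc.mean_options_count
        add("mean_options_count", cand, PUBLISHED["mean_options_count"][cand],
            f"{float(moc):.1f}", str(moc))
        for metric, frac in (
            ("macro_precision", cc.macro_precision),
            ("macro_recall", cc.macro_recall),
            ("macro_f1", cc.macro_f1),
        ):
            add(metric, cand, PUBLISHED[metric][cand], format_percent(frac), str(frac))
        for stratum, metric in (
            ("unanimous", "unanimous_accuracy"),
            ("non_unanimous", "non_unanimous_accuracy"),
        ):
            p = concordance.stratification.accuracy[cand][stratum]
            if p is not None:
                add(metric, cand, PUBLISHED[metric][cand], p.display(), str(p))
    if concordance.overlap is not None:
        for (a, b), published in PUBLISHED["inter_ai_agreement"].items():
            p = concordance.overlap.get(a, b)
            add("inter_ai_agreement", f"{a}|{b}", published, p.display(), str(p))
    for (a, b), published in PUBLISHED["cohen_kappa"].items():
        k = reliability.pair(a, b)
        add("cohen_kappa", f"{a}|{b}", published, k.display,
            f"po={k.po}, pe={k.pe}")
    f = reliability.fleiss
    add("fleiss_kappa", "|".join(reliability.model.raters),
        PUBLISHED["fleiss_kappa"], f.display, f"Po={f.p_bar_o}, Pe={f.p_bar_e}")
    return pd.DataFrame(rows)
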