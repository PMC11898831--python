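"""The embedded 22-case Dupuytren's-disease study panel.

The packaged dataset is the coded recommendation grid from a multicentric
comparison of five AI chat systems against three experienced hand surgeons:
22 standardized clinical vignettes, each rated by every rater with one or
more management-option codes (slash notation, 11-category vocabulary).
Candidates are the AI systems; references are the surgeons.

``PUBLISHED`` carries the statistics the original study reported for this
panel, used by the reproduction report to mark which printed numbers the
coded grid actually supports and which it does not (several printed values
— Surgeon II/III agreements, average option counts, precision/recall/F1,
inter-AI percentages and consensus-stratified accuracies — are not
recoverable from the coded grid under any evident convention; the package
computes and reports its own values for those).

Two transcription caveats, preserved verbatim from the source table: the
Copilot cells of cases 9 and 13 appear swapped relative to the free-text
narrative of the study (case 13's narrative describes observation while the
grid codes 8 on case 13 and 4 on case 9), and Surgeon II's case-4 free text
is conditional but coded flatly as ``2/6/8``. The fixture follows the coded
grid cell-for-cell.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import Panel, load_panel

CANDIDATE_RATERS: tuple[str, ...] = (
    "chatgpt",
    "gemini",
    "perplexity",
    "deepseek",
    "copilot",
)
REFERENCE_RATERS: tuple[str, ...] = ("surgeon1", "surgeon2", "surgeon3")

DISPLAY_NAMES: dict[str, str] = {
    "chatgpt": "ChatGPT",
    "gemini": "Gemini",
    "perplexity": "Perplexity",
    "deepseek": "DeepSeek",
    "copilot": "Copilot",
    "surgeon1": "Surgeon I",
    "surgeon2": "Surgeon II",
    "surgeon3": "Surgeon III",
}

#: Statistics as printed by the original study, keyed the way the package
#: computes them. Percentages are on the 0–100 scale, kappas on -1..1.
PUBLISHED: dict[str, dict] = {
    "union_accuracy": {
        "chatgpt": 81.8, "gemini": 86.4, "perplexity": 77.3,
        "deepseek": 63.6, "copilot": 40.9,
    },
    "surgeon1_agreement": {
        "chatgpt": 72.7, "gemini": 77.3, "perplexity": 54.5,
        "deepseek": 45.5, "copilot": 31.8,
    },
    "surgeon2_agreement": {
        "chatgpt": 36.4, "gemini": 36.4, "perplexity": 40.9,
        "deepseek": 27.3, "copilot": 18.2,
    },
    "surgeon3_agreement": {
        "chatgpt": 18.2, "gemini": 22.7, "perplexity": 40.9,
        "deepseek": 27.3, "copilot": 31.8,
    },
    "average_surgeon_agreement": {
        "chatgpt": 42.4, "gemini": 45.5, "perplexity": 45.4,
        "deepseek": 33.4, "copilot": 27.3,
    },
    "mean_options_count": {
        "chatgpt": 2.0, "gemini": 2.1, "perplexity": 2.0,
        "deepseek": 1.8, "copilot": 1.3,
    },
    "macro_precision": {
        "chatgpt": 62.0, "gemini": 64.0, "perplexity": 60.0,
        "deepseek": 55.0, "copilot": 45.0,
    },
    "macro_recall": {
        "chatgpt": 58.0, "gemini": 60.0, "perplexity": 57.0,
        "deepseek": 52.0, "copilot": 42.0,
    },
    "macro_f1": {
        "chatgpt": 60.0, "gemini": 62.0, "perplexity": 58.5,
        "deepseek": 53.5, "copilot": 43.5,
    },
    "unanimous_accuracy": {
        "chatgpt": 90.0, "gemini": 92.0, "perplexity": 85.0,
        "deepseek": 70.0, "copilot": 50.0,
    },
    "non_unanimous_accuracy": {
        "chatgpt": 75.0, "gemini": 80.0, "perplexity": 70.0,
        "deepseek": 55.0, "copilot": 35.0,
    },
    "inter_ai_agreement": {
        ("chatgpt", "gemini"): 75.0,
        ("chatgpt", "perplexity"): 70.0,
        ("chatgpt", "deepseek"): 65.0,
        ("chatgpt", "copilot"): 50.0,
        ("gemini", "perplexity"): 78.0,
        ("gemini", "deepseek"): 70.0,
        ("gemini", "copilot"): 55.0,
        ("perplexity", "deepseek"): 68.0,
        ("perplexity", "copilot"): 52.0,
        ("deepseek", "copilot"): 48.0,
    },
    "cohen_kappa": {
        ("surgeon1", "surgeon2"): 0.224,
        ("surgeon1", "surgeon3"): 0.081,
        ("surgeon2", "surgeon3"): 0.169,
    },
    "fleiss_kappa": 0.122,
}


def _data_path(name: str):
    return resources.files("multirater.data").joinpath(name)


def fixture_csv_text() -> str:
    """Raw CSV text of the embedded coded panel."""
    return _data_path("dupuytren_coded_panel.csv").read_text(encoding="utf-8")


def case_descriptions() -> dict[int, str]:
    """Optional vignette text per case (metadata only; no metric uses it)."""
    with resources.as_file(_data_path("case_descriptions.csv")) as path:
        df = pd.read_csv(path)
    return {int(row["case"]): str(row["description"]) for _, row in df.iterrows()}


def builtin_study_panel(include_descriptions: bool = True) -> Panel:
    """The 22-case × 8-rater study panel, transcribed cell-for-cell.

    Candidates: ChatGPT, Gemini, Perplexity, DeepSeek, Copilot.
    References: Surgeons I–III.
    """
    panel = load_panel(
        fixture_csv_text(),
        candidate_raters=CANDIDATE_RATERS,
        reference_raters=REFERENCE_RATERS,
    )
    if include_descriptions:
        descriptions = case_descriptions()
        cases = tuple(
            type(c)(c.case_id, c.ratings, descriptions.get(c.case_id))
            for c in panel.cases
        )
        panel = Panel(
            cases, panel.candidate_raters, panel.reference_raters, DISPLAY_NAMES
        )
    else:
        panel = Panel(
            panel.cases, panel.candidate_raters, panel.reference_raters, DISPLAY_NAMES
        )
    return panel
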