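import pytest

from multirater import Panel, Recommendation, builtin_study_panel
from multirater.panel import CaseRecord


@pytest.fixture(scope="session")
def study_panel() -> Panel:
    return builtin_study_panel()


def make_panel(rows, candidates, references):
    """Build a panel from rows of {rater: tuple-of-codes}; case ids 1..n."""
    cases = tuple(
        CaseRecord(i + 1, {r: Recommendation(tuple(v)) for r, v in row.items()})
        for i, row in enumerate(rows)
    )
    return Panel(cases, tuple(candidates), tuple(references))


@pytest.fixture
def toy_panel() -> Panel:
    """Two candidates, two references, three cases with known overlaps."""
    rows = [
        {"a": (1, 2), "b": (3,), "r1": (1,), "r2": (4,)},
        {"a": (5,), "b": (5, 6), "r1": (5,), "r2": (5,)},
        {"a": (7,), "b": (8,), "r1": (9,), "r2": (7, 9)},
    ]
    return make_panel(rows, ["a", "b"], ["r1", "r2"])
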