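"""Coded management-option vocabulary.

Recommendations in a panel are recorded as small integer codes drawn from a
fixed 11-category vocabulary of Dupuytren's-disease management modalities,
from minimally invasive needle techniques through open surgery to salvage
procedures. Codes are nominal (unordered) categories.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OptionCode:
    """A single coded management modality."""

    code: int
    label: str

    def __int__(self) -> int:
        return self.code


OPTION_LABELS: dict[int, str] = {
    1: "Percutaneous needle aponeurotomy (PNA)",
    2: "Collagenase injection (CCH)",
    3: "Cordless needle fasciotomy (CNF)",
    4: "Limited fasciectomy",
    5: "Dermofasciectomy",
    6: "Dermofasciectomy with skin graft",
    7: "Partial fasciectomy",
    8: "Conservative management (observation, splinting, or hand therapy)",
    9: "Multidisciplinary approach",
    10: "Salvage procedures (including possible digit amputation)",
    11: "Arthrodesis",
}

VALID_CODES: frozenset[int] = frozenset(OPTION_LABELS)

_REGISTRY: dict[int, OptionCode] = {
    code: OptionCode(code, label) for code, label in OPTION_LABELS.items()
}


class UnknownOptionError(ValueError):
    """Raised when a code outside the 11-category vocabulary is looked up."""


def get_option(code: int) -> OptionCode:
    """Look up the :class:`OptionCode` for an integer code.

    Raises :class:`UnknownOptionError` for any code outside ``1..11``.
    """
    try:
        return _REGISTRY[code]
    except KeyError:
        raise UnknownOptionError(
            f"unknown management-option code {code!r}; valid codes are 1..11"
        ) from None
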