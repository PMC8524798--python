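"""WHO Anatomical Therapeutic Chemical (ATC) code handling.

ATC codes are hierarchical: a full 7-character code such as ``B01AC06``
(aspirin) nests inside the chemical subgroup ``B01AC`` (platelet aggregation
inhibitors), the pharmacological subgroup ``B01A``, the therapeutic subgroup
``B01`` and the anatomical main group ``B``.  Rule matching in this package
is pure prefix matching on this hierarchy, so the only structural facts we
need are the legal truncation lengths and the per-position character classes.
"""

from __future__ import annotations

import re

__all__ = ["ATCFormatError", "canonical_atc", "is_valid_atc", "is_prefix_of"]

# Legal levels: 1 (anatomical), 3 (therapeutic), 4 (pharmacological),
# 5 (chemical subgroup), 7 (chemical substance).
_LEVEL_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z][0-9]{2}$"),
    4: re.compile(r"^[A-Z][0-9]{2}[A-Z]$"),
    5: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"),
}


class ATCFormatError(ValueError):
    """Raised when a string is not a structurally valid ATC code."""


def canonical_atc(code: str) -> str:
    """Validate *code* and return its canonical (uppercase) form.

    Raises
    ------
    ATCFormatError
        If the code length or per-position character classes do not follow
        the WHO ATC level structure.
    """
    if not isinstance(code, str):
        raise ATCFormatError(f"ATC code must be a string, got {type(code).__name__}")
    c = code.strip().upper()
    pattern = _LEVEL_PATTERNS.get(len(c))
    if pattern is None or not pattern.match(c):
        raise ATCFormatError(f"not a valid ATC code: {code!r}")
    return c


def is_valid_atc(code: str) -> bool:
    try:
        canonical_atc(code)
        return True
    except ATCFormatError:
        return False


def is_prefix_of(prefix: str, code: str) -> bool:
    """True iff *prefix* is an ancestor of (or equal to) *code* in the ATC tree.

    Both arguments must already be canonical uppercase codes; plain string
    prefix testing is exact because every legal truncation of a valid code is
    itself a valid code at a coarser level.
    """
    return code.startswith(prefix)
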