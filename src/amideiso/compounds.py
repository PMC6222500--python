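"""Model-compound codes and substitution bookkeeping.

The model set is glycylglycine methyl ester (GGMe) and its tert-butyl
derivatives.  Each compound is named by a four-character code ``N<d1><d2><d3>0``
where the three digits flag a tert-butyl substitution at, respectively, the
N-terminal amino nitrogen (R1), the N-terminal alpha-carbon (R2) and the
C-terminal alpha-carbon (R3).  Alpha-carbon substitutions default to the
*S* configuration; a prime after the third digit (``N011'0``) marks the
unnatural *R* configuration at R3.  The trailing ``0`` stands for the methyl
ester and is fixed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "Compound",
    "CompoundCodeError",
    "parse_compound_code",
    "parse_labeled_code",
    "substitution_counts",
    "PAPER_CODES",
]

# Typographic prime (U+2019) is accepted on input; ASCII is canonical.
_PRIMES = "'’"
_CODE_RE = re.compile(r"^N([019])([019])([019])(['’])?([09])$")

#: The ten compound codes of the model set, canonical ASCII form.
PAPER_CODES = (
    "N0000", "N0010", "N0100", "N0110", "N011'0",
    "N1000", "N1010", "N1100", "N1110", "N111'0",
)


class CompoundCodeError(ValueError):
    """Raised for a malformed compound code; names the offending character."""


@dataclass(frozen=True)
class Compound:
    """A substituted-GGMe model compound.

    Attributes
    ----------
    code:
        Canonical code, ASCII prime (e.g. ``"N011'0"``).
    r1:
        Substituent on the amino nitrogen: ``"H"`` or ``"tBu"``.
    r2:
        Substituent on the N-terminal alpha-carbon: ``"H"`` or ``"tBu-S"``.
    r3:
        Substituent on the C-terminal alpha-carbon: ``"H"``, ``"tBu-S"`` or
        ``"tBu-R"``.
    """

    code: str
    r1: str
    r2: str
    r3: str
    ester: str = "methyl"

    def __post_init__(self) -> None:
        if self.r1 not in ("H", "tBu"):
            raise CompoundCodeError(f"invalid R1 substituent {self.r1!r}")
        if self.r2 not in ("H", "tBu-S"):
            raise CompoundCodeError(f"invalid R2 substituent {self.r2!r}")
        if self.r3 not in ("H", "tBu-S", "tBu-R"):
            raise CompoundCodeError(f"invalid R3 substituent {self.r3!r}")


def parse_compound_code(code: str) -> Compound:
    """Parse a compound code like ``"N0110"`` or ``"N011'0"``.

    The prime may be the ASCII apostrophe or the typographic U+2019; the
    canonical form stored on the returned :class:`Compound` uses ASCII.

    Raises
    ------
    CompoundCodeError
        If the code does not match the ``N[01][01][01]'?0`` pattern, if a
        prime follows an unsubstituted third position, or if any digit is
        outside {0, 1}.
    """
    if not isinstance(code, str):
        raise CompoundCodeError(f"compound code must be text, got {type(code).__name__}")
    if not code.startswith("N"):
        raise CompoundCodeError(
            f"compound code {code!r} must start with 'N', got {code[:1]!r}"
        )
    m = _CODE_RE.match(code)
    if m is None:
        # locate the first character that breaks the pattern for the message
        for i, ch in enumerate(code[1:], start=1):
            if ch not in "01" + _PRIMES:
                raise CompoundCodeError(
                    f"compound code {code!r}: unexpected character {ch!r} at position {i}"
                )
        raise CompoundCodeError(f"malformed compound code {code!r}")
    d1, d2, d3, prime, d4 = m.groups()
    for pos, d in ((1, d1), (2, d2), (3, d3)):
        if d not in "01":
            raise CompoundCodeError(
                f"compound code {code!r}: digit {d!r} at position {pos} outside {{0,1}}"
            )
    if d4 != "0":
        raise CompoundCodeError(
            f"compound code {code!r}: fourth digit {d4!r} must be 0 (methyl ester)"
        )
    if prime and d3 == "0":
        raise CompoundCodeError(
            f"compound code {code!r}: prime requires a substituent at the third position"
        )
    r1 = "tBu" if d1 == "1" else "H"
    r2 = "tBu-S" if d2 == "1" else "H"
    if d3 == "0":
        r3 = "H"
    else:
        r3 = "tBu-R" if prime else "tBu-S"
    canonical = "N" + d1 + d2 + d3 + ("'" if prime else "") + "0"
    return Compound(code=canonical, r1=r1, r2=r2, r3=r3)


def parse_labeled_code(label: str) -> tuple[Compound, str]:
    """Parse a code with a trailing isomer letter, e.g. ``"N1110t"``.

    Returns the compound and the isomer name (``"trans"`` for ``t``,
    ``"cis"`` for ``c``).  A bare code without suffix is rejected.
    """
    if not label or label[-1] not in "tc":
        raise CompoundCodeError(
            f"labeled code {label!r} must end in 't' (trans) or 'c' (cis)"
        )
    isomer = "trans" if label[-1] == "t" else "cis"
    return parse_compound_code(label[:-1]), isomer


def substitution_counts(c: Compound) -> tuple[int, int]:
    """Number of tert-butyl groups on the sp3 nitrogen and on sp3 carbons.

    Returns ``(nN, nC)`` with ``nN`` in {0, 1} and ``nC`` in {0, 1, 2}; the
    R3 chirality does not affect the count.
    """
    n_n = 1 if c.r1 == "tBu" else 0
    n_c = sum(1 for r in (c.r2, c.r3) if r != "H")
    return n_n, n_c
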