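"""Cis/trans energetics: relative stabilities, solvation shifts, barriers.

All quantities are referenced to the minimum-energy trans conformer of the
same compound and phase: a positive relative energy means the cis isomer is
destabilized.  The four directional rotation barriers (syn/anti x +/-) are
condensed to an effective barrier dG_eff, the minimum Gibbs barrier over
the directions actually determined — the operative barrier if the system
takes the easiest path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .records import ConformerRecord

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BARRIER_KEYS",
    "IsomerPair",
    "BarrierEntry",
    "BarrierSummary",
    "relative_energy",
    "solvation_shift",
    "effective_barrier",
    "equilibrium_cis_fraction",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987204e-3

#: Canonical ordering of barrier keys: anti before syn, + before -.
#: This is also the tie-break order for the effective-barrier argmin.
BARRIER_KEYS: tuple[tuple[str, str], ...] = (
    ("anti", "+"),
    ("anti", "-"),
    ("syn", "+"),
    ("syn", "-"),
)


@dataclass
class IsomerPair:
    """Matched trans/cis records for one compound and phase."""

    trans: ConformerRecord
    cis: ConformerRecord

    def __post_init__(self) -> None:
        if self.trans.isomer != "trans" or self.cis.isomer != "cis":
            raise ValueError("IsomerPair requires one trans and one cis record")
        if self.trans.compound.code != self.cis.compound.code:
            raise ValueError(
                f"isomer pair mixes compounds "
                f"{self.trans.compound.code!r} and {self.cis.compound.code!r}"
            )
        if self.trans.phase != self.cis.phase:
            raise ValueError("isomer pair mixes phases")

    @property
    def compound_code(self) -> str:
        return self.trans.compound.code

    @property
    def phase(self) -> str:
        return self.trans.phase


def relative_energy(pair: IsomerPair, field_name: str = "E") -> float:
    """Cis-minus-trans energy difference, kcal/mol.

    ``field_name`` selects the electronic energy (``"E"``, from ``opt_e``)
    or any other numeric attribute carried by both records (e.g. a free
    energy stored as ``g``).
    """
    attr = {"E": "opt_e", "G": "g"}.get(field_name, field_name)
    try:
        t = getattr(pair.trans, attr)
        c = getattr(pair.cis, attr)
    except AttributeError:
        raise ValueError(f"records carry no field {field_name!r}") from None
    if t is None or c is None:
        raise ValueError(f"field {field_name!r} is absent on one record")
    return c - t


def solvation_shift(cis_solv: float, trans_solv: float) -> float:
    """Cis-minus-trans solvation energy, kcal/mol (negative: cis better solvated)."""
    if cis_solv is None or trans_solv is None:
        raise ValueError("solvation energies are water-phase quantities; got absent value")
    return cis_solv - trans_solv


def solvation_shift_pair(pair: IsomerPair) -> float:
    """:func:`solvation_shift` from an :class:`IsomerPair` (water phase only)."""
    if pair.phase != "water":
        raise ValueError("solvation shift is defined only in the water phase")
    return solvation_shift(pair.cis.solvation_e, pair.trans.solvation_e)


@dataclass(frozen=True)
class BarrierEntry:
    """One directional barrier: electronic and Gibbs heights, kcal/mol."""

    d_e: float | None = None
    d_g: float | None = None


@dataclass
class BarrierSummary:
    """The up-to-four directional barriers of one compound/phase.

    ``barriers`` maps ``(type, direction)`` keys — type in {anti, syn},
    direction in {+, -} — to :class:`BarrierEntry` or ``None`` for entries
    not determined (symmetric compounds).  ``dg_eff`` is the minimum
    present Gibbs barrier and ``argmin`` its key.
    """

    compound_code: str
    phase: str
    barriers: dict[tuple[str, str], BarrierEntry | None] = field(default_factory=dict)
    dg_eff: float | None = None
    argmin: tuple[str, str] | None = None


def effective_barrier(
    entries: Mapping[tuple[str, str], BarrierEntry | None],
    compound_code: str = "",
    phase: str = "",
) -> BarrierSummary:
    """Select the effective (minimum) Gibbs barrier from directional entries.

    Absent entries (``None`` or entries without a Gibbs value) are skipped.
    Ties go to the canonically first key (anti before syn, + before -).

    Raises
    ------
    ValueError
        If no entry carries a Gibbs barrier, or an unknown key appears.
    """
    for key in entries:
        if key not in BARRIER_KEYS:
            raise ValueError(f"unknown barrier key {key!r}; expected one of {BARRIER_KEYS}")
    best_key: tuple[str, str] | None = None
    best: float = math.inf
    for key in BARRIER_KEYS:  # canonical order makes the tie-break explicit
        entry = entries.get(key)
        if entry is None or entry.d_g is None:
            continue
        if entry.d_g < best:
            best = entry.d_g
            best_key = key
    if best_key is None:
        raise ValueError("all directional barrier entries are absent")
    return BarrierSummary(
        compound_code=compound_code,
        phase=phase,
        barriers=dict(entries),
        dg_eff=best,
        argmin=best_key,
    )


def equilibrium_cis_fraction(d_g: float, temperature: float = 298.15) -> float:
    """Equilibrium cis fraction for a cis-trans free-energy gap.

    Two-state Boltzmann weight: ``exp(-dG/RT) / (1 + exp(-dG/RT))`` with
    ``d_g`` the cis-minus-trans Gibbs energy in kcal/mol.  Strictly
    decreasing in ``d_g``; 0.5 at ``d_g`` = 0.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    x = -d_g / (GAS_CONSTANT_KCAL * temperature)
    # logistic form, evaluated stably for large |x|
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)
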