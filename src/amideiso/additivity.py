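"""Group-additivity steric-energy analysis.

The additivity principle estimates the energy of a tert-butyl-substituted
compound as the energy of the unsubstituted parent scaffold (GGMe, N0000)
plus one transferable group increment per substitution.  Two increments are
used, one per attachment-atom class:

* ``E_tb^N`` — tert-butyl on the pyramidal sp3 amino nitrogen, derived as
  E(tert-butylamine) - E(ammonia);
* ``E_tb^C`` — tert-butyl on an sp3 carbon, derived as
  E(neopentane) - E(methane);

each evaluated per phase (gas / water continuum).  The additive estimate is

    AddE = optE(N0000, isomer, phase) + nN * E_tb^N + nC * E_tb^C

and the steric energy is the excess of the directly optimized energy over
that estimate, stE = optE - AddE.  The sign convention makes steric strain
positive.  Each (isomer, phase) block carries its own base energy and is
processed independently; blocks are never mixed because their absolute
energy scales need not agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .compounds import Compound, substitution_counts
from .records import ConformerRecord, ISOMERS, PHASES

__all__ = [
    "GroupIncrement",
    "AdditivityModel",
    "AdditivityConfigError",
    "derive_increment",
    "additive_energy",
    "steric_energy",
    "steric_table",
    "StericRow",
]

ATTACHMENTS = ("sp3-N", "sp3-C")


class AdditivityConfigError(ValueError):
    """A base energy or increment required by the model is missing."""


@dataclass(frozen=True)
class GroupIncrement:
    """Additive energy of one tert-butyl substitution, kcal/mol."""

    attachment: str
    phase: str
    value: float

    def __post_init__(self) -> None:
        if self.attachment not in ATTACHMENTS:
            raise ValueError(f"attachment must be one of {ATTACHMENTS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if not math.isfinite(self.value):
            raise ValueError("increment value must be finite")


@dataclass
class AdditivityModel:
    """Base energies of the reference compound plus group increments.

    ``base_energies`` maps ``(isomer, phase)`` to the optimized energy of
    the reference compound (N0000) for that block; ``increments`` maps
    ``(attachment, phase)`` to a :class:`GroupIncrement` — exactly one per
    pair.
    """

    base_energies: dict[tuple[str, str], float] = field(default_factory=dict)
    increments: dict[tuple[str, str], GroupIncrement] = field(default_factory=dict)
    reference_code: str = "N0000"

    def add_increment(self, inc: GroupIncrement) -> None:
        key = (inc.attachment, inc.phase)
        if key in self.increments:
            raise AdditivityConfigError(f"duplicate increment for {key}")
        self.increments[key] = inc

    def increment(self, attachment: str, phase: str) -> float:
        try:
            return self.increments[(attachment, phase)].value
        except KeyError:
            raise AdditivityConfigError(
                f"no {attachment} increment for the {phase} phase"
            ) from None

    def base_energy(self, isomer: str, phase: str) -> float:
        try:
            return self.base_energies[(isomer, phase)]
        except KeyError:
            raise AdditivityConfigError(
                f"no base energy for ({isomer}, {phase}); the reference compound "
                f"{self.reference_code} record is required for this block"
            ) from None


def derive_increment(parent_e: float, substituted_e: float) -> float:
    """Group increment from a parent/substituted small-molecule energy pair.

    Simply ``substituted_e - parent_e`` (e.g. tert-butylamine minus ammonia
    for the sp3-N increment); both energies in kcal/mol.
    """
    if not (math.isfinite(parent_e) and math.isfinite(substituted_e)):
        raise ValueError("energies must be finite")
    return substituted_e - parent_e


def additive_energy(
    model: AdditivityModel, compound: Compound, isomer: str, phase: str
) -> float:
    """Additivity estimate AddE for one compound/isomer/phase, kcal/mol."""
    if isomer not in ISOMERS:
        raise ValueError(f"isomer must be one of {ISOMERS}, got {isomer!r}")
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    n_n, n_c = substitution_counts(compound)
    add_e = model.base_energy(isomer, phase)
    if n_n:
        add_e += n_n * model.increment("sp3-N", phase)
    if n_c:
        add_e += n_c * model.increment("sp3-C", phase)
    return add_e


def steric_energy(opt_e: float, add_e: float) -> float:
    """Steric energy stE = optE - AddE, kcal/mol (strain is positive)."""
    if not (math.isfinite(opt_e) and math.isfinite(add_e)):
        raise ValueError("energies must be finite")
    return opt_e - add_e


@dataclass(frozen=True)
class StericRow:
    """One row of a steric-energy table (machine precision, unrounded)."""

    compound: Compound
    isomer: str
    phase: str
    opt_e: float
    n_n: int
    n_c: int
    add_e: float
    st_e: float

    def display(self, decimals: int = 3) -> dict[str, object]:
        """Rounded view matching the conventional 3-decimal presentation."""
        return {
            "compound": self.compound.code,
            "isomer": self.isomer,
            "phase": self.phase,
            "optE": round(self.opt_e, decimals),
            "n_tBu_N": self.n_n or None,
            "n_tBu_C": self.n_c or None,
            "AddE": round(self.add_e, decimals),
            "stE": round(self.st_e, decimals),
        }


def steric_table(
    records: Iterable[ConformerRecord], model: AdditivityModel
) -> Mapping[tuple[str, str, str], StericRow]:
    """Steric-energy table for a batch of conformer records.

    Keyed by ``(compound code, isomer, phase)``.  When the model carries no
    base energy for a record's (isomer, phase) block, the block's reference-
    compound record (if present in ``records``) supplies it; otherwise an
    :class:`AdditivityConfigError` is raised.
    """
    records = list(records)
    for rec in records:
        key = (rec.isomer, rec.phase)
        if key not in model.base_energies and rec.compound.code == model.reference_code:
            model.base_energies[key] = rec.opt_e
    table: dict[tuple[str, str, str], StericRow] = {}
    for rec in records:
        n_n, n_c = substitution_counts(rec.compound)
        add_e = additive_energy(model, rec.compound, rec.isomer, rec.phase)
        key = (rec.compound.code, rec.isomer, rec.phase)
        if key in table:
            raise ValueError(f"duplicate record for {key}")
        table[key] = StericRow(
            compound=rec.compound,
            isomer=rec.isomer,
            phase=rec.phase,
            opt_e=rec.opt_e,
            n_n=n_n,
            n_c=n_c,
            add_e=add_e,
            st_e=steric_energy(rec.opt_e, add_e),
        )
    return table
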