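"""Conformer energy records: the common currency between modules."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .compounds import Compound
from .geometry import DihedralSet
from .io import Structure

__all__ = ["ConformerRecord", "ISOMERS", "PHASES"]

ISOMERS = ("trans", "cis")
PHASES = ("gas", "water")


@dataclass
class ConformerRecord:
    """One optimized minimum-energy conformer.

    ``opt_e`` is the optimized electronic energy in kcal/mol.  The solvation
    energy is meaningful only for water-phase records; supplying one for a
    gas-phase record is rejected.  Dihedrals, dipole (Debye) and Cartesian
    structure are optional payloads.
    """

    compound: Compound
    isomer: str
    phase: str
    opt_e: float
    solvation_e: float | None = None
    dipole: float | None = None
    dihedrals: DihedralSet | None = None
    structure: Structure | None = None

    def __post_init__(self) -> None:
        if self.isomer not in ISOMERS:
            raise ValueError(f"isomer must be one of {ISOMERS}, got {self.isomer!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not math.isfinite(self.opt_e):
            raise ValueError(f"opt_e must be finite, got {self.opt_e!r}")
        if self.solvation_e is not None and self.phase != "water":
            raise ValueError("solvation energy is only defined for the water phase")

    @property
    def label(self) -> str:
        """Code with isomer suffix, e.g. ``"N1110t"``."""
        return self.compound.code + ("t" if self.isomer == "trans" else "c")
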