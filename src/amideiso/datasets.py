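"""Access to the packaged reference tables (tab-separated fixtures).

The package ships, as plain TSV, the published B3LYP results for GGMe and
its nine tert-butyl derivatives: minimum-energy backbone dihedrals,
small-molecule energies defining the group increments, optimized/additive/
steric energies for both isomers and phases, cis-relative energies, and
the directional rotation-barrier tables.  Functions here return them as
typed rows, conformer records, or ready-to-use model objects.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .additivity import AdditivityModel, GroupIncrement, derive_increment
from .compounds import parse_compound_code, parse_labeled_code
from .energetics import BarrierEntry
from .io import EnergyTableRow, load_energy_table
from .records import ConformerRecord

__all__ = [
    "TABLE_FILES",
    "table_path",
    "load_table",
    "conformer_records",
    "increment_pairs",
    "build_model",
    "barrier_entries",
]

#: name -> (packaged file, loader schema)
TABLE_FILES: dict[str, tuple[str, str]] = {
    "compounds": ("compounds.tsv", "compounds"),
    "dihedrals_minimum_energy": ("dihedrals_minimum_energy.tsv", "dihedrals"),
    "increments_gas": ("increments_gas.tsv", "increments"),
    "increments_water": ("increments_water.tsv", "increments"),
    "steric_trans_gas": ("steric_trans_gas.tsv", "steric"),
    "steric_trans_water": ("steric_trans_water.tsv", "steric"),
    "steric_cis_gas": ("steric_cis_gas.tsv", "steric"),
    "steric_cis_water": ("steric_cis_water.tsv", "steric"),
    "cis_relative_gas": ("cis_relative_gas.tsv", "cis_relative"),
    "cis_relative_water": ("cis_relative_water.tsv", "cis_relative"),
    "barriers_gas": ("barriers_gas.tsv", "barriers"),
    "barriers_water": ("barriers_water.tsv", "barriers"),
}

_STERIC_TABLES = {
    ("trans", "gas"): "steric_trans_gas",
    ("trans", "water"): "steric_trans_water",
    ("cis", "gas"): "steric_cis_gas",
    ("cis", "water"): "steric_cis_water",
}


def table_path(name: str) -> Path:
    """Filesystem path of a packaged table."""
    if name not in TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; known: {sorted(TABLE_FILES)}")
    fname, _ = TABLE_FILES[name]
    return Path(str(resources.files("amideiso.data").joinpath(fname)))


def load_table(name: str) -> list[EnergyTableRow]:
    """Load a packaged table by name under its schema."""
    fname, schema = TABLE_FILES[name] if name in TABLE_FILES else (None, None)
    if fname is None:
        raise KeyError(f"unknown table {name!r}; known: {sorted(TABLE_FILES)}")
    return load_energy_table(table_path(name), schema)


def conformer_records(isomer: str, phase: str) -> list[ConformerRecord]:
    """Conformer records (optE, solvation energy where given) for one block."""
    key = (isomer, phase)
    if key not in _STERIC_TABLES:
        raise ValueError(f"no packaged table for isomer={isomer!r}, phase={phase!r}")
    # cis-water solvation energies are printed alongside the relative
    # energies rather than in the steric table; join them in by code
    extra_solv: dict[str, float | None] = {}
    if key == ("cis", "water"):
        for row in load_table("cis_relative_water"):
            compound, _ = parse_labeled_code(row.code)
            extra_solv[compound.code] = row.get("solvationE")
    records = []
    for row in load_table(_STERIC_TABLES[key]):
        compound, row_isomer = parse_labeled_code(row.code)
        if row_isomer != isomer:
            raise ValueError(f"row {row.code!r} disagrees with table isomer {isomer!r}")
        solvation = None
        if phase == "water":
            solvation = row.get("solvationE")
            if solvation is None:
                solvation = extra_solv.get(compound.code)
        records.append(
            ConformerRecord(
                compound=compound,
                isomer=isomer,
                phase=phase,
                opt_e=row["optE"],
                solvation_e=solvation,
            )
        )
    return records


def increment_pairs(phase: str) -> dict[str, tuple[float, float, float]]:
    """Small-molecule energy pairs defining the group increments.

    Maps attachment class to ``(parent_optE, substituted_optE, printed
    increment)`` for the requested phase.
    """
    name = {"gas": "increments_gas", "water": "increments_water"}[phase]
    out = {}
    for row in load_table(name):
        out[row.code] = (
            row["parent_optE"],
            row["substituted_optE"],
            row["Etb_printed"],
        )
    return out


def build_model(phases: tuple[str, ...] = ("gas", "water")) -> AdditivityModel:
    """Additivity model with increments re-derived from the packaged
    small-molecule energies (not the printed increment column)."""
    model = AdditivityModel()
    for phase in phases:
        for attachment, (parent_e, substituted_e, _printed) in increment_pairs(phase).items():
            model.add_increment(
                GroupIncrement(
                    attachment=attachment,
                    phase=phase,
                    value=derive_increment(parent_e, substituted_e),
                )
            )
    return model


def barrier_entries(
    phase: str,
) -> dict[str, tuple[dict[tuple[str, str], BarrierEntry | None], float]]:
    """Directional barrier entries and the printed effective barrier.

    Maps compound code to ``(entries, printed dG_eff)`` where ``entries``
    is keyed ``(type, direction)`` and not-determined entries are ``None``.
    """
    name = {"gas": "barriers_gas", "water": "barriers_water"}[phase]
    out = {}
    for row in load_table(name):
        code = parse_compound_code(row.code).code  # canonical ASCII prime
        entries: dict[tuple[str, str], BarrierEntry | None] = {}
        for kind in ("anti", "syn"):
            for direction, suffix in (("+", "plus"), ("-", "minus")):
                d_e = row.get(f"dE_{kind}_{suffix}")
                d_g = row.get(f"dG_{kind}_{suffix}")
                if d_e is None and d_g is None:
                    entries[(kind, direction)] = None
                else:
                    entries[(kind, direction)] = BarrierEntry(d_e=d_e, d_g=d_g)
        out[code] = (entries, row["dG_eff"])
    return out
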