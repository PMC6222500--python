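"""Structures, XYZ reading/writing, and delimited energy-table loading.

Energies are handled in kcal/mol throughout the package;
:data:`HARTREE_TO_KCAL` is provided for ingesting raw quantum-chemistry
output, but no QM file format beyond plain XYZ is parsed here.

Table fixtures are tab-separated text mirroring printed tables: cells may
carry thousands separators, the typographic minus (U+2212), blank cells for
structurally absent values and ``ND`` ("not determined") markers.  The loader
normalizes all of these; ``ND`` and blank cells become ``None``, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "Structure",
    "XyzFormatError",
    "read_xyz",
    "write_xyz",
    "EnergyTableRow",
    "TableSchemaError",
    "TABLE_SCHEMAS",
    "load_energy_table",
]

#: CODATA-derived conversion used when ingesting hartree energies.
HARTREE_TO_KCAL = 627.5094740631


# ---------------------------------------------------------------------------
# Structures and XYZ


@dataclass
class Structure:
    """An ordered list of atoms with Cartesian coordinates in Angstrom."""

    atoms: list[tuple[str, float, float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure requires at least one atom")
        for i, (el, x, y, z) in enumerate(self.atoms):
            if not all(map(_finite, (x, y, z))):
                raise ValueError(f"non-finite coordinate on atom {i} ({el})")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self):
        import numpy as np

        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [el for el, *_ in self.atoms]


def _finite(v: float) -> bool:
    return v == v and abs(v) != float("inf")


class XyzFormatError(ValueError):
    """Malformed XYZ input; the message carries the 1-based line number."""


def read_xyz(path: str | Path) -> Structure:
    """Read a single-frame XYZ file.

    Standard dialect: an atom-count line, a comment line, then one
    ``element x y z`` line per atom.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise XyzFormatError(f"{path}: line 1: missing atom count")
    try:
        natoms = int(lines[0].strip())
    except ValueError:
        raise XyzFormatError(
            f"{path}: line 1: atom count {lines[0].strip()!r} is not an integer"
        ) from None
    if natoms < 1:
        raise XyzFormatError(f"{path}: line 1: atom count must be >= 1")
    if len(lines) < 2 + natoms:
        raise XyzFormatError(
            f"{path}: header declares {natoms} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines are present"
        )
    label = lines[1].strip()
    atoms: list[tuple[str, float, float, float]] = []
    for i in range(natoms):
        lineno = 3 + i
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise XyzFormatError(
                f"{path}: line {lineno}: expected 'element x y z', got {lines[2 + i]!r}"
            )
        el = parts[0]
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise XyzFormatError(
                f"{path}: line {lineno}: non-numeric coordinate in {parts[1:4]!r}"
            ) from None
        atoms.append((el, x, y, z))
    return Structure(atoms=atoms, label=label)


def write_xyz(structure: Structure, path: str | Path) -> None:
    """Write a Structure as XYZ; coordinates keep 6 decimals (round-trip safe)."""
    path = Path(path)
    out = [str(len(structure)), structure.label]
    for el, x, y, z in structure.atoms:
        out.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Delimited energy tables


class TableSchemaError(ValueError):
    """A fixture/table file does not satisfy the requested schema."""


@dataclass
class EnergyTableRow:
    """One typed row of a delimited energy table.

    ``values`` maps header names (preserved verbatim from the file) to
    floats, ``None`` (blank or ``ND`` cell) or pass-through text.
    """

    code: str
    values: dict[str, object] = field(default_factory=dict)

    def get(self, column: str, default: object = None) -> object:
        return self.values.get(column, default)

    def __getitem__(self, column: str) -> object:
        return self.values[column]


def _schema(required: Sequence[str], numeric: Sequence[str], key: str = "compound"):
    return {"required": tuple(required), "numeric": tuple(numeric), "key": key}


#: Known table layouts.  ``required`` columns must exist; ``numeric`` columns
#: are parsed to float where non-absent.
TABLE_SCHEMAS: Mapping[str, Mapping[str, object]] = {
    "compounds": _schema(["compound", "R1", "R2", "R3"], []),
    "dihedrals": _schema(
        ["compound"],
        [
            "psiN_gas", "omega_gas", "phiC_gas", "psiC_gas",
            "psiN_water", "omega_water", "phiC_water", "psiC_water",
        ],
    ),
    "increments": _schema(
        ["attachment", "parent_optE", "substituted_optE"],
        ["parent_optE", "substituted_optE", "Etb_printed"],
        key="attachment",
    ),
    "steric": _schema(
        ["compound", "optE", "n_tBu_N", "n_tBu_C", "AddE", "stE"],
        ["solvationE", "optE", "n_tBu_N", "n_tBu_C", "AddE", "stE"],
    ),
    "cis_relative": _schema(
        ["compound", "dE", "dG"],
        ["solvationE", "psiN", "omega", "phiC", "psiC", "dE", "dG"],
    ),
    "barriers": _schema(
        ["compound", "dG_eff"],
        [
            "dE_anti_plus", "dG_anti_plus", "dE_anti_minus", "dG_anti_minus",
            "dE_syn_plus", "dG_syn_plus", "dE_syn_minus", "dG_syn_minus",
            "dG_eff",
        ],
    ),
}

_ABSENT = {"", "ND", "nd", "N.D.", "—"}


def _clean_cell(raw: str) -> str:
    return raw.strip().replace("−", "-").replace(",", "")


def parse_numeric_cell(raw: str) -> float | None:
    """Normalize one printed numeric cell; absent markers give ``None``."""
    s = raw.strip()
    if s in _ABSENT:
        return None
    return float(_clean_cell(s))


def load_energy_table(path: str | Path, schema: str) -> list[EnergyTableRow]:
    """Load a tab-separated energy table under a named schema.

    Raises
    ------
    TableSchemaError
        For an unknown schema name, an empty file, a missing required
        column, or an unparsable numeric cell.
    """
    if schema not in TABLE_SCHEMAS:
        raise TableSchemaError(
            f"unknown table schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}"
        )
    spec = TABLE_SCHEMAS[schema]
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableSchemaError(f"{path}: empty table file") from None
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise TableSchemaError(f"{path}: table has a header but no rows")
    rows: list[EnergyTableRow] = []
    for idx, rec in df.iterrows():
        values: dict[str, object] = {}
        for col in df.columns:
            raw = rec[col]
            if col in spec["numeric"]:
                try:
                    values[col] = parse_numeric_cell(raw)
                except ValueError:
                    raise TableSchemaError(
                        f"{path}: row {idx + 1}, column {col!r}: "
                        f"cannot parse {raw!r} as a number"
                    ) from None
            else:
                values[col] = raw.strip()
        rows.append(EnergyTableRow(code=str(rec[spec["key"]]).strip(), values=values))
    return rows


def iter_column(rows: Iterable[EnergyTableRow], column: str):
    """Yield ``(code, value)`` pairs for one column of a loaded table."""
    for row in rows:
        yield row.code, row.get(column)
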