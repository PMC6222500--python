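"""Backbone torsions, amide-planarity and H-bond tests, rigid superposition.

Torsions follow the IUPAC sign convention (positive clockwise looking from
the second to the third atom) and are reported in degrees in the half-open
interval (-180, 180], with 180 preferred over -180 (matching the usual
"-179.7 / 178.3" style of reported backbone dihedrals).

The amide torsion omega measures planarity: the deviation is the angular
distance to the nearer of 0 (cis) and 180 (trans), and a conformer is
flagged as distorted when that deviation exceeds a tolerance (default 5
degrees).  The intramolecular H-bond between the amino nitrogen and the
amide hydrogen is a pure distance criterion, present when the N...H
distance is at most the cutoff (default 2.3 Angstrom, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Structure

__all__ = [
    "DihedralSet",
    "AtomMap",
    "GeometryError",
    "dihedral",
    "backbone_dihedrals",
    "planarity_deviation",
    "is_distorted",
    "hbond_present",
    "superpose",
    "min_group_distance",
    "wrap_angle",
    "angular_distance",
    "PLANARITY_TOLERANCE",
    "HBOND_CUTOFF",
]

#: Default amide-planarity tolerance, degrees.
PLANARITY_TOLERANCE = 5.0
#: Default N...H hydrogen-bond distance cutoff, Angstrom (inclusive).
HBOND_CUTOFF = 2.3

_DIHEDRAL_NAMES = ("psiN", "omega", "phiC", "psiC")


class GeometryError(ValueError):
    """Degenerate geometric input (collinear torsion, bad alignment set...)."""


@dataclass(frozen=True)
class DihedralSet:
    """The four backbone torsions flanking the amide bond, in degrees.

    ``psiN`` and ``omega`` belong to the N-terminal residue; ``phiC`` and
    ``psiC`` to the C-terminal (ester) residue.  All values are wrapped to
    (-180, 180].
    """

    psiN: float
    omega: float
    phiC: float
    psiC: float

    def __post_init__(self) -> None:
        for name in _DIHEDRAL_NAMES:
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} = {v} outside (-180, 180]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _DIHEDRAL_NAMES}


@dataclass
class AtomMap:
    """0-based atom indices naming the backbone quadruples of a Structure.

    ``torsions`` maps each dihedral name (psiN, omega, phiC, psiC) to its
    four atom indices.  ``hbond_donor`` / ``amide_h`` locate the amino
    nitrogen and the amide hydrogen for the H-bond test; ``amide_frame``
    lists the atoms used to align structures at the amide moiety.
    """

    torsions: Mapping[str, tuple[int, int, int, int]]
    hbond_donor: int | None = None
    amide_h: int | None = None
    amide_frame: tuple[int, ...] = field(default_factory=tuple)

    def validate(self, structure: Structure) -> None:
        n = len(structure)
        for name in _DIHEDRAL_NAMES:
            if name not in self.torsions:
                raise ValueError(f"AtomMap missing torsion {name!r}")
            quad = self.torsions[name]
            if len(quad) != 4 or len(set(quad)) != 4:
                raise ValueError(f"torsion {name!r}: indices {quad} not 4 distinct atoms")
            if any(not (0 <= i < n) for i in quad):
                raise ValueError(f"torsion {name!r}: index out of bounds for {n} atoms")
        for idx in (self.hbond_donor, self.amide_h):
            if idx is not None and not (0 <= idx < n):
                raise ValueError(f"atom index {idx} out of bounds for {n} atoms")


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180], preferring +180 over -180."""
    w = (float(deg) + 180.0) % 360.0 - 180.0
    if w == -180.0:
        w = 180.0
    return w


def angular_distance(a: float, b: float) -> float:
    """Unsigned angular separation of two angles in degrees, in [0, 180]."""
    return abs(wrap_angle(a - b))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in (-180, 180].

    Raises :class:`GeometryError` when either bonded triple is collinear
    (the torsion is then undefined) or consecutive points coincide.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise GeometryError("central bond is degenerate (p2 == p3)")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1)
    norm2 = np.linalg.norm(n2)
    if norm1 < 1e-10 * max(np.linalg.norm(b1) * np.linalg.norm(b2), 1e-30):
        raise GeometryError("p1, p2, p3 are collinear: torsion undefined")
    if norm2 < 1e-10 * max(np.linalg.norm(b2) * np.linalg.norm(b3), 1e-30):
        raise GeometryError("p2, p3, p4 are collinear: torsion undefined")
    # atan2 formulation: numerically stable for near 0/180 torsions
    b2_hat = b2 / np.linalg.norm(b2)
    ang = np.degrees(np.arctan2(np.dot(b2_hat, np.cross(n1, n2)), np.dot(n1, n2)))
    return wrap_angle(ang)


def backbone_dihedrals(structure: Structure, atom_map: AtomMap) -> DihedralSet:
    """Compute the four named backbone torsions of a structure."""
    atom_map.validate(structure)
    xyz = structure.coords()
    values = {}
    for name in _DIHEDRAL_NAMES:
        quad = atom_map.torsions[name]
        try:
            values[name] = dihedral(*(xyz[i] for i in quad))
        except GeometryError as exc:
            raise GeometryError(f"torsion {name!r}: {exc}") from exc
    return DihedralSet(**values)


def planarity_deviation(omega: float) -> float:
    """Angular distance of omega to the nearer of 0 (cis) and 180 (trans).

    The same rule serves cis and trans conformers; the result lies in
    [0, 90].
    """
    if not (-180.0 < omega <= 180.0):
        raise ValueError(f"omega = {omega} outside (-180, 180]")
    return min(angular_distance(omega, 0.0), angular_distance(omega, 180.0))


def is_distorted(omega: float, tolerance: float = PLANARITY_TOLERANCE) -> bool:
    """True when the amide plane is twisted beyond ``tolerance`` degrees."""
    return planarity_deviation(omega) > tolerance


def hbond_present(dist_nh: float, cutoff: float = HBOND_CUTOFF) -> bool:
    """Distance-only H-bond criterion, inclusive at the cutoff."""
    if dist_nh < 0:
        raise ValueError(f"distance must be non-negative, got {dist_nh}")
    return dist_nh <= cutoff


def superpose(
    mobile: Structure,
    ref: Structure,
    index_pairs: Sequence[tuple[int, int]],
) -> tuple[float, Structure]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    ``index_pairs`` lists ``(mobile_index, ref_index)`` atom pairs; at least
    three non-collinear pairs are required.  Only proper rotations are
    allowed (no reflection — chirality is preserved).  Returns the RMSD over
    the paired atoms and a transformed copy carrying every atom of
    ``mobile``.
    """
    if len(index_pairs) < 3:
        raise GeometryError("superposition needs at least 3 atom pairs")
    mob_xyz = mobile.coords()
    ref_xyz = ref.coords()
    mi = np.array([p[0] for p in index_pairs])
    ri = np.array([p[1] for p in index_pairs])
    if mi.max() >= len(mobile) or ri.max() >= len(ref):
        raise GeometryError("index pair out of bounds")
    a = mob_xyz[mi]
    b = ref_xyz[ri]
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    # rank < 2 means the paired atoms are collinear (or coincident)
    if np.linalg.matrix_rank(b_c, tol=1e-8) < 2 or np.linalg.matrix_rank(a_c, tol=1e-8) < 2:
        raise GeometryError("paired atoms are collinear: alignment is degenerate")
    rot, _ = Rotation.align_vectors(b_c, a_c)  # proper rotation only
    moved = rot.apply(mob_xyz - a.mean(axis=0)) + b.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[mi] - b) ** 2, axis=1))))
    transformed = Structure(
        atoms=[
            (el, float(x), float(y), float(z))
            for el, (x, y, z) in zip(mobile.elements(), moved)
        ],
        label=mobile.label,
    )
    return rmsd, transformed


def min_group_distance(
    structure: Structure,
    group_a: Sequence[int],
    group_b: Sequence[int],
) -> float:
    """Minimum pairwise Euclidean distance between two disjoint atom groups."""
    if not len(group_a) or not len(group_b):
        raise ValueError("both atom groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("atom groups must be disjoint")
    xyz = structure.coords()
    a = xyz[np.asarray(group_a, dtype=int)]
    b = xyz[np.asarray(group_b, dtype=int)]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())
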