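"""Ground-truth-known synthetic inputs for every analysis stage.

Three generators:

* Fourier torsional potentials — double-well energy profiles over the amide
  torsion with wells near 0 (cis) and 180 (trans) and direction-dependent
  barriers, emulating the shape of a relaxed scan along omega.  A dense-grid
  :func:`ground_truth` provides oracle well/barrier positions for testing
  the scan driver.
* Additive conformer-energy tables — base energy + group increments +
  injected non-negative steric offsets, emulating the statistical structure
  of the optimized-energy tables (an additive baseline plus positive steric
  strain growing with substitution count).
* Idealized dipeptide-ester backbone fragments built by internal-coordinate
  (NeRF) placement with prescribed backbone dihedrals, for round-trip tests
  of the torsion code.  Bond lengths and angles are fixed canonical values;
  these fragments are geometric test bodies, not energetic models.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compounds import PAPER_CODES, parse_compound_code, substitution_counts
from .geometry import AtomMap, DihedralSet, wrap_angle
from .io import Structure
from .records import ConformerRecord
from .scan import EnergyBackend

__all__ = [
    "FourierTerm",
    "TorsionPotentialSpec",
    "GroundTruth",
    "BarrierTruth",
    "SyntheticTableSpec",
    "make_potential",
    "ground_truth",
    "make_energy_table",
    "make_backbone_fragment",
    "random_potential_spec",
]


# ---------------------------------------------------------------------------
# Torsional potentials


@dataclass(frozen=True)
class FourierTerm:
    """One cosine term: V/2 * (1 - cos(k*(omega - gamma)))."""

    k: int
    v: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("Fourier order k must be a positive integer")


@dataclass(frozen=True)
class TorsionPotentialSpec:
    """A torsional potential as a sum of Fourier terms plus an offset.

    At least one term must have order k >= 2 so the potential can carry the
    two wells of a cis/trans pair.
    """

    terms: tuple[FourierTerm, ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("potential spec needs at least one Fourier term")
        if not any(t.k >= 2 for t in self.terms):
            raise ValueError("potential needs a term with k >= 2 for a double well")


def make_potential(spec: TorsionPotentialSpec, name: str = "synthetic", phase: str = "gas") -> EnergyBackend:
    """Build a deterministic, 360-periodic energy backend from a spec."""
    terms = spec.terms
    offset = spec.offset

    def evaluate(omega):
        omega = np.asarray(omega, dtype=float)
        e = np.zeros_like(omega) + offset
        for t in terms:
            e = e + 0.5 * t.v * (1.0 - np.cos(np.radians(t.k * (omega - t.gamma))))
        return e if e.ndim else float(e)

    return EnergyBackend(evaluate=evaluate, name=name, phase=phase)


@dataclass(frozen=True)
class BarrierTruth:
    """Oracle barrier for one (start isomer, direction) arc."""

    omega: float
    e_abs: float
    rel_start: float
    rel_trans: float


@dataclass
class GroundTruth:
    """Dense-grid oracle description of a double-well torsional potential."""

    omega_min_trans: float
    omega_min_cis: float
    e_min_trans: float
    e_min_cis: float
    barriers: dict[tuple[str, str], BarrierTruth] = field(default_factory=dict)


def ground_truth(spec: TorsionPotentialSpec, grid_step: float = 0.001) -> GroundTruth:
    """Oracle well and barrier locations by dense grid + quadratic refinement.

    The grid step (default 0.001 degrees) sits far below any scan step, so
    oracle error is negligible when comparing scan output against it.  The
    potential must have exactly two interior minima per period.
    """
    backend = make_potential(spec)
    n = int(round(360.0 / grid_step))
    omegas = -180.0 + grid_step * np.arange(n)
    energies = np.asarray(backend.evaluate(omegas))

    prev_e = np.roll(energies, 1)
    next_e = np.roll(energies, -1)
    is_min = (energies < prev_e) & (energies <= next_e)
    minima_idx = np.flatnonzero(is_min)
    if len(minima_idx) != 2:
        raise ValueError(
            f"potential has {len(minima_idx)} minima on the grid, need exactly 2"
        )

    def refine(idx: int) -> tuple[float, float]:
        # parabola through the grid point and its periodic neighbours
        om = omegas[idx]
        e0, e1, e2 = energies[(idx - 1) % n], energies[idx], energies[(idx + 1) % n]
        denom = e0 - 2.0 * e1 + e2
        if abs(denom) < 1e-300:
            return float(om), float(e1)
        delta = 0.5 * (e0 - e2) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        om_ref = om + delta * grid_step
        e_ref = e1 - 0.25 * (e0 - e2) * delta
        return float(om_ref), float(e_ref)

    mins = [refine(i) for i in minima_idx]
    # trans well is the one nearer 180, cis the one nearer 0
    d_trans = [min(abs(wrap_angle(om - 180.0)), 180.0) for om, _ in mins]
    trans_i = int(np.argmin(d_trans))
    (om_t, e_t) = mins[trans_i]
    (om_c, e_c) = mins[1 - trans_i]

    gt = GroundTruth(
        omega_min_trans=wrap_angle(om_t),
        omega_min_cis=wrap_angle(om_c),
        e_min_trans=e_t,
        e_min_cis=e_c,
    )

    for start_isomer, start, e_start in (("trans", om_t, e_t), ("cis", om_c, e_c)):
        for direction, sgn in (("+", 1.0), ("-", -1.0)):
            delta = (sgn * (omegas - start)) % 360.0
            mask = (delta > grid_step) & (delta < 180.0 - grid_step)
            arc_idx = np.flatnonzero(mask)
            peak = arc_idx[int(np.argmax(energies[arc_idx]))]
            om_b, e_b = refine(int(peak))
            gt.barriers[(start_isomer, direction)] = BarrierTruth(
                omega=wrap_angle(om_b),
                e_abs=e_b,
                rel_start=e_b - e_start,
                rel_trans=e_b - e_t,
            )
    return gt


def random_potential_spec(rng: np.random.Generator) -> TorsionPotentialSpec:
    """Draw a random double-well spec with wells near 0/180.

    A dominant 2-fold term carries the double well; weak 1- and 3-fold
    terms tilt the wells (trans bias) and skew the two barriers so the +
    and - directions differ.
    """
    v2 = rng.uniform(8.0, 16.0)
    g2 = rng.normal(0.0, 2.0)
    v1 = rng.uniform(0.5, 3.0)
    g1 = 180.0 + rng.normal(0.0, 15.0)
    v3 = rng.uniform(0.0, 1.5)
    g3 = rng.uniform(0.0, 360.0)
    return TorsionPotentialSpec(
        terms=(
            FourierTerm(2, float(v2), float(g2)),
            FourierTerm(1, float(v1), float(g1)),
            FourierTerm(3, float(v3), float(g3)),
        )
    )


# ---------------------------------------------------------------------------
# Additive energy tables with injected steric offsets

#: Reference-compound base energies per (isomer, phase), kcal/mol — the
#: optimized GGMe energies used as the default additive baseline.
DEFAULT_BASE_ENERGIES: dict[tuple[str, str], float] = {
    ("trans", "gas"): -333806.071,
    ("cis", "gas"): -333801.441,
    ("trans", "water"): -381811.506,
    ("cis", "water"): -333819.556,
}

#: Default tert-butyl group increments per (attachment, phase), kcal/mol.
DEFAULT_INCREMENTS: dict[tuple[str, str], float] = {
    ("sp3-N", "gas"): -98709.131,
    ("sp3-C", "gas"): -98712.134,
    ("sp3-N", "water"): -98707.646,
    ("sp3-C", "water"): -98711.962,
}


@dataclass
class SyntheticTableSpec:
    """Recipe for an additive conformer-energy table with known strain.

    ``offsets`` maps ``(code, isomer, phase)`` to an injected steric
    offset; entries not given are drawn half-normal (scale
    ``offset_scale`` kcal/mol, non-negative like real steric strain) for
    substituted compounds and fixed at 0 for the reference compound.
    """

    base_energies: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_ENERGIES)
    )
    increments: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_INCREMENTS)
    )
    offsets: dict[tuple[str, str, str], float] = field(default_factory=dict)
    isomers: tuple[str, ...] = ("trans", "cis")
    phases: tuple[str, ...] = ("gas", "water")
    codes: tuple[str, ...] = PAPER_CODES
    offset_scale: float = 4.0
    seed: int = 0


def make_energy_table(
    spec: SyntheticTableSpec,
) -> tuple[list[ConformerRecord], dict[tuple[str, str, str], float]]:
    """Generate conformer records with known injected steric offsets.

    Returns the records and the offset map actually used (the recovery
    target for a steric-table analysis).  optE = base + nN*E_tb^N +
    nC*E_tb^C + offset.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ConformerRecord] = []
    used: dict[tuple[str, str, str], float] = {}
    for phase in spec.phases:
        for isomer in spec.isomers:
            base = spec.base_energies[(isomer, phase)]
            for code in spec.codes:
                compound = parse_compound_code(code)
                n_n, n_c = substitution_counts(compound)
                key = (compound.code, isomer, phase)
                if compound.code == "N0000":
                    offset = 0.0
                elif key in spec.offsets:
                    offset = float(spec.offsets[key])
                else:
                    offset = float(abs(rng.normal(0.0, spec.offset_scale)))
                if offset < 0:
                    raise ValueError(f"steric offset for {key} must be >= 0")
                opt_e = (
                    base
                    + n_n * spec.increments[("sp3-N", phase)]
                    + n_c * spec.increments[("sp3-C", phase)]
                    + offset
                )
                used[key] = offset
                records.append(
                    ConformerRecord(
                        compound=compound, isomer=isomer, phase=phase, opt_e=opt_e
                    )
                )
    return records, used


# ---------------------------------------------------------------------------
# Backbone fragments by internal-coordinate construction

# canonical internal coordinates (Angstrom, degrees); only dihedrals vary
_BOND_N_CA = 1.47
_BOND_CA_C = 1.52
_BOND_C_N = 1.33
_BOND_C_O = 1.23
_BOND_N_H = 1.01
_BOND_C_OE = 1.34  # ester C-O
_BOND_O_C = 1.44  # ester O-CH3
_ANGLE_SP3 = 109.5
_ANGLE_SP2 = 120.0


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C with angle B-C-D and torsion A-B-C-D (NeRF)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("collinear reference frame in internal-coordinate placement")
    n /= n_norm
    m = np.cross(n, bc)
    # sign of the n-component fixes the handedness so that the torsion
    # A-B-C-D measured back from the coordinates equals `torsion`
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_backbone_fragment(dihedrals: DihedralSet) -> tuple[Structure, AtomMap]:
    """Build a minimal dipeptide-ester backbone with prescribed dihedrals.

    Atom order: N1, CA1, C1, N2, CA2, C2, O3, CMe (the eight-atom main
    chain), then the carbonyl oxygen on C1 and the amide hydrogen on N2.
    The four named torsions are carried by consecutive main-chain
    quadruples, so ``backbone_dihedrals`` on the returned structure and map
    round-trips the requested values.
    """
    coords = np.zeros((10, 3))
    # seed triad: N1 at origin, CA1 on x, C1 in the xy-plane
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (_BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _ANGLE_SP3)
    coords[2] = coords[1] + _BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    chain_spec = [
        # (frame a, b, c), bond, angle, torsion
        ((0, 1, 2), _BOND_C_N, _ANGLE_SP2, dihedrals.psiN),   # N2
        ((1, 2, 3), _BOND_N_CA, _ANGLE_SP2, dihedrals.omega),  # CA2
        ((2, 3, 4), _BOND_CA_C, _ANGLE_SP3, dihedrals.phiC),   # C2
        ((3, 4, 5), _BOND_C_OE, _ANGLE_SP2, dihedrals.psiC),   # O3 (ester O)
        ((4, 5, 6), _BOND_O_C, _ANGLE_SP2, 180.0),             # CMe
    ]
    for i, ((a, b, c), bond, angle, torsion) in enumerate(chain_spec, start=3):
        coords[i] = _place_nerf(coords[a], coords[b], coords[c], bond, angle, torsion)

    # decorations: carbonyl O anti to N2 across C1; amide H anti to CA2
    coords[8] = _place_nerf(
        coords[0], coords[1], coords[2], _BOND_C_O, _ANGLE_SP2,
        wrap_angle(dihedrals.psiN + 180.0),
    )
    coords[9] = _place_nerf(
        coords[1], coords[2], coords[3], _BOND_N_H, _ANGLE_SP2,
        wrap_angle(dihedrals.omega + 180.0),
    )

    elements = ["N", "C", "C", "N", "C", "C", "O", "C", "O", "H"]
    structure = Structure(
        atoms=[(el, float(x), float(y), float(z)) for el, (x, y, z) in zip(elements, coords)],
        label="synthetic dipeptide-ester backbone fragment",
    )
    atom_map = AtomMap(
        torsions={
            "psiN": (0, 1, 2, 3),
            "omega": (1, 2, 3, 4),
            "phiC": (2, 3, 4, 5),
            "psiC": (3, 4, 5, 6),
        },
        hbond_donor=0,
        amide_h=9,
        amide_frame=(1, 2, 3, 4),
    )
    return structure, atom_map
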