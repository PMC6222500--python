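"""Torsion math, planarity rule, H-bond criterion, superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from amideiso import (
    GeometryError,
    Structure,
    dihedral,
    hbond_present,
    is_distorted,
    min_group_distance,
    planarity_deviation,
    superpose,
)
from amideiso import datasets

from conftest import canonical


def torsion_oracle(p1, p2, p3, p4):
    """Independent torsion formulation: projection onto the central-bond plane."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


def random_quadruple(rng):
    while True:
        pts = rng.normal(size=(4, 3)) * 3.0
        b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
        if (np.linalg.norm(np.cross(b1, b2)) > 1e-3
                and np.linalg.norm(np.cross(b2, b3)) > 1e-3):
            return pts


# ---------------------------------------------------------------------------
# dihedral


def test_eclipsed_and_anti_planar_cases():
    assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-12)
    assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)


def test_dihedral_matches_independent_oracle(rng):
    for _ in range(100):
        pts = random_quadruple(rng)
        mine = dihedral(*pts)
        ref = torsion_oracle(*pts)
        assert abs((mine - ref + 180.0) % 360.0 - 180.0) < 1e-9


def test_collinear_points_are_rejected():
    with pytest.raises(GeometryError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))
    with pytest.raises(GeometryError):
        dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (2, 0, 0))
    with pytest.raises(GeometryError):  # degenerate central bond
        dihedral((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 0, 0))


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10**9))
def test_dihedral_rigid_motion_invariance_and_symmetries(seed):
    """Invariant under rigid motion; symmetric under reversal; mirror negates."""
    rng = np.random.default_rng(seed)
    pts = random_quadruple(rng)
    base = dihedral(*pts)
    rot = Rotation.random(random_state=np.random.RandomState(seed % 2**31))
    shift = rng.normal(size=3) * 10
    moved = rot.apply(pts) + shift
    assert abs(dihedral(*moved) - base) < 1e-9 or abs(abs(dihedral(*moved)) - 180.0) < 1e-9
    # full reversal of the point order preserves the IUPAC torsion
    assert dihedral(*pts[::-1]) == pytest.approx(base, abs=1e-9)
    # mirror reflection negates it
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-9) or (
        abs(base) == pytest.approx(180.0, abs=1e-9)
    )


# ---------------------------------------------------------------------------
# planarity


@pytest.mark.parametrize(
    "omega,deviation,distorted",
    [
        (169.5, 10.5, True),     # twisted trans amide
        (-177.9, 2.1, False),    # essentially planar trans
        (180.0, 0.0, False),
        (0.1, 0.1, False),       # near-planar cis
        (-8.5, 8.5, True),       # twisted cis
        (90.0, 90.0, True),
    ],
)
def test_planarity_deviation_and_flag(omega, deviation, distorted):
    assert planarity_deviation(omega) == pytest.approx(deviation, abs=1e-9)
    assert is_distorted(omega) is distorted


def test_planarity_deviation_range(rng):
    for omega in rng.uniform(-179.99, 180.0, 500):
        d = planarity_deviation(float(omega))
        assert 0.0 <= d <= 90.0


def test_distortion_flags_match_highlighted_conformers():
    """The >5-degree rule flags exactly the known twisted minimum-energy
    geometries: three in the gas phase, four in water."""
    expected = {
        "gas": {"N0110", "N1110", "N111'0"},
        "water": {"N0110", "N1100", "N1110", "N111'0"},
    }
    rows = datasets.load_table("dihedrals_minimum_energy")
    for phase in ("gas", "water"):
        flagged = {
            canonical(row.code)
            for row in rows
            if is_distorted(row[f"omega_{phase}"])
        }
        assert flagged == expected[phase]


# ---------------------------------------------------------------------------
# H-bond


@pytest.mark.parametrize("dist,present", [(2.0, True), (2.31, False), (2.30, True)])
def test_hbond_distance_criterion_inclusive_cutoff(dist, present):
    assert hbond_present(dist) is present


def test_hbond_negative_distance_rejected():
    with pytest.raises(ValueError):
        hbond_present(-0.1)


# ---------------------------------------------------------------------------
# superposition


def _structure(coords, element="C"):
    return Structure(atoms=[(element, *map(float, xyz)) for xyz in coords])


def _rmsd_at_rotation(rotvec, a, b):
    rot = Rotation.from_rotvec(rotvec)
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    return np.sqrt(np.mean(np.sum((rot.apply(a_c) - b_c) ** 2, axis=1)))


def rmsd_oracle(a, b, n_starts=40, seed=0):
    """Exhaustive multi-start minimization over rotation space."""
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=np.random.RandomState(int(s))).as_rotvec()
        for s in rng.integers(0, 2**31 - 1, n_starts)
    ]
    for x0 in starts:
        res = minimize(_rmsd_at_rotation, x0, args=(a, b), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_identical_structures_have_zero_rmsd(rng):
    coords = rng.normal(size=(6, 3)) * 4
    s = _structure(coords)
    rmsd, moved = superpose(s, s, [(i, i) for i in range(6)])
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(moved.coords(), coords, atol=1e-9)


def test_rigid_copy_superposes_exactly(rng):
    coords = rng.normal(size=(5, 3)) * 4
    rot = Rotation.random(random_state=np.random.RandomState(3))
    moved_coords = rot.apply(coords) + np.array([1.0, -2.0, 3.0])
    rmsd, back = superpose(_structure(moved_coords), _structure(coords),
                           [(i, i) for i in range(5)])
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(back.coords(), coords, atol=1e-8)


def test_superposition_matches_multistart_oracle(rng):
    for trial in range(5):
        a = rng.normal(size=(5, 3)) * 3
        b = rng.normal(size=(5, 3)) * 3
        rmsd, _ = superpose(_structure(a), _structure(b), [(i, i) for i in range(5)])
        assert rmsd == pytest.approx(rmsd_oracle(a, b, seed=trial), abs=1e-6)


def test_superposition_never_worse_than_identity(rng):
    for _ in range(10):
        a = rng.normal(size=(6, 3)) * 3
        b = a + rng.normal(size=(6, 3)) * 0.5
        rmsd, _ = superpose(_structure(a), _structure(b), [(i, i) for i in range(6)])
        identity_rmsd = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert rmsd <= identity_rmsd + 1e-12


def test_mirror_images_do_not_superpose_to_zero(rng):
    """The determinant guard forbids reflections: chirality is preserved."""
    a = rng.normal(size=(5, 3)) * 3
    mirrored = a * np.array([1.0, 1.0, -1.0])
    rmsd, _ = superpose(_structure(mirrored), _structure(a), [(i, i) for i in range(5)])
    assert rmsd > 0.1


def test_degenerate_alignment_sets_are_rejected():
    line = _structure([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
    with pytest.raises(GeometryError):
        superpose(line, line, [(0, 0), (1, 1)])
    with pytest.raises(GeometryError):
        superpose(line, line, [(0, 0), (1, 1), (2, 2)])


# ---------------------------------------------------------------------------
# group distances


def test_min_group_distance_simple_and_brute_force(rng):
    s = _structure([(0, 0, 0), (3, 0, 0)])
    assert min_group_distance(s, [0], [1]) == pytest.approx(3.0)
    coords = rng.normal(size=(12, 3)) * 5
    s = _structure(coords)
    ga, gb = [0, 2, 4, 6], [1, 3, 5, 7, 9]
    brute = min(np.linalg.norm(coords[i] - coords[j]) for i in ga for j in gb)
    assert min_group_distance(s, ga, gb) == pytest.approx(brute, abs=1e-12)


def test_group_distance_input_validation():
    s = _structure([(0, 0, 0), (1, 0, 0)])
    with pytest.raises(ValueError):
        min_group_distance(s, [], [1])
    with pytest.raises(ValueError):
        min_group_distance(s, [0, 1], [1])
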