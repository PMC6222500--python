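"""Directional relaxed-coordinate-scan (RCS) driver for the amide torsion.

The driver sweeps the amide torsion omega from a minimum-energy conformer
half a rotation (180 degrees) towards the opposite isomer, against a
pluggable 1-D energy backend.  Geometry relaxation at fixed omega — the
"relaxed" part of an RCS — is the backend's responsibility, so the driver
works identically over analytic test potentials and over any future
constrained-optimization backend.

Each scan runs in rounds of decreasing step size (default 15, 2 and
0.125 degrees in the gas phase; the final round is 0.25 degrees in the
water continuum).  After the coarse sweep, every later round re-scans a
window of plus/minus one previous-round step around the incumbent maximum,
so the peak can only be refined, never lost.  The highest point of the
profile is the energy-barrier geometry (EBG), a transition-state proxy;
it is classified *syn* when its omega lies nearer to +/-60 degrees and
*anti* when nearer to +/-120 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .geometry import angular_distance, wrap_angle

__all__ = [
    "EnergyBackend",
    "ScanSchedule",
    "ScanProfile",
    "EBG",
    "ScanError",
    "run_rcs",
    "find_ebg",
    "classify_ebg",
    "barrier_set",
    "DEFAULT_SCHEDULES",
]


class ScanError(RuntimeError):
    """Scan failure: bad start point, backend error, or flat/boundary profile."""


@dataclass
class EnergyBackend:
    """Deterministic, 360-periodic torsional energy function.

    ``evaluate`` maps omega (degrees) to an energy in kcal/mol.  For a
    constrained-optimization backend this is the relaxed energy at fixed
    omega; here it is typically an analytic potential.
    """

    evaluate: Callable[[float], float]
    name: str = "backend"
    phase: str = "gas"

    def __call__(self, omega: float) -> float:
        try:
            e = float(self.evaluate(omega))
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise ScanError(f"backend {self.name!r} failed at omega={omega:.4f}: {exc}") from exc
        if not math.isfinite(e):
            raise ScanError(f"backend {self.name!r} returned non-finite energy at omega={omega:.4f}")
        return e


@dataclass(frozen=True)
class ScanSchedule:
    """Round step sizes in degrees, coarse to fine, strictly decreasing."""

    steps: tuple[float, ...] = (15.0, 2.0, 0.125)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("schedule needs at least one round")
        if any(s <= 0 for s in self.steps):
            raise ValueError("step sizes must be positive")
        if any(b >= a for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("step sizes must be strictly decreasing")

    @property
    def final_step(self) -> float:
        return self.steps[-1]


DEFAULT_SCHEDULES: Mapping[str, ScanSchedule] = {
    "gas": ScanSchedule((15.0, 2.0, 0.125)),
    "water": ScanSchedule((15.0, 2.0, 0.25)),
}


@dataclass
class ScanProfile:
    """All points evaluated during one directional scan.

    Omegas are kept on the unwrapped scan axis (monotone along the scan
    direction, e.g. 180 -> 360 for a + scan from trans), so the profile is
    strictly monotone in the direction of travel.
    """

    direction: str
    start_isomer: str
    points: list[tuple[float, float]] = field(default_factory=list)
    backend_name: str = "backend"
    n_evaluations: int = 0

    @property
    def start_omega(self) -> float:
        return self.points[0][0]

    @property
    def start_energy(self) -> float:
        return self.points[0][1]


@dataclass(frozen=True)
class EBG:
    """A located energy-barrier geometry (transition-state proxy).

    ``omega_star`` is wrapped to (-180, 180]; ``e_star`` is the barrier
    height relative to the scan's starting conformer.  ``e_rel_trans`` is
    filled by :func:`barrier_set` when the scan started from the cis well
    and the height is re-referenced to the trans minimum.  ``kind`` is the
    proximity-based syn/anti classification; ``ambiguous`` marks the exact
    tie at |omega| = 90.
    """

    kind: str
    direction: str
    omega_star: float
    e_star: float
    ambiguous: bool = False
    e_rel_trans: float | None = None


def _sign(direction: str) -> int:
    if direction == "+":
        return 1
    if direction == "-":
        return -1
    raise ValueError(f"direction must be '+' or '-', got {direction!r}")


def classify_ebg(omega_star: float) -> tuple[str, bool]:
    """Classify a barrier position as syn (near +/-60) or anti (near +/-120).

    Returns ``(kind, ambiguous)``; an exact tie in angular distance (at
    |omega| = 90) is classified syn with the ambiguity flag set.
    """
    if not (-180.0 < omega_star <= 180.0):
        raise ValueError(f"omega_star = {omega_star} outside (-180, 180]")
    d_syn = min(angular_distance(omega_star, 60.0), angular_distance(omega_star, -60.0))
    d_anti = min(angular_distance(omega_star, 120.0), angular_distance(omega_star, -120.0))
    if math.isclose(d_syn, d_anti, abs_tol=1e-12):
        return "syn", True
    return ("syn", False) if d_syn < d_anti else ("anti", False)


def run_rcs(
    backend: EnergyBackend,
    start: float,
    direction: str,
    schedule: ScanSchedule | None = None,
    start_isomer: str = "trans",
) -> ScanProfile:
    """Run one directional multi-round scan of 180 degrees of arc.

    ``start`` must sit at a local minimum of the backend, checked to within
    one coarse step.  Round 1 sweeps from ``start`` to the opposite isomer
    at the coarse step; each later round re-scans plus/minus one
    previous-round step around the incumbent maximum at the finer step
    (clamped to the scanned arc).  The returned profile carries every
    evaluated point, sorted along the scan direction.
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULES["gas"]
    sgn = _sign(direction)
    coarse = schedule.steps[0]
    evals = 0

    cache: dict[float, float] = {}

    def energy(omega: float) -> float:
        nonlocal evals
        key = round(omega, 9)
        if key not in cache:
            cache[key] = backend(omega)
            evals += 1
        return cache[key]

    # start must be a minimum within one coarse step; the probe on the
    # far side of the start lies outside the arc and is kept off the profile
    e0 = energy(start)
    e_fwd = energy(start + sgn * coarse)
    e_back = backend(start - sgn * coarse)
    evals += 1
    if e0 > e_fwd + 1e-9 or e0 > e_back + 1e-9:
        raise ScanError(
            f"start omega={start:.3f} is not a local minimum within one "
            f"{coarse:.3f}-degree step"
        )

    arc_lo, arc_hi = (start, start + 180.0) if sgn > 0 else (start - 180.0, start)

    def clamp(omega: float) -> float:
        return min(max(omega, arc_lo), arc_hi)

    # round 1: coarse sweep over the half rotation
    n_steps = math.ceil(180.0 / coarse)
    grid = [start + sgn * k * coarse for k in range(n_steps + 1)]
    grid[-1] = clamp(grid[-1])
    for omega in grid:
        energy(omega)

    for prev_step, step in zip(schedule.steps, schedule.steps[1:]):
        interior = _interior_argmax(cache, start, sgn)
        if interior is None:
            raise ScanError(
                f"no interior maximum found on the arc from omega={start:.3f} "
                f"({direction}); flat or boundary-peaked profile"
            )
        center = interior
        half = math.ceil(prev_step / step)
        for j in range(-half, half + 1):
            omega = clamp(center + j * step)
            energy(omega)

    if _interior_argmax(cache, start, sgn) is None:
        raise ScanError(
            f"no interior maximum found on the arc from omega={start:.3f} ({direction})"
        )

    points = sorted(cache.items(), key=lambda kv: sgn * kv[0])
    return ScanProfile(
        direction=direction,
        start_isomer=start_isomer,
        points=[(float(o), float(e)) for o, e in points],
        backend_name=backend.name,
        n_evaluations=evals,
    )


def _interior_argmax(cache: dict[float, float], start: float, sgn: int) -> float | None:
    """Omega of the highest strictly interior cached point, or None."""
    points = sorted(cache.items(), key=lambda kv: sgn * kv[0])
    if len(points) < 3:
        return None
    interior = points[1:-1]
    best = max(interior, key=lambda kv: kv[1])
    # a flat or monotone profile peaks at a boundary: no interior barrier
    if best[1] <= max(points[0][1], points[-1][1]):
        return None
    return best[0]


def find_ebg(profile: ScanProfile) -> EBG:
    """Locate and classify the barrier of a scan profile.

    The barrier is the argmax over the profile points; a maximum sitting on
    the profile boundary is rejected (no interior barrier was bracketed).
    """
    if len(profile.points) < 3:
        raise ScanError("profile too short to contain an interior maximum")
    energies = [e for _, e in profile.points]
    i_max = max(range(len(energies)), key=energies.__getitem__)
    if i_max in (0, len(energies) - 1):
        raise ScanError(
            f"profile maximum at the boundary (omega={profile.points[i_max][0]:.3f}); "
            "no interior barrier"
        )
    omega_unwrapped, e_abs = profile.points[i_max]
    omega_star = wrap_angle(omega_unwrapped)
    kind, ambiguous = classify_ebg(omega_star)
    return EBG(
        kind=kind,
        direction=profile.direction,
        omega_star=omega_star,
        e_star=e_abs - profile.start_energy,
        ambiguous=ambiguous,
    )


def barrier_set(
    trans_backend: EnergyBackend,
    cis_backend: EnergyBackend,
    trans_start: float = 180.0,
    cis_start: float = 0.0,
    symmetric: bool = False,
    schedule: ScanSchedule | None = None,
) -> dict[tuple[str, str], EBG | None]:
    """Run the full directional scan protocol for one compound/phase.

    Trans-start scans supply the ``(syn, +)`` / ``(syn, -)`` entries and
    cis-start scans the ``(anti, +)`` / ``(anti, -)`` entries (the protocol
    labels; each EBG also carries its own proximity classification).  For a
    symmetric compound only the + direction is scanned and the mirror
    entries are reported absent (``None``), as rotation in the opposite
    direction traverses an equivalent geometry.

    Anti entries are re-referenced to the trans minimum via
    ``e_rel_trans``, assuming both backends share one absolute energy
    scale.  Scan failures propagate tagged with their (type, direction).
    """
    directions = ("+",) if symmetric else ("+", "-")
    out: dict[tuple[str, str], EBG | None] = {key: None for key in
                                              (("anti", "+"), ("anti", "-"),
                                               ("syn", "+"), ("syn", "-"))}
    e_trans_min = trans_backend(trans_start)
    for label, backend, start, isomer in (
        ("syn", trans_backend, trans_start, "trans"),
        ("anti", cis_backend, cis_start, "cis"),
    ):
        for direction in directions:
            try:
                profile = run_rcs(backend, start, direction, schedule, start_isomer=isomer)
                ebg = find_ebg(profile)
            except ScanError as exc:
                raise ScanError(f"({label}, {direction}): {exc}") from exc
            e_abs = ebg.e_star + profile.start_energy
            out[(label, direction)] = EBG(
                kind=ebg.kind,
                direction=direction,
                omega_star=ebg.omega_star,
                e_star=ebg.e_star,
                ambiguous=ebg.ambiguous,
                e_rel_trans=e_abs - e_trans_min,
            )
    return out
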