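"""Relaxed-coordinate-scan driver: location, refinement, classification."""

import numpy as np
import pytest

from amideiso.scan import (
    EBG,
    EnergyBackend,
    ScanError,
    ScanProfile,
    ScanSchedule,
    barrier_set,
    classify_ebg,
    find_ebg,
    run_rcs,
)
from amideiso.synthetic import (
    FourierTerm,
    TorsionPotentialSpec,
    ground_truth,
    make_potential,
)

TWO_WELL = TorsionPotentialSpec(terms=(FourierTerm(2, 10.0),))  # height-10 double well
ASYMMETRIC = TorsionPotentialSpec(
    terms=(FourierTerm(1, 3.0, 180.0), FourierTerm(2, 20.0))
)  # 1.5*(1+cos w) + 10*(1-cos 2w)

#: loose driver budget: coarse sweep + two bracketing refinement windows
EVAL_BUDGET = int(np.ceil(180 / 15) + 2 * (2 * 15 / 2) + 2 * (2 * 2 / 0.125)) + 10


def test_symmetric_cosine_barrier_both_directions():
    backend = make_potential(TWO_WELL)
    plus = run_rcs(backend, 180.0, "+")
    # profile lives on the unwrapped scan axis: the + barrier sits at 270
    omega_max = max(plus.points, key=lambda p: p[1])[0]
    assert omega_max == pytest.approx(270.0, abs=0.125)
    ebg = find_ebg(plus)
    assert ebg.e_star == pytest.approx(10.0, abs=1e-6)
    assert ebg.omega_star == pytest.approx(-90.0, abs=0.125)
    assert ebg.ambiguous  # exactly between the syn and anti zones

    minus = run_rcs(backend, 180.0, "-")
    assert find_ebg(minus).omega_star == pytest.approx(90.0, abs=0.125)
    assert find_ebg(minus).e_star == pytest.approx(10.0, abs=1e-6)


def test_asymmetric_barrier_matches_dense_grid_oracle():
    truth = ground_truth(ASYMMETRIC)
    backend = make_potential(ASYMMETRIC)
    for start_isomer, start in (("trans", truth.omega_min_trans),
                                ("cis", truth.omega_min_cis)):
        for direction in ("+", "-"):
            profile = run_rcs(backend, start, direction, start_isomer=start_isomer)
            ebg = find_ebg(profile)
            oracle = truth.barriers[(start_isomer, direction)]
            assert abs((ebg.omega_star - oracle.omega + 180) % 360 - 180) <= 0.125
            assert ebg.e_star == pytest.approx(oracle.rel_start, abs=0.01)
            assert profile.n_evaluations <= EVAL_BUDGET


def test_refinement_never_loses_the_peak():
    """Each extra refinement round can only raise the barrier estimate."""
    backend = make_potential(ASYMMETRIC)
    estimates = []
    for rounds in (1, 2, 3):
        schedule = ScanSchedule((15.0, 2.0, 0.125)[:rounds])
        profile = run_rcs(backend, 180.0, "+", schedule)
        estimates.append(find_ebg(profile).e_star)
    assert estimates[0] <= estimates[1] + 1e-9 <= estimates[2] + 2e-9


def test_even_potential_directions_agree():
    backend = make_potential(TorsionPotentialSpec(
        terms=(FourierTerm(2, 14.0), FourierTerm(4, 2.0))))
    plus = find_ebg(run_rcs(backend, 180.0, "+"))
    minus = find_ebg(run_rcs(backend, 180.0, "-"))
    assert plus.e_star == pytest.approx(minus.e_star, abs=1e-6)


def test_profile_points_monotone_along_direction():
    backend = make_potential(TWO_WELL)
    for direction, sign in (("+", 1), ("-", -1)):
        profile = run_rcs(backend, 180.0, direction)
        omegas = [o for o, _ in profile.points]
        assert all(sign * (b - a) > 0 for a, b in zip(omegas, omegas[1:]))
        assert profile.start_omega == 180.0


def test_start_must_be_a_minimum():
    backend = make_potential(TWO_WELL)
    with pytest.raises(ScanError, match="not a local minimum"):
        run_rcs(backend, 140.0, "+")


def test_flat_profile_is_an_error():
    flat = EnergyBackend(evaluate=lambda omega: 1.0, name="flat")
    with pytest.raises(ScanError, match="interior maximum"):
        run_rcs(flat, 180.0, "+")


def test_backend_failure_carries_omega():
    def boom(omega):
        if omega > 200:
            raise RuntimeError("SCF blew up")
        return 10.0 * (1 - np.cos(np.radians(2 * omega)))

    backend = EnergyBackend(evaluate=boom, name="fragile")
    with pytest.raises(ScanError, match="omega=2"):
        run_rcs(backend, 180.0, "+")


def test_boundary_maximum_is_rejected_by_find_ebg():
    rising = ScanProfile(
        direction="+", start_isomer="trans",
        points=[(180.0 + 15 * k, float(k)) for k in range(13)],
    )
    with pytest.raises(ScanError, match="boundary"):
        find_ebg(rising)


@pytest.mark.parametrize(
    "omega,kind,ambiguous",
    [(62.0, "syn", False), (-118.0, "anti", False), (90.0, "syn", True),
     (-90.0, "syn", True), (55.0, "syn", False), (130.0, "anti", False)],
)
def test_classification_by_proximity(omega, kind, ambiguous):
    got_kind, got_flag = classify_ebg(omega)
    assert (got_kind, got_flag) == (kind, ambiguous)


# ---------------------------------------------------------------------------
# barrier_set protocol


def test_symmetric_compound_scans_one_direction():
    backend = make_potential(TWO_WELL)
    out = barrier_set(backend, backend, symmetric=True)
    assert out[("syn", "+")] is not None and out[("anti", "+")] is not None
    assert out[("syn", "-")] is None and out[("anti", "-")] is None


def test_asymmetric_compound_has_four_distinct_entries():
    truth = ground_truth(ASYMMETRIC)
    backend = make_potential(ASYMMETRIC)
    out = barrier_set(
        backend, backend,
        trans_start=truth.omega_min_trans, cis_start=truth.omega_min_cis,
    )
    assert all(v is not None for v in out.values())
    # cis-start entries re-referenced to the trans minimum: offset by the
    # cis-trans well gap (3 kcal/mol for this potential)
    gap = truth.e_min_cis - truth.e_min_trans
    for direction in ("+", "-"):
        anti = out[("anti", direction)]
        assert anti.e_rel_trans == pytest.approx(anti.e_star + gap, abs=1e-9)
        syn = out[("syn", direction)]
        assert syn.e_rel_trans == pytest.approx(syn.e_star, abs=1e-9)


def test_direction_dependent_barriers_differ():
    spec = TorsionPotentialSpec(
        terms=(FourierTerm(2, 20.0), FourierTerm(3, 2.0, 20.0), FourierTerm(1, 2.0, 170.0))
    )
    truth = ground_truth(spec)
    backend = make_potential(spec)
    out = barrier_set(backend, backend,
                      trans_start=truth.omega_min_trans,
                      cis_start=truth.omega_min_cis)
    assert abs(out[("syn", "+")].e_star - out[("syn", "-")].e_star) > 0.1


def test_hysteresis_pair_with_syn_effective_barrier():
    """A backend pair where the easiest path crosses a syn geometry: the
    trans-start barriers sit near +/-60 and below both cis-start (anti)
    barriers, emulating relaxation-path hysteresis."""
    trans_spec = TorsionPotentialSpec(
        terms=(FourierTerm(1, 10.2278, 180.0), FourierTerm(2, 7.0644), FourierTerm(3, 2.0))
    )
    cis_spec = TorsionPotentialSpec(
        terms=(FourierTerm(1, 13.29614), FourierTerm(2, 9.18372), FourierTerm(3, 2.6, 180.0))
    )
    t_truth = ground_truth(trans_spec)
    c_truth = ground_truth(cis_spec)
    out = barrier_set(
        make_potential(trans_spec), make_potential(cis_spec),
        trans_start=t_truth.omega_min_trans, cis_start=c_truth.omega_min_cis,
    )
    syn_heights = [out[("syn", d)].e_rel_trans for d in "+-"]
    anti_heights = [out[("anti", d)].e_rel_trans for d in "+-"]
    assert min(syn_heights) < min(anti_heights)
    for d in "+-":
        assert out[("syn", d)].kind == "syn"
        assert out[("anti", d)].kind == "anti"
        # verify against each backend's own dense-grid oracle
        assert out[("syn", d)].e_star == pytest.approx(
            t_truth.barriers[("trans", d)].rel_start, abs=0.01)
        assert out[("anti", d)].e_star == pytest.approx(
            c_truth.barriers[("cis", d)].rel_start, abs=0.01)


def test_schedule_validation():
    with pytest.raises(ValueError):
        ScanSchedule(())
    with pytest.raises(ValueError):
        ScanSchedule((2.0, 15.0))
    with pytest.raises(ValueError):
        ScanSchedule((15.0, -1.0))
    with pytest.raises(ValueError):
        run_rcs(make_potential(TWO_WELL), 180.0, "up")
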