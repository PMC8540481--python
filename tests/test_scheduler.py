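import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ahmt import profiles
from ahmt.scheduler import (
    InstrumentConstraints,
    SchedulingInfeasibleError,
    plan_level,
    plan_series,
    reference_budget,
)
from conftest import EXPECTED_NANO, EXPECTED_PCR


@pytest.mark.parametrize(
    "t_ref, p_ref, expected",
    [(10, 20, 400.0), (10, 2, 40.0), (1, 1, 2.0)],
)
def test_reference_budget_is_twice_the_symmetric_product(t_ref, p_ref, expected):
    assert reference_budget(t_ref, p_ref) == expected


@pytest.mark.parametrize("target", sorted(EXPECTED_PCR))
def test_pcr_levels_match_published_transfer_table(pcr_schedules, target):
    sched = next(s for s in pcr_schedules if s.target_concentration == target)
    (t_ws, p_ws), (t_db, p_db) = EXPECTED_PCR[target]
    assert (sched.ws_step.duration_min, sched.ws_step.pressure_psi) == (t_ws, p_ws)
    assert (sched.dbge_step.duration_min, sched.dbge_step.pressure_psi) == (t_db, p_db)


@pytest.mark.parametrize("target", sorted(EXPECTED_NANO))
def test_nanovial_levels_match_published_transfer_table(nano_schedules, target):
    sched = next(s for s in nano_schedules if s.target_concentration == target)
    (t_ws, p_ws), (t_db, p_db) = EXPECTED_NANO[target]
    assert (sched.ws_step.duration_min, sched.ws_step.pressure_psi) == (t_ws, p_ws)
    assert (sched.dbge_step.duration_min, sched.dbge_step.pressure_psi) == (t_db, p_db)


def test_lowest_nanovial_level_reports_its_rounding_error(nano_schedules):
    """Pressure quantisation at 6.25 µg/mL (3.75 -> 3.8 psi) shifts the
    achieved concentration to 2.5/40.5*100 ~ 6.17 µg/mL, which the schedule
    must report."""
    s = nano_schedules[0]
    assert s.achieved_concentration == pytest.approx(100 * 2.5 / 40.5, rel=1e-12)
    assert s.relative_dilution_error == pytest.approx(6.1728395 / 6.25 - 1, rel=1e-6)
    # all other levels are exact
    for other in nano_schedules[1:]:
        assert other.relative_dilution_error == 0.0


def test_mid_level_is_symmetric(pcr_schedules):
    """2-fold dilution: WS and DBGE share the same time and pressure."""
    s = next(x for x in pcr_schedules if x.target_concentration == 50.0)
    assert (s.ws_step.duration_min, s.ws_step.pressure_psi) == (10.0, 20.0)
    assert (s.dbge_step.duration_min, s.dbge_step.pressure_psi) == (10.0, 20.0)


def test_pass_through_level():
    s = plan_level(100.0, 100.0, 400.0, profiles.PCR_CONSTRAINTS)
    assert s.undiluted
    assert s.ws_step is None and s.dbge_step is None
    assert s.achieved_concentration == 100.0


def test_target_above_stock_rejected():
    with pytest.raises(ValueError, match="stock"):
        plan_level(150.0, 100.0, 400.0, profiles.PCR_CONSTRAINTS)


def test_infeasible_level_names_the_problem():
    # 0.1 µg/mL -> WS product 0.4 psi·min; even 1 min at p_min 2.5 overshoots.
    with pytest.raises(SchedulingInfeasibleError):
        plan_level(0.1, 100.0, 400.0, profiles.PCR_CONSTRAINTS)


def test_plan_series_propagates_level_index():
    with pytest.raises(SchedulingInfeasibleError, match="level 1"):
        plan_series([50.0, 0.1], 100.0, 400.0, profiles.PCR_CONSTRAINTS)


def test_determinism(pcr_schedules):
    again = plan_series(
        sorted(EXPECTED_PCR), 100.0, profiles.PCR_BUDGET, profiles.PCR_CONSTRAINTS
    )
    assert again == pcr_schedules


def test_budget_conservation(pcr_schedules, nano_schedules):
    """Lengthened (rule 2) and pinned (rule 3) transfers preserve the
    product exactly; quantised (rule 1) ones deviate at most by one
    pressure quantum over the default time per solution."""
    for sched, c in (
        (pcr_schedules, profiles.PCR_CONSTRAINTS),
        (nano_schedules, profiles.NANOVIAL_CONSTRAINTS),
    ):
        tol = 2 * c.p_quantum * c.t_default  # two solutions, worst case
        for s in sched:
            assert abs(s.total_product - s.budget) <= tol + 1e-9


@given(
    targets=st.lists(
        st.floats(min_value=5.0, max_value=99.0), min_size=2, max_size=8
    )
)
def test_achieved_concentration_monotone_in_target(targets):
    """Among schedulable targets, achieved concentration never decreases."""
    schedules = []
    for t in sorted(targets):
        try:
            schedules.append(
                plan_level(t, 100.0, profiles.PCR_BUDGET, profiles.PCR_CONSTRAINTS)
            )
        except SchedulingInfeasibleError:
            continue  # targets whose products miss the exact grid
    achieved = [s.achieved_concentration for s in schedules]
    assert all(a <= b + 1e-12 for a, b in zip(achieved, achieved[1:]))


def _brute_force_rule2(product, c: InstrumentConstraints):
    """Exhaustive search over the full (t, p) grid for the minimal-time
    executable pair that preserves the product exactly."""
    best = None
    k = 1
    while True:
        t = c.t_default + k * c.t_quantum
        if t > c.t_max + 1e-9:
            break
        n_p = round(product / t / c.p_quantum)
        for n in (n_p - 1, n_p, n_p + 1):
            p = n * c.p_quantum
            if c.p_min - 1e-9 <= p <= c.p_max + 1e-9 and math.isclose(
                t * p, product, rel_tol=1e-9
            ):
                if best is None:
                    best = (t, p)
        if best:
            break
        k += 1
    return best


@pytest.mark.parametrize("product", [375.0, 350.0, 330.0, 345.0, 360.0])
def test_rule2_matches_exhaustive_grid_search(product):
    """When the default-time pressure overshoots, the scheduler picks the
    same (minimal-time, exact-product) grid pair as brute-force enumeration."""
    c = profiles.PCR_CONSTRAINTS
    expected = _brute_force_rule2(product, c)
    if expected is None:
        with pytest.raises(SchedulingInfeasibleError):
            plan_level(product / 4.0, 100.0, 400.0, c)
    else:
        s = plan_level(100.0 - product / 4.0, 100.0, 400.0, c)
        assert (s.dbge_step.duration_min, s.dbge_step.pressure_psi) == expected
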