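"""Cohort engine: stepping, discounting, accrual — checked against a
path-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirvcea.engine import CohortTrace, ModelSettings, discount_factor, run, step
from mirvcea.transitions import DAYS_PER_YEAR, TransitionSchedule


def enumerate_paths_oracle(schedule, costs, utilities, settings):
    """Independent oracle: enumerate every state path of the embedded Markov
    chain, weight by its probability, and accrue outcomes along the way.

    States 0=stable, 1=progressive, 2=dead; transitions exactly as specified
    (no progressive->stable, dead absorbing).  Exponential in the horizon, so
    only usable for a handful of cycles.
    """
    h = settings.horizon_cycles
    ypc = settings.cycle_days / DAYS_PER_YEAR
    df = [
        (1 + settings.annual_discount_rate) ** (-(c * ypc)) for c in range(h)
    ]

    def trans_prob(state, nxt, c):
        p_sp, p_sd, p_pd = schedule.p_sp[c], schedule.p_sd[c], schedule.p_pd[c]
        table = {
            (0, 0): 1 - p_sp - p_sd, (0, 1): p_sp, (0, 2): p_sd,
            (1, 1): 1 - p_pd, (1, 2): p_pd,
            (2, 2): 1.0,
        }
        return table.get((state, nxt), 0.0)

    total = {"cost": 0.0, "ly": 0.0, "qaly": 0.0}
    occ = np.zeros((h + 1, 3))
    for path in itertools.product(range(3), repeat=h):
        full = (0,) + path  # everyone starts stable
        prob = 1.0
        for c in range(h):
            prob *= trans_prob(full[c], full[c + 1], c)
            if prob == 0.0:
                break
        if prob == 0.0:
            continue
        for c in range(h):
            state = full[c]
            total["cost"] += prob * costs[c, state] * df[c]
            total["ly"] += prob * (state != 2) * ypc * df[c]
            total["qaly"] += prob * utilities[c, state] * ypc * df[c]
        for c in range(h + 1):
            occ[c, full[c]] += prob
    return total, occ


def make_schedule(p_sp, p_sd, p_pd):
    return TransitionSchedule(p_sp=np.asarray(p_sp, float),
                              p_sd=np.asarray(p_sd, float),
                              p_pd=np.asarray(p_pd, float))


class TestStep:
    def test_identity_when_no_transitions(self):
        np.testing.assert_allclose(step((0.5, 0.3, 0.2), 0, 0, 0), (0.5, 0.3, 0.2))

    def test_direct_arithmetic(self):
        np.testing.assert_allclose(step((1, 0, 0), 0.3, 0.1, 0.0), (0.6, 0.3, 0.1))

    def test_death_absorbing(self):
        np.testing.assert_allclose(step((0, 1, 0), 0.0, 0.0, 1.0), (0, 0, 1))

    def test_rejects_excess_probability(self):
        with pytest.raises(ValueError):
            step((1, 0, 0), 0.7, 0.5, 0.0)


class TestDiscountFactor:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, ModelSettings()) == 1.0

    def test_zero_rate_is_one(self):
        settings = ModelSettings(annual_discount_rate=0.0)
        assert discount_factor(40, settings) == 1.0

    def test_closed_form_cycle_13(self):
        settings = ModelSettings(annual_discount_rate=0.03)
        expected = 1.03 ** (-(13 * 28 / 365.25))
        assert discount_factor(13, settings) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9710, abs=5e-4)


class TestRun:
    def test_stable_cohort_qaly_closed_form(self):
        h = 26
        settings = ModelSettings(horizon_cycles=h, annual_discount_rate=0.0)
        sched = make_schedule(np.zeros(h), np.zeros(h), np.zeros(h))
        utilities = np.tile([0.61, 0.5, 0.0], (h, 1))
        trace = run(sched, np.zeros((h, 3)), utilities, settings)
        years = h * 28 / 365.25
        assert trace.total_qaly == pytest.approx(0.61 * years, rel=1e-12)
        assert trace.total_ly == pytest.approx(years, rel=1e-12)

    def test_zero_costs_zero_total(self, runner):
        h = 5
        settings = ModelSettings(horizon_cycles=h)
        sched = make_schedule([0.1] * h, [0.05] * h, [0.2] * h)
        trace = run(sched, np.zeros((h, 3)), np.zeros((h, 3)), settings)
        assert trace.total_cost == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_path_enumeration_oracle_equivalence(self, seed):
        """Engine totals equal exhaustive path enumeration on small cases."""
        rng = np.random.default_rng(seed)
        h = 5
        p_sd = rng.uniform(0, 0.2, h)
        p_sp = rng.uniform(0, 0.5, h)
        p_pd = rng.uniform(0, 0.6, h)
        sched = make_schedule(p_sp, p_sd, p_pd)
        costs = np.zeros((h, 3))
        costs[:, 0] = rng.uniform(100, 20000, h)
        costs[:, 1] = rng.uniform(0, 500, h)
        utilities = np.tile([0.61, 0.5, 0.0], (h, 1))
        settings = ModelSettings(horizon_cycles=h, annual_discount_rate=0.03)
        trace = run(sched, costs, utilities, settings)
        oracle, occ = enumerate_paths_oracle(sched, costs, utilities, settings)
        assert trace.total_cost == pytest.approx(oracle["cost"], abs=1e-9)
        assert trace.total_ly == pytest.approx(oracle["ly"], abs=1e-12)
        assert trace.total_qaly == pytest.approx(oracle["qaly"], abs=1e-12)
        np.testing.assert_allclose(trace.occupancy, occ, atol=1e-12)

    def test_two_cycle_hand_example(self):
        # cycle 0: half progress; cycle 1: half of progressive die
        sched = make_schedule([0.5, 0.0], [0.0, 0.0], [0.0, 0.5])
        settings = ModelSettings(horizon_cycles=2, annual_discount_rate=0.0)
        costs = np.zeros((2, 3))
        costs[:, 0] = 100.0  # stable-state cost only
        utilities = np.tile([0.61, 0.5, 0.0], (2, 1))
        trace = run(sched, costs, utilities, settings)
        np.testing.assert_allclose(trace.occupancy[1], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(trace.occupancy[2], [0.5, 0.5 + 0.25 - 0.5, 0.25])
        # accrual on start-of-cycle occupancy: cycles 0 and 1
        assert trace.total_cost == pytest.approx(100 * 1.0 + 100 * 0.5)
        ypc = 28 / 365.25
        assert trace.total_qaly == pytest.approx(
            (0.61 + 0.5 * 0.61 + 0.5 * 0.5) * ypc
        )

    def test_mass_conservation_and_monotone_death(self, runner):
        trace = runner.trace("mirv")
        sums = trace.occupancy.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-15)
        for arr in (trace.cum_cost, trace.cum_ly, trace.cum_qaly):
            assert np.all(np.diff(arr) >= -1e-12)

    def test_discounting_never_increases_totals(self):
        h = 20
        sched = make_schedule([0.1] * h, [0.02] * h, [0.3] * h)
        costs = np.zeros((h, 3))
        costs[:, 0] = 1000.0
        utilities = np.tile([0.61, 0.5, 0.0], (h, 1))
        disc = run(sched, costs, utilities, ModelSettings(horizon_cycles=h))
        undisc = run(
            sched, costs, utilities,
            ModelSettings(horizon_cycles=h, annual_discount_rate=0.0),
        )
        assert disc.total_cost < undisc.total_cost
        assert disc.total_qaly < undisc.total_qaly
        np.testing.assert_allclose(disc.cum_cost_undisc, undisc.cum_cost)

    def test_unit_utilities_make_qalys_equal_lys(self):
        h = 15
        sched = make_schedule([0.2] * h, [0.05] * h, [0.3] * h)
        utilities = np.tile([1.0, 1.0, 0.0], (h, 1))
        trace = run(sched, np.zeros((h, 3)), utilities, ModelSettings(horizon_cycles=h))
        assert trace.total_qaly == pytest.approx(trace.total_ly, rel=1e-12)

    def test_half_cycle_correction_averages_occupancy(self):
        h = 3
        sched = make_schedule([0.5, 0.0, 0.0], [0.0] * 3, [0.0] * 3)
        costs = np.zeros((h, 3))
        costs[:, 0] = 100.0
        settings = ModelSettings(
            horizon_cycles=h, annual_discount_rate=0.0, half_cycle_correction=True
        )
        trace = run(sched, costs, np.zeros((h, 3)), settings)
        # stable occupancies 1, .5, .5 -> averaged bases .75, .5, .5
        assert trace.total_cost == pytest.approx(100 * (0.75 + 0.5 + 0.5))

    def test_horizon_mismatch_rejected(self):
        sched = make_schedule([0.0] * 4, [0.0] * 4, [0.0] * 4)
        with pytest.raises(ValueError):
            run(sched, np.zeros((5, 3)), np.zeros((5, 3)), ModelSettings(horizon_cycles=5))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    p_sp=st.floats(0, 0.6), p_sd=st.floats(0, 0.4), p_pd=st.floats(0, 1),
    occ0=st.floats(0, 1), occ1=st.floats(0, 1),
)
def test_step_conserves_mass_property(p_sp, p_sd, p_pd, occ0, occ1):
    """A single step never creates or destroys cohort mass."""
    if p_sp + p_sd > 1:
        p_sd = 1 - p_sp
    total = occ0 + occ1
    if total > 1:
        occ0, occ1 = occ0 / total, occ1 / total
    occ = (occ0, occ1, 1 - occ0 - occ1) if occ0 + occ1 <= 1 else (occ0, occ1, 0.0)
    nxt = step(occ, p_sp, p_sd, p_pd)
    assert nxt.sum() == pytest.approx(sum(occ), abs=1e-12)
    assert np.all(nxt >= -1e-15)
    assert nxt[2] >= occ[2] - 1e-15
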