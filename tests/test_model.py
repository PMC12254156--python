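"""Unit tests for the five-stock engagement model."""

import numpy as np
import pytest

from reaimsim import (
    FlowRecord,
    Parameters,
    StockState,
    annual_to_step_fraction,
    initial_state,
    make_default_parameters,
    participation_proportion,
    simulate,
    step,
)


class TestParameters:
    def test_defaults_are_canonical(self):
        p = make_default_parameters()
        assert p.total_population == 5000
        assert p.exposure_rate == 150
        assert p.steps_per_year == 12
        assert p.horizon_years == 50
        assert (p.p_initial_reach, p.p_disengage, p.p_delayed_reach, p.p_reengage) == (
            0, 0, 0, 0,
        )
        assert p.dt == pytest.approx(1 / 12)
        assert p.n_steps == 600

    @pytest.mark.parametrize(
        "field,value",
        [
            ("total_population", 0),
            ("exposure_rate", -1),
            ("p_initial_reach", 1.2),
            ("p_disengage", -0.1),
            ("p_delayed_reach", 2),
            ("p_reengage", -1e-6),
            ("steps_per_year", 0),
            ("horizon_years", 0),
        ],
    )
    def test_invalid_values_rejected_with_field_named(self, field, value):
        with pytest.raises(ValueError, match=field):
            make_default_parameters().replace(**{field: value})


class TestAnnualToStepFraction:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundary_fractions(self, p, expected):
        assert annual_to_step_fraction(p, 12) == expected

    def test_effective_annual_semantics(self):
        # q such that twelve consecutive steps deplete exactly 94% per year
        q = annual_to_step_fraction(0.94, 12)
        assert q == pytest.approx(0.2090, abs=5e-5)
        assert (1 - q) ** 12 == pytest.approx(0.06, abs=1e-12)

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            annual_to_step_fraction(p, 12)


class TestStep:
    def test_all_zero_rates_leave_state_unchanged(self):
        params = make_default_parameters().replace(exposure_rate=0.0)
        state = StockState(unaware=3000, participating=1500, disengaged=500)
        new_state, flows = step(state, params)
        assert new_state == state
        assert all(f == 0 for f in flows.as_tuple())

    def test_exposure_moves_constant_flow_per_step(self):
        params = make_default_parameters()
        new_state, flows = step(initial_state(params), params)
        assert new_state.unaware == pytest.approx(5000 - 150 / 12)
        assert flows.exposure == pytest.approx(150 / 12)

    def test_exposure_clipped_at_remaining_unaware(self):
        params = make_default_parameters()
        state = StockState(unaware=3.0, participating=4997.0)
        new_state, flows = step(state, params)
        assert flows.exposure == pytest.approx(3.0)
        assert new_state.unaware == pytest.approx(0.0)

    def test_not_engaged_is_one_step_transit(self):
        params = make_default_parameters().replace(p_initial_reach=0.3)
        state = StockState(unaware=1000, not_engaged=200)
        new_state, flows = step(state, params)
        in_transit = 200 + 150 / 12
        assert new_state.not_engaged == 0.0
        assert flows.initial_reach == pytest.approx(0.3 * in_transit)
        assert flows.non_uptake == pytest.approx(0.7 * in_transit)

    def test_conservation_and_flow_bounds(self):
        params = make_default_parameters().replace(
            p_initial_reach=0.4, p_disengage=0.6, p_delayed_reach=0.3, p_reengage=0.8
        )
        state = StockState(
            unaware=1000, not_initially_participating=800, participating=2200,
            disengaged=1000,
        )
        new_state, flows = step(state, params)
        assert new_state.total() == pytest.approx(state.total(), rel=1e-12)
        assert flows.delayed_reach <= state.not_initially_participating
        assert flows.disengagement <= state.participating
        assert flows.reengagement <= state.disengaged
        assert all(f >= 0 for f in flows.as_tuple())

    def test_negative_stock_rejected(self):
        params = make_default_parameters()
        with pytest.raises(ValueError, match="participating"):
            step(StockState(unaware=5000, participating=-1.0), params)


class TestSimulate:
    def test_zero_exposure_keeps_population_unaware(self):
        params = make_default_parameters().replace(exposure_rate=0.0)
        traj = simulate(params)
        assert all(s == initial_state(params) for s in traj.states)

    def test_full_initial_reach_exhausts_population_into_participation(self):
        # unaware drains linearly at 150/yr, emptying at year 33.3 < 50
        params = make_default_parameters().replace(p_initial_reach=1.0)
        traj = simulate(params)
        assert traj.final_state().participating == pytest.approx(5000, rel=1e-12)
        assert traj.final_state().unaware == pytest.approx(0.0, abs=1e-9)

    def test_shapes_and_replayability(self):
        params = make_default_parameters().replace(
            p_initial_reach=0.5, p_disengage=0.3, p_reengage=0.2, horizon_years=2
        )
        traj = simulate(params)
        assert len(traj.states) == len(traj.times) == len(traj.flows) + 1
        assert len(traj.cost_increments) == len(traj.flows)
        # applying step to states[i] reproduces states[i+1]
        for i in [0, 5, 11, 23]:
            replayed, _ = step(traj.states[i], params)
            assert replayed == traj.states[i + 1]

    def test_conservation_at_every_recorded_time(self):
        params = make_default_parameters().replace(
            p_initial_reach=0.7, p_disengage=0.5, p_delayed_reach=0.94, p_reengage=0.94
        )
        traj = simulate(params)
        totals = np.array([s.total() for s in traj.states])
        assert np.allclose(totals, 5000, rtol=1e-9)

    def test_custom_start_state(self):
        params = make_default_parameters().replace(
            exposure_rate=0.0, p_reengage=0.94, horizon_years=1
        )
        traj = simulate(params, start=StockState(disengaged=1000))
        assert traj.final_state().participating == pytest.approx(940, rel=1e-12)


class TestParticipationProportion:
    @pytest.mark.parametrize(
        "participating,expected", [(0.0, 0.0), (1250.0, 0.25), (5000.0, 1.0)]
    )
    def test_proportion_of_total_population(self, participating, expected):
        params = make_default_parameters()
        state = StockState(unaware=5000 - participating, participating=participating)
        assert participation_proportion(state, params) == pytest.approx(expected)
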