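"""Carbon-stock simulator: allometry, schedules, stepping, diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatghg.carbon_model import (
    DEFAULT_ALLOMETRY,
    EcosystemState,
    PeatExhaustedError,
    ScenarioSpec,
    Schedule,
    biomass_carbon,
    default_scenarios,
    initial_state,
    mean_annual_change,
    neutrality_year,
    peat_depth_to_c_stock,
    scenario_from_dict,
    scenario_to_dict,
    simulate,
    step,
)


class TestBiomassCarbon:
    def test_zero_volume(self):
        assert biomass_carbon(0.0) == (0.0, 0.0, 0.0)

    def test_hand_oracle_v100(self):
        stem, branch, root = biomass_carbon(100.0)
        # 100 x 420 kg/m3 x 0.5 C = 21 t; branches 12%; roots 19% of AG
        assert stem == pytest.approx(21.0)
        assert branch == pytest.approx(2.52)
        assert root == pytest.approx(4.4688)
        assert stem + branch + root == pytest.approx(27.9888)

    def test_hand_oracle_v400_total(self):
        assert sum(biomass_carbon(400.0)) == pytest.approx(111.9552)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            biomass_carbon(-1.0)


class TestSchedule:
    def test_breakpoints_validated(self):
        with pytest.raises(ValueError):
            Schedule(breakpoints=((5, 1.0),))  # must start at 0
        with pytest.raises(ValueError):
            Schedule(breakpoints=((0, 1.0), (0, 2.0)))

    def test_constant_extrapolation_after_last(self):
        s = Schedule(breakpoints=((0, 0.0), (50, 4.0), (160, 0.1)))
        assert s(200) == 0.1
        assert s(160) == 0.1

    @given(q=st.floats(0, 400))
    @settings(max_examples=1000, derandomize=True)
    def test_agrees_with_independent_piecewise_linear_evaluator(self, q):
        bps = ((0, -2.0), (20, 0.0), (50, 4.0), (160, 0.1))
        s = Schedule(breakpoints=bps)

        def brute(x):
            if x >= bps[-1][0]:
                return bps[-1][1]
            for (y0, r0), (y1, r1) in zip(bps, bps[1:]):
                if y0 <= x <= y1:
                    return r0 + (r1 - r0) * (x - y0) / (y1 - y0)
            return bps[0][1]

        assert s(q) == pytest.approx(brute(q), abs=1e-12)


def test_peat_depth_to_c_stock():
    assert peat_depth_to_c_stock(2.0) == 686.0
    assert peat_depth_to_c_stock(0.0) == 0.0
    assert peat_depth_to_c_stock(1.0) == 343.0
    with pytest.raises(ValueError):
        peat_depth_to_c_stock(-0.1)


def _zero_scenario(**kw):
    defaults = dict(
        name="null",
        increment_schedule=Schedule.constant(0.0),
        peat_flux_schedule=Schedule.constant(0.0),
    )
    defaults.update(kw)
    return ScenarioSpec(**defaults)


class TestStep:
    def test_open_bog_single_step(self, scenarios):
        spec = scenarios["pristine_open_bog"]
        s0 = initial_state(spec)
        s1 = step(s0, 1, spec)
        assert s1.stem_volume == s0.stem_volume  # increment 0
        assert s1.peat_c == pytest.approx(s0.peat_c + 0.22)

    def test_zero_everything_is_fixed_point(self):
        spec = _zero_scenario(initial_stem_volume=50.0)
        s0 = initial_state(spec)
        s1 = step(s0, 1, spec)
        assert s1.total_c == pytest.approx(s0.total_c, abs=1e-12)
        assert s1.stem_volume == s0.stem_volume

    def test_harvest_moves_stem_to_export_and_crown_to_residue(self, scenarios):
        spec = scenarios["drained_managed_bog_forest"]
        traj = simulate(spec, 300)
        before, after = traj[99], traj[100]
        # at harvest the stand stood at 400 m3 (4 m3/yr x 100 yr)
        stem400, branch400, root400 = (
            21.0 * 4, 2.52 * 4, 4.4688 * 4)
        assert after.cumulative_export_c == pytest.approx(stem400)
        assert after.residue_c == pytest.approx(branch400 + root400)
        assert after.stem_volume == 0.0
        assert after.stem_c == after.branch_c == after.root_c == 0.0
        # the event itself conserves carbon: pools only move
        assert before.peat_c - 0.9 == pytest.approx(after.peat_c)

    def test_peat_exhaustion_halts_with_year(self):
        spec = _zero_scenario(
            peat_flux_schedule=Schedule.constant(-10.0), initial_peat_c=686.0
        )
        with pytest.raises(PeatExhaustedError) as err:
            simulate(spec, 300)
        assert err.value.year == 69  # 686 / 10 rounded up


class TestSimulate:
    def test_trivial_horizon(self, scenarios):
        traj = simulate(scenarios["restored_bog"], horizon=1)
        assert len(traj) == 2
        assert [s.year for s in traj.states] == [0, 1]

    def test_determinism_bit_identical(self, scenarios):
        for name, spec in scenarios.items():
            a = simulate(spec, 300)
            b = simulate(spec, 300)
            assert a.states == b.states

    def test_harvests_strictly_inside_horizon(self, scenarios):
        spec = scenarios["drained_managed_bog_forest"]
        traj = simulate(spec, 300)
        # harvests at 100 and 200 only; year 300 is evaluated pre-harvest
        exports = np.array([s.cumulative_export_c for s in traj.states])
        jumps = np.flatnonzero(np.diff(exports) > 0) + 1
        assert list(jumps) == [100, 200]
        assert traj[-1].stem_volume == pytest.approx(400.0)

    def test_bookkeeping_identity_every_step(self, scenarios):
        """d(total + export) = peat flux + biomass growth - residue decay."""
        for name, spec in scenarios.items():
            traj = simulate(spec, 300)
            for prev, cur in zip(traj.states, traj.states[1:]):
                inc = spec.increment_schedule(prev.stand_age + 1)
                grown_volume = prev.stem_volume + inc
                growth = sum(biomass_carbon(grown_volume, spec.allometry)) - (
                    prev.stem_c + prev.branch_c + prev.root_c
                )
                decay = prev.residue_c * (
                    1.0 - math.exp(-spec.residue_decay_rate)
                )
                lhs = (cur.total_c + cur.cumulative_export_c) - (
                    prev.total_c + prev.cumulative_export_c
                )
                rhs = spec.peat_flux_schedule(cur.year) + growth - decay
                assert lhs == pytest.approx(rhs, abs=1e-9), (name, cur.year)

    def test_mass_conservation_with_all_rates_zero(self):
        spec = _zero_scenario(initial_stem_volume=120.0)
        traj = simulate(spec, 300)
        assert np.allclose(traj.total_c, traj.total_c[0], atol=1e-9)

    def test_drained_peat_strictly_decreasing(self, scenarios):
        traj = simulate(scenarios["drained_managed_bog_forest"], 300)
        peat = np.array([s.peat_c for s in traj.states])
        assert np.all(np.diff(peat) < 0)


class TestDiagnostics:
    def test_restored_bog_neutral_at_year_20(self, scenarios):
        traj = simulate(scenarios["restored_bog"], 300)
        assert neutrality_year(traj) == 20

    def test_open_bog_neutral_immediately(self, scenarios):
        traj = simulate(scenarios["pristine_open_bog"], 300)
        assert neutrality_year(traj) == 1

    def test_neutrality_matches_brute_force_scan(self, scenarios):
        for name, spec in scenarios.items():
            traj = simulate(spec, 300)
            total = traj.total_c
            expected = None
            for t in range(1, len(total)):
                if total[t] - total[t - 1] >= 0:
                    expected = t
                    break
            assert neutrality_year(traj) == expected, name

    def test_never_neutral_returns_none(self):
        spec = _zero_scenario(peat_flux_schedule=Schedule.constant(-0.5))
        traj = simulate(spec, 100)
        assert neutrality_year(traj) is None

    def test_restored_bog_sequesters_022_after_transition(self, scenarios):
        traj = simulate(scenarios["restored_bog"], 300)
        assert mean_annual_change(traj, 20, 300) == pytest.approx(0.22, abs=1e-9)

    def test_drained_forest_peat_loss_09(self, scenarios):
        traj = simulate(scenarios["drained_managed_bog_forest"], 300)
        peat_loss = (traj[0].peat_c - traj[-1].peat_c) / 300
        assert peat_loss == pytest.approx(0.9, abs=1e-12)

    def test_drained_forest_ecosystem_loss_in_published_band(self, scenarios):
        traj = simulate(scenarios["drained_managed_bog_forest"], 300)
        loss = -mean_annual_change(traj, 0, 300)
        assert 0.4 <= loss <= 0.6

    def test_regenerated_forest_pristine_like_after_160(self, scenarios):
        traj = simulate(scenarios["regenerated_unmanaged_forest"], 300)
        assert mean_annual_change(traj, 160, 300) == pytest.approx(0.1, abs=0.005)

    def test_constant_state_mean_change_zero(self):
        traj = simulate(_zero_scenario(), 50)
        assert mean_annual_change(traj, 0, 50) == 0.0

    def test_bad_window_rejected(self, scenarios):
        traj = simulate(scenarios["restored_bog"], 300)
        with pytest.raises(ValueError):
            mean_annual_change(traj, 200, 100)
        with pytest.raises(ValueError):
            mean_annual_change(traj, 0, 301)


def test_scenario_dict_round_trip(scenarios):
    for spec in scenarios.values():
        assert scenario_from_dict(scenario_to_dict(spec)) == spec
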