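"""Scenario integration: conservation, linearity, oracle agreement, summaries."""

import numpy as np
import pytest

from radonpreg import (
    IntakeScenario,
    acute_fetal_fraction,
    chronic_profile,
    integrated_activity,
    solve,
    solve_expm,
)
from radonpreg.simulate import SimulationResult


class TestScenarios:
    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            IntakeScenario.acute(200.0, -1.0)
        with pytest.raises(ValueError):
            IntakeScenario.chronic(1.0, start=100.0, end=50.0)
        with pytest.raises(ValueError):
            IntakeScenario(route="ingestion", mode="acute", day=1.0)

    def test_cumulative_intake(self):
        sc = IntakeScenario.chronic(2.0, 10.0, 20.0)
        assert sc.cumulative_intake(10.0) == 0.0
        assert sc.cumulative_intake(15.0) == pytest.approx(10.0)
        assert sc.cumulative_intake(25.0) == pytest.approx(20.0)


class TestSolve:
    def test_zero_intake_identically_zero(self, params):
        res = solve(IntakeScenario.acute(200.0, 0.0), params=params, follow_up_days=1.0)
        assert np.all(res.activities == 0.0)

    def test_sealed_system_conserves_activity(self, params_stable):
        """No decay, vent disabled: total activity constant to 1e-9 relative."""
        res = solve(
            IntakeScenario.acute(200.0, 1.0),
            params=params_stable,
            rtol=1e-10,
            atol=1e-14,
            follow_up_days=3.0,
        )
        total = res.activities.sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-9

    def test_mass_balance_with_decay(self, params):
        res = solve(IntakeScenario.acute(150.0, 1.0), params=params, follow_up_days=3.0)
        assert res.mass_balance_error() < 1e-8
        assert res.decayed[-1] > 0.0

    def test_nonnegative_activities(self, params):
        res = solve(IntakeScenario.acute(105.0, 1.0), params=params, follow_up_days=2.0)
        assert res.activities.min() >= 0.0

    def test_total_body_activity_decreases_after_bolus(self, params):
        """With sources off, body burden (excluding the sink) strictly decays."""
        res = solve(IntakeScenario.acute(200.0, 1.0), params=params, follow_up_days=2.0)
        body = res.activities.sum(axis=1) - res.exhaled
        assert np.all(np.diff(body) < 1e-12 * body.max())  # strict decay up to rounding

    def test_linearity_in_amount(self, params):
        grid = np.arange(200.0, 201.0 + 1e-9, 0.05)
        r1 = solve(IntakeScenario.acute(200.0, 1.0), t_grid=grid, params=params)
        r2 = solve(IntakeScenario.acute(200.0, 2.0), t_grid=grid, params=params)
        # atol floor: the smallest compartments sit at the solver's absolute
        # tolerance, where adaptive step selection differs between the two runs
        assert np.allclose(2.0 * r1.activities, r2.activities, rtol=1e-5, atol=1e-9)

    def test_chronic_linearity_in_rate(self, params):
        r1 = chronic_profile(1.0, window=(150.0, 160.0), params=params)
        r2 = chronic_profile(2.0, window=(150.0, 160.0), params=params)
        assert np.allclose(2.0 * r1.activities, r2.activities, rtol=1e-6, atol=1e-14)

    def test_adaptive_agrees_with_expm_constant_coefficients(self, params):
        """Frozen gestational physiology: matrix-exponential stepping is exact
        per step, so any discrepancy is adaptive-solver error."""
        grid = np.arange(200.0, 202.0 + 1e-9, 0.1)
        a = solve(
            IntakeScenario.acute(200.0, 1.0), t_grid=grid, params=params,
            rtol=1e-10, atol=1e-14, frozen_day=200.0,
        )
        b = solve_expm(IntakeScenario.acute(200.0, 1.0), t_grid=grid, params=params, step=0.1, frozen_day=200.0)
        mask = a.activities > 1e-10
        rel = np.abs(a.activities[mask] - b.activities[mask]) / a.activities[mask]
        assert rel.max() < 1e-6

    def test_adaptive_agrees_with_expm_varying_coefficients(self, params):
        """Time-varying coefficients: agreement at the level of the oracle's own
        piecewise-constant discretization error (first order in the step)."""
        grid = np.arange(200.0, 201.0 + 1e-9, 0.1)
        a = solve(IntakeScenario.acute(200.0, 1.0), t_grid=grid, params=params, rtol=1e-10, atol=1e-14)
        b = solve_expm(IntakeScenario.acute(200.0, 1.0), t_grid=grid, params=params, step=0.01)
        mask = a.activities > 1e-10
        rel = np.abs(a.activities[mask] - b.activities[mask]) / a.activities[mask]
        assert rel.max() < 1e-3

    def test_solver_deterministic(self, params):
        r1 = solve(IntakeScenario.acute(200.0, 1.0), params=params, follow_up_days=1.0)
        r2 = solve(IntakeScenario.acute(200.0, 1.0), params=params, follow_up_days=1.0)
        assert np.array_equal(r1.activities, r2.activities)


class TestSummaryQuantities:
    def test_acute_fraction_zero_before_fetal_model(self, params):
        with pytest.warns(UserWarning):
            assert acute_fetal_fraction(50.0, params=params) == 0.0

    def test_acute_fraction_scales_with_route(self, params):
        """Injection bypasses the exhaled dead-space loss, so the injected
        fraction exceeds the inhaled one."""
        inh = acute_fetal_fraction(200.0, "inhalation", params=params, follow_up_days=1.0)
        inj = acute_fetal_fraction(200.0, "injection", params=params, follow_up_days=1.0)
        assert 0.0 < inh < inj

    def test_inclusive_tally_dominates(self, params):
        sc = IntakeScenario.acute(200.0, 1.0)
        res = solve(sc, params=params, follow_up_days=1.0)
        assert res.fetal_fraction(True).max() >= res.fetal_fraction(False).max()

    def test_chronic_profile_reports_concentrations(self, params):
        res = chronic_profile(1.0, window=(0.0, 190.0), params=params)
        s = res.summary()
        assert set(s["final_fetal_content_Bq"]) == {
            "fetal-lungs", "fetal-brain", "fetal-kidneys", "fetal-bone", "fetal-liver",
            "fetal-thyroid", "fetal-bone-marrow", "fetal-other", "fetal-adipose",
        }
        assert s["final_fetal_concentration_Bq_per_g"]["fetal-brain"] > 0

    def test_integrated_activity(self, params):
        times = np.linspace(0.0, 10.0, 101)
        acts = np.zeros((101, 24))
        comp_idx = 2
        acts[:, comp_idx] = 1.0
        res = SimulationResult(
            times=times,
            activities=acts,
            decayed=np.zeros(101),
            scenario=IntakeScenario.acute(0.0, 1.0),
            params=params,
        )
        comp = res.compartments[comp_idx]
        assert integrated_activity(res, comp) == pytest.approx(10.0)
        zero_comp = res.compartments[0]
        assert integrated_activity(res, zero_comp) == 0.0
        # additivity over adjacent windows
        left = integrated_activity(res, comp, (0.0, 4.0))
        right = integrated_activity(res, comp, (4.0, 10.0))
        assert left + right == pytest.approx(integrated_activity(res, comp, (0.0, 10.0)))
        with pytest.raises(ValueError):
            integrated_activity(res, comp, (5.0, 20.0))

    def test_integrated_activity_on_simulation(self, params):
        res = solve(IntakeScenario.acute(200.0, 1.0), params=params, follow_up_days=2.0)
        ia = integrated_activity(res, "fat1")
        split = integrated_activity(res, "fat1", (200.0, 200.5)) + integrated_activity(
            res, "fat1", (200.5, 202.0)
        )
        assert ia > 0
        assert split == pytest.approx(ia, rel=1e-12)

    def test_tidy_frame_shape(self, params):
        res = solve(IntakeScenario.acute(200.0, 1.0), params=params, follow_up_days=1.0)
        frame = res.to_frame()
        assert set(frame.columns) == {"time_day", "compartment", "activity_Bq"}
        assert frame["compartment"].nunique() == 24
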