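"""Forcing fits, RK4 integration contracts, and scenario behaviour."""

import numpy as np
import pandas as pd
import pytest

from crococompete.errors import DomainError, InsufficientDataError
from crococompete.model_core import EcosystemState, PhytoGroupParams, ZooParams
from crococompete.simulation_engine import (
    NutrientForcing,
    ScenarioConfig,
    fit_nutrient_forcing,
    fit_quadratic_drawdown,
    run_ecosystem_scenario,
    run_incubation,
    scenario_suite,
)


class TestQuadraticForcingFit:
    def test_exact_quadratic_recovered(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        a, b, c = 2.0, -10.0, 50.0
        coeffs = fit_quadratic_drawdown(t, a * t**2 + b * t + c)
        assert coeffs == pytest.approx((a, b, c), abs=1e-9)

    def test_constant_series(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        coeffs = fit_quadratic_drawdown(t, np.full(4, 7.5))
        assert coeffs == pytest.approx((0.0, 0.0, 7.5), abs=1e-9)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        t = np.repeat([0.0, 1.0, 2.0, 3.0], 3)
        truth = (4.0, -45.0, 110.0)
        y = np.clip(truth[0] * t**2 + truth[1] * t + truth[2] + rng.normal(0, 2, t.size),
                    0, None)
        coeffs = fit_quadratic_drawdown(t, y)
        # independent solution of the normal equations
        design = np.vander(t, 3)
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert coeffs == pytest.approx(tuple(oracle), rel=1e-8)
        # and within 3 standard errors of the generating truth
        resid = y - design @ oracle
        sigma2 = resid @ resid / (len(y) - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        assert np.all(np.abs(np.array(oracle) - truth) < 3 * se)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_quadratic_drawdown([0.0, 1.0], [5.0, 4.0])

    @pytest.mark.parametrize("policy,expected_day3", [
        ("half-limit", 3.0), ("zero", 0.0),
    ])
    def test_censoring_substitution(self, policy, expected_day3):
        t = [0.0, 1.0, 2.0, 3.0]
        c = [100.0, 50.0, 20.0, 5.0]  # day 3 at/below a limit of 6
        coeffs = fit_quadratic_drawdown(t, c, detection_limit=6.0, censoring=policy)
        design = np.vander(np.array(t), 3)
        oracle = np.linalg.lstsq(design, [100.0, 50.0, 20.0, expected_day3], rcond=None)[0]
        assert coeffs == pytest.approx(tuple(oracle), abs=1e-9)

    def test_forcing_clips_negative_evaluations(self):
        forcing = NutrientForcing.quadratic((0.0, -10.0, 5.0), (0.0, 0.0, 1.0))
        nut = forcing.at(2.0)  # raw nh4 would be -15
        assert nut.nh4 == 0.0
        assert nut.no3 == 1.0

    def test_fit_nutrient_forcing_combines_both_series(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        forcing = fit_nutrient_forcing(t, 100.0 - 30.0 * t, 50.0 - 10.0 * t,
                                       nh4_detection_limit=0.0, no3_detection_limit=0.0)
        assert forcing.at(1.0).nh4 == pytest.approx(70.0, abs=1e-8)
        assert forcing.at(2.0).no3 == pytest.approx(30.0, abs=1e-8)


class TestIncubationIntegration:
    def test_exponential_closed_form(self):
        p = PhytoGroupParams("X", vmax_nh4=0.8, vmax_no3=0.4, k_nh4=1.0, k_no3=1.0)
        forcing = NutrientForcing.constant(1e12, 1e12)  # fully saturating
        traj = run_incubation([p], forcing, [2.0], t_end=1.0, dt=0.01)
        assert traj.final("X") == pytest.approx(2.0 * np.exp(1.2), rel=1e-6)

    def test_zero_initial_stays_zero(self, cro_params, m3_forcing):
        traj = run_incubation([cro_params], m3_forcing, [0.0], t_end=3.0, dt=0.01)
        assert np.all(traj.pools[cro_params.name] == 0.0)

    def test_rapid_early_growth_of_high_uptake_group(
        self, cro_params, oth_params, m3_forcing
    ):
        traj = run_incubation(
            [cro_params, oth_params], m3_forcing, {"Cro": 5.0, "Oth": 15.0},
            t_end=3.0, dt=0.01,
        )
        day1 = np.searchsorted(traj.time, 1.0)
        cro_fold = traj.pools["Cro"][day1] / traj.pools["Cro"][0]
        oth_fold = traj.pools["Oth"][day1] / traj.pools["Oth"][0]
        assert cro_fold > oth_fold

    def test_step_halving_convergence(self, cro_params, m3_forcing):
        final = {}
        for dt in (0.02, 0.01):
            traj = run_incubation([cro_params], m3_forcing, [5.0], t_end=3.0, dt=dt)
            final[dt] = traj.final("Cro")
        assert abs(final[0.01] - final[0.02]) / final[0.01] < 1e-3

    def test_negative_initial_rejected(self, cro_params, m3_forcing):
        with pytest.raises(DomainError):
            run_incubation([cro_params], m3_forcing, [-1.0], t_end=1.0)


class TestEcosystemIntegration:
    def test_symmetry_preserved(self, zoo_params):
        p = dict(vmax_nh4=1.0, vmax_no3=0.5, k_nh4=50.0, k_no3=50.0)
        cro = PhytoGroupParams("Cro", **p)
        oth = PhytoGroupParams("Oth", **p)
        cfg = ScenarioConfig(
            label="sym", forcing=NutrientForcing.constant(10.0, 10.0),
            initial=EcosystemState(2.0, 2.0, 0.5), fixation_enabled=False,
            t_end=5.0, dt=0.01,
        )
        traj = run_ecosystem_scenario(cfg, cro, oth, zoo_params)
        np.testing.assert_allclose(traj.pools["Cro"], traj.pools["Oth"], rtol=1e-12)

    def test_no_grazing_no_mortality_keeps_relative_abundance(self):
        p = dict(vmax_nh4=1.0, vmax_no3=0.0, k_nh4=50.0, k_no3=50.0)
        cro = PhytoGroupParams("Cro", **p)
        oth = PhytoGroupParams("Oth", **p)
        zoo = ZooParams(g_max=0.0, k_g=5.0, m_zoo=0.0)
        cfg = ScenarioConfig(
            label="free", forcing=NutrientForcing.constant(25.0, 0.0),
            initial=EcosystemState(1.0, 3.0, 1.0), fixation_enabled=False,
            t_end=4.0, dt=0.01,
        )
        traj = run_ecosystem_scenario(cfg, cro, oth, zoo)
        ratio = traj.pools["Cro"] / traj.pools["Oth"]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_fixation_rescues_low_nutrient_biomass(
        self, cro_params, oth_params, zoo_params, ecosystem_initial
    ):
        runs = {}
        for label, fixation in (("B", False), ("C", True)):
            cfg = ScenarioConfig(
                label=label, forcing=NutrientForcing.constant(1.0, 1.0),
                initial=ecosystem_initial, fixation_enabled=fixation,
                t_end=10.0, dt=0.01,
            )
            runs[label] = run_ecosystem_scenario(cfg, cro_params, oth_params, zoo_params)
        assert runs["C"].final("Cro") > runs["B"].final("Cro")

    def test_total_n_budget_audit(self, cro_params, oth_params, zoo_params,
                                  ecosystem_initial):
        """Central-difference d(total N)/dt matches growth minus quadratic
        zooplankton mortality along the stored trajectory."""
        cfg = ScenarioConfig(
            label="audit", forcing=NutrientForcing.constant(10.0, 10.0),
            initial=ecosystem_initial, fixation_enabled=True, t_end=5.0, dt=0.01,
        )
        traj = run_ecosystem_scenario(cfg, cro_params, oth_params, zoo_params)
        total = traj.pools["Cro"] + traj.pools["Oth"] + traj.pools["Zoo"]
        d_total = np.gradient(total, traj.time)
        rhs = (
            traj.growth_rates["Cro"] * traj.pools["Cro"]
            + traj.growth_rates["Oth"] * traj.pools["Oth"]
            - zoo_params.m_zoo * traj.pools["Zoo"] ** 2
        )
        scale = np.maximum(np.abs(rhs), 1e-3)
        # interior points only: np.gradient is first-order at the ends
        assert np.all(np.abs(d_total - rhs)[1:-1] / scale[1:-1] < 1e-2)

    def test_nonnegative_pools_everywhere(self, cro_params, oth_params, zoo_params,
                                          ecosystem_initial):
        trajs = scenario_suite(cro_params, oth_params, zoo_params, ecosystem_initial,
                               t_end=10.0, dt=0.01)
        for traj in trajs.values():
            for series in traj.pools.values():
                assert np.all(series >= 0.0)


class TestScenarioSuite:
    def test_canonical_directions(self, cro_params, oth_params, zoo_params,
                                  ecosystem_initial):
        trajs = scenario_suite(cro_params, oth_params, zoo_params, ecosystem_initial)
        assert trajs["A"].final("Cro") > trajs["A"].final("Oth")
        assert trajs["B"].final("Cro") < trajs["B"].final("Oth")
        assert trajs["C"].final("Cro") > trajs["B"].final("Cro")

    def test_trajectory_csv_round_trip(self, cro_params, oth_params, zoo_params,
                                       ecosystem_initial, tmp_path):
        trajs = scenario_suite(cro_params, oth_params, zoo_params, ecosystem_initial,
                               t_end=1.0, dt=0.1)
        path = tmp_path / "a.csv"
        trajs["A"].to_csv(path)
        text = path.read_text()
        assert text.startswith("# scenario: A")
        frame = pd.read_csv(path, comment="#")
        assert set(frame.columns) == {"time_d", "pool", "value_nmolN_L", "scenario"}
        assert set(frame["pool"]) == {"Cro", "Oth", "Zoo"}
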