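"""Box-model structure: steady state, conservation, feedbacks, convergence."""

from dataclasses import replace

import numpy as np
import pytest

from fernspike import carboncycle as cc


def short_params(t_end=30.0, **kw):
    kw.setdefault("spinup_ky", 2.0)
    return cc.ModelParams(t_end_ky=t_end, **kw)


class TestSteadyState:
    def test_donor_controlled_stocks(self, model_params):
        res, _ = cc.initialize_steady_state(model_params)
        assert res["plant"].mass == pytest.approx(
            model_params.NPP_0 * model_params.tau_plant
        )
        litter = res["plant"].mass / model_params.tau_plant
        assert res["soil"].mass == pytest.approx(litter * model_params.tau_soil)
        assert res["plant"].mass + res["soil"].mass == pytest.approx(2800.0)

    def test_tendencies_below_1e9(self, model_params):
        _, fluxes = cc.initialize_steady_state(model_params)
        tend = cc._tendencies(
            {r.name: r.mass for r in cc.initialize_steady_state(model_params)[0].values()},
            fluxes,
        )
        assert max(abs(v) for v in tend.values()) < 1e-9

    def test_infeasible_params_reported(self):
        # atmosphere mass inconsistent with pCO2_0 leaves a standing air-sea
        # imbalance: no steady state exists.
        with pytest.raises(ValueError, match="air-sea"):
            cc.initialize_steady_state(cc.ModelParams(M_A0=2000.0))

    def test_step_at_steady_state_is_identity(self, model_params):
        res, _ = cc.initialize_steady_state(model_params)
        quiet = cc.ScenarioConfig.control(injection_rate=0.0)
        after = cc.step(res, t_ky=-1.0, dt=1.0, scenario=quiet, params=model_params)
        for name in cc.RESERVOIRS:
            assert after[name].mass == pytest.approx(res[name].mass, rel=1e-12)
            assert after[name].d13c == pytest.approx(res[name].d13c, abs=1e-9)

    def test_injection_only_step_adds_to_atmosphere(self, model_params):
        res, _ = cc.initialize_steady_state(model_params)
        scn = cc.ScenarioConfig.control(injection_rate=0.98)
        after = cc.step(res, t_ky=0.0, dt=1.0, scenario=scn, params=model_params)
        assert after["atmosphere"].mass - res["atmosphere"].mass == pytest.approx(
            0.98, rel=1e-9
        )

    def test_no_injection_drift_below_0p1pct_over_200ky(self):
        params = cc.ModelParams(t_end_ky=200.0, spinup_ky=0.0, save_every=100.0)
        quiet = cc.ScenarioConfig.control(injection_rate=0.0)
        traj = cc.run_scenario(params, quiet)
        for name in cc.RESERVOIRS:
            m = traj.mass[name]
            drift = np.abs(m / m[0] - 1.0).max()
            assert drift < 1e-3, name


class TestPieces:
    @pytest.mark.parametrize(
        "t_ky, reduction, recovery, expected",
        [(-5.0, 0.5, 0.003, 1.0),
         (100.0, 0.5, 0.003, 0.8),
         (500.0, 0.5, 0.003, 1.0)],  # capped at 1
    )
    def test_gpp_multiplier(self, t_ky, reduction, recovery, expected):
        scn = cc.ScenarioConfig.feedback(reduction, recovery_rate_per_ky=recovery)
        assert cc.gpp_multiplier(t_ky, scn) == pytest.approx(expected)

    def test_gpp_multiplier_crosses_070_at_133ky(self):
        scn = cc.ScenarioConfig.feedback(0.7, recovery_rate_per_ky=0.003)
        t = (0.7 - 0.3) / 0.003  # 133.33 ky
        assert cc.gpp_multiplier(t, scn) == pytest.approx(0.7)
        assert cc.gpp_multiplier(t - 1.0, scn) < 0.7

    def test_kerogen_flux_baseline_and_formula(self, model_params):
        assert cc.kerogen_flux(0.0, 0.0, model_params) == model_params.F_ker0
        p = replace(model_params, kerogen_gain=4.0)
        assert cc.kerogen_flux(0.5, 0.0, p) == pytest.approx(3 * p.F_ker0)

    def test_kerogen_flux_monotone_in_deficit_and_warming(self):
        p = cc.ModelParams(kerogen_temp_sensitive=True)
        deficits = np.linspace(0, 1, 11)
        vals = [cc.kerogen_flux(d, 0.0, p) for d in deficits]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        warm = [cc.kerogen_flux(0.5, dT, p) for dT in np.linspace(0, 8, 9)]
        assert all(b >= a for a, b in zip(warm, warm[1:]))

    def test_kerogen_flux_rejects_bad_deficit(self, model_params):
        with pytest.raises(ValueError):
            cc.kerogen_flux(1.5, 0.0, model_params)

    def test_pmol_conversion(self):
        assert cc.pgc_from_pmol(1.0) == pytest.approx(12.011)

    def test_reservoir_validation(self):
        with pytest.raises(ValueError):
            cc.Reservoir("atmosphere", -1.0, -6.5)
        with pytest.raises(ValueError):
            cc.Reservoir("atmosphere", 100.0, -80.0)
        with pytest.raises(ValueError):
            cc.Reservoir("mantle", 100.0, -6.5)


class TestConservation:
    def test_carbon_and_13c_budgets_close(self):
        params = short_params(t_end=30.0)
        scn = cc.ScenarioConfig.feedback(0.5)
        traj = cc.run_scenario(params, scn)
        assert np.abs(traj.conservation).max() < 1e-6
        assert np.abs(traj.conservation_13c).max() < 1e-6

    def test_isotope_identity_limit(self):
        """With zero fractionations and all compositions equal to the
        injected composition, every reservoir's δ¹³C stays constant."""
        params = short_params(
            t_end=10.0, eps_land=0.0, eps_airsea=0.0, d13c_atm0=-6.5, d13c_ker=-6.5
        )
        scn = cc.ScenarioConfig.feedback(0.5, injection_d13c=-6.5)
        traj = cc.run_scenario(params, scn)
        for name in cc.RESERVOIRS:
            assert np.abs(traj.d13c[name] + 6.5).max() < 1e-9


class TestScenarioBehaviour:
    def test_zero_reduction_no_feedbacks_equals_control(self):
        params = short_params(t_end=10.0)
        a = cc.run_scenario(params, cc.ScenarioConfig.control(injection_d13c=-30.0))
        b = cc.run_scenario(
            params,
            cc.ScenarioConfig(
                label="x", gpp_reduction=0.0, injection_d13c=-30.0,
                feedback_biosphere=False, feedback_respiration=False,
                feedback_kerogen=False,
            ),
        )
        assert np.array_equal(a.pco2, b.pco2)
        assert np.array_equal(a.d13c["surface_ocean"], b.d13c["surface_ocean"])

    def test_half_reduction_halves_terrestrial_stock(self):
        params = short_params(t_end=20.0)
        traj = cc.run_scenario(params, cc.ScenarioConfig.feedback(0.5))
        min_frac = traj.terrestrial_stock.min() / traj.terrestrial_stock0
        assert min_frac == pytest.approx(0.5, abs=0.05)

    def test_feedback_surface_d13c_never_above_control(self):
        params = short_params(t_end=60.0)
        ctrl = cc.run_scenario(params, cc.ScenarioConfig.control(injection_d13c=-32.0))
        fb = cc.run_scenario(params, cc.ScenarioConfig.feedback(0.5, injection_d13c=-32.0))
        event = fb.t_ky >= 0
        diff = fb.d13c["surface_ocean"][event] - ctrl.d13c["surface_ocean"][event]
        assert diff.max() < 1e-6

    def test_delta_pco2_nonnegative_when_feedbacks_add_carbon(self):
        params = short_params(t_end=60.0)
        ctrl = cc.run_scenario(params, cc.ScenarioConfig.control(injection_d13c=-32.0))
        fb = cc.run_scenario(params, cc.ScenarioConfig.feedback(0.5, injection_d13c=-32.0))
        assert (fb.pco2 - ctrl.pco2).min() > -1e-6

    def test_amplification_monotone_in_gpp_reduction(self):
        params = short_params(t_end=40.0)
        ctrl = cc.run_scenario(params, cc.ScenarioConfig.control(injection_d13c=-32.0))
        peaks, transfers = [], []
        for red in (0.1, 0.3, 0.5, 0.7):
            fb = cc.run_scenario(
                params, cc.ScenarioConfig.feedback(red, injection_d13c=-32.0)
            )
            d = cc.compare_to_control(fb, ctrl)
            peaks.append(d.peak_delta_pco2)
            transfers.append(d.terrestrial_transfer_pgc)
        assert all(b > a for a, b in zip(peaks, peaks[1:]))
        assert all(b > a for a, b in zip(transfers, transfers[1:]))

    def test_dt_halving_changes_peak_pco2_below_0p5pct(self):
        scn = cc.ScenarioConfig.feedback(0.5)
        coarse = cc.run_scenario(short_params(t_end=15.0), scn)
        fine = cc.run_scenario(short_params(t_end=15.0, dt=0.125), scn)
        assert abs(fine.pco2.max() / coarse.pco2.max() - 1.0) < 5e-3

    def test_compare_identical_runs_gives_zero_diagnostics(self):
        params = short_params(t_end=10.0)
        traj = cc.run_scenario(params, cc.ScenarioConfig.control(injection_d13c=-30.0))
        d = cc.compare_to_control(traj, traj)
        assert d.peak_delta_pco2 == 0.0
        assert d.max_extra_d13c_deepening == 0.0
        assert d.body_mean_delta_pco2 == 0.0 or np.isnan(d.body_mean_delta_pco2)

    def test_mismatched_grids_rejected(self):
        a = cc.run_scenario(short_params(t_end=10.0), cc.ScenarioConfig.control())
        b = cc.run_scenario(short_params(t_end=12.0), cc.ScenarioConfig.control())
        with pytest.raises(ValueError, match="time grid"):
            cc.delta_series(a, b)

    def test_trajectory_dataframe_columns(self):
        traj = cc.run_scenario(short_params(t_end=5.0), cc.ScenarioConfig.control())
        df = traj.to_dataframe()
        for col in ("t_ky", "pCO2_ppm", "dT_C", "mass_plant", "d13c_surface_ocean",
                    "flux_kerogen", "cum_injected"):
            assert col in df.columns
        assert (np.diff(df["t_ky"]) > 0).all()
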