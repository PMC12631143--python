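"""PBPK model: conservation laws, linearity, CKD scaling, closed-form
oracle agreement, calibration recovery, evaluation metrics, sensitivities."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ldmtx import pbpk
from ldmtx.pbpk import Individual, Regimen
from ldmtx.synthetic_data import PKObservationPlan, generate_pk_observations


@pytest.fixture(scope="module")
def ref():
    return pbpk.reference_individual()


def eigen_solution(params, individual, dose_mg, times):
    """Independent closed-form solution of the linear 3-state system."""
    eff = pbpk.scale_to_ckd(params, individual)
    ka, F = params.ka, params.F
    Vc, Vp, Q, cl = eff["Vc"], eff["Vp"], eff["Q"], eff["CL_total"]
    A = np.array([[-ka, 0.0, 0.0],
                  [ka * F, -(cl + Q) / Vc, Q / Vp],
                  [0.0, Q / Vc, -Q / Vp]])
    lam, V = np.linalg.eig(A)
    y0 = np.array([pbpk.dose_mg_to_umol(dose_mg, params.molecular_weight), 0.0, 0.0])
    coef = np.linalg.solve(V, y0)
    states = np.real(V @ (coef[:, None] * np.exp(np.outer(lam, times))))
    return states[1] / Vc


class TestSimulation:
    def test_matches_closed_form_eigen_solution(self, default_params, ref):
        prof = pbpk.simulate_profile(default_params, ref, Regimen(dose_mg=10.0),
                                     dt=0.05)
        oracle = eigen_solution(default_params, ref, 10.0, prof.times_h)
        np.testing.assert_allclose(prof.conc_umol_L, oracle, rtol=1e-8,
                                   atol=1e-12)

    def test_mass_balance_single_and_multiple_doses(self, default_params, ref):
        single = pbpk.simulate_profile(default_params, ref, Regimen(dose_mg=15.0))
        assert single.mass_balance_error() < 1e-3
        multi = pbpk.simulate_profile(default_params, ref,
                                      Regimen(dose_mg=15.0, n_doses=3), dt=0.1)
        assert multi.mass_balance_error() < 1e-3

    def test_cmax_and_auc_linear_in_dose(self, default_params, ref):
        p1 = pbpk.simulate_profile(default_params, ref, Regimen(dose_mg=5.0))
        p2 = pbpk.simulate_profile(default_params, ref, Regimen(dose_mg=10.0))
        assert p2.cmax == pytest.approx(2 * p1.cmax, rel=1e-6)
        assert p2.auc_last == pytest.approx(2 * p1.auc_last, rel=1e-6)

    def test_weekly_steady_state_equals_superposed_single_doses(
            self, default_params, ref):
        n = 3
        multi = pbpk.simulate_profile(default_params, ref,
                                      Regimen(dose_mg=7.5, n_doses=n), dt=0.1)
        single = pbpk.simulate_profile(
            default_params, ref, Regimen(dose_mg=7.5),
            grid=multi.times_h, dt=0.1)
        summed = np.zeros_like(multi.conc_umol_L)
        t = multi.times_h
        step = 168.0
        for k in range(n):
            shifted = np.where(t >= k * step,
                               np.interp(np.maximum(t - k * step, 0.0),
                                         single.times_h, single.conc_umol_L),
                               0.0)
            summed += shifted
        np.testing.assert_allclose(multi.conc_umol_L, summed, rtol=1e-6,
                                   atol=1e-12)

    def test_terminal_slope_matches_two_compartment_closed_form(self, ref):
        # filtration-only limit: no secretion/hepatic/biliary, fu = 1
        params = replace(pbpk.default_parameters(), fu=1.0)
        eff = pbpk.scale_to_ckd(params, ref)
        cl = eff["CL_filtration"]
        Vc, Vp, Q = eff["Vc"], eff["Vp"], eff["Q"]
        # disposition eigenvalues of the 2x2 central/peripheral system
        tr = -(cl + Q) / Vc - Q / Vp
        det = cl * Q / (Vc * Vp)
        lam_z = (tr + math.sqrt(tr**2 - 4 * det)) / 2  # slow eigenvalue
        prof = _simulate_filtration_only(params, ref)
        t, c = prof.times_h, prof.conc_umol_L
        sel = (t > 48) & (t < 120) & (c > 0)
        slope = np.polyfit(t[sel], np.log(c[sel]), 1)[0]
        assert slope == pytest.approx(lam_z, rel=0.01)

    def test_negative_or_invalid_inputs_rejected(self, default_params, ref):
        with pytest.raises(ValueError, match="dose_mg"):
            Regimen(dose_mg=-1.0)
        with pytest.raises(ValueError, match="grid"):
            pbpk.simulate_profile(default_params, ref, Regimen(dose_mg=5.0),
                                  grid=np.array([1.0, 0.5]))


def _simulate_filtration_only(params, ref):
    """Profile with secretion/hepatic/biliary clearances effectively zero.

    Such a parameter set violates the urinary-share invariants on purpose,
    so the integrator pieces are driven directly (the limit check needs the
    bare filtration-only system).
    """
    from scipy.linalg import expm

    bare = replace(params, CL_sec=1e-12, CL_hep=1e-12, CL_bile=1e-12)
    eff = pbpk.scale_to_ckd(bare, ref)
    M = pbpk._system_matrix(bare, eff)
    grid = np.linspace(0.0, 168.0, 1681)
    P = expm(M * (grid[1] - grid[0]))
    y = np.zeros(5)
    y[0] = pbpk.dose_mg_to_umol(10.0, params.molecular_weight)
    conc = np.empty(grid.size)
    for i in range(grid.size):
        conc[i] = y[1] / eff["Vc"]
        y = P @ y
    return pbpk.ConcentrationProfile(times_h=grid, conc_umol_L=conc)


class TestCKDScaling:
    def test_transporter_ratio_halves_at_half_reference_egfr(self, default_params):
        ind = pbpk.reference_individual(egfr=pbpk.EGFR_REF / 2, stage="CKD3a")
        assert ind.transporter_ratio == pytest.approx(0.5)
        eff = pbpk.scale_to_ckd(default_params, ind)
        assert eff["CL_secretion"] == pytest.approx(default_params.CL_sec / 2)

    def test_reference_individual_reproduces_healthy_clearances(
            self, default_params, ref):
        eff = pbpk.scale_to_ckd(default_params, ref)
        assert eff["CL_secretion"] == pytest.approx(default_params.CL_sec)
        assert eff["CL_total"] == pytest.approx(default_params.cl_total_ref)
        assert eff["transporter_ratio"] == pytest.approx(1.0)

    def test_cmax_strictly_decreasing_in_egfr(self, default_params):
        egfrs = np.linspace(30.0, pbpk.EGFR_REF, 12)
        cmax = []
        for e in egfrs:
            ind = pbpk.reference_individual(egfr=float(e), stage="healthy")
            cmax.append(pbpk.simulate_profile(default_params, ind,
                                              Regimen(dose_mg=7.5), dt=0.1).cmax)
        assert np.all(np.diff(cmax) < 0)

    def test_hepatic_multiplier_dial(self, default_params, ref):
        eff = pbpk.scale_to_ckd(default_params, ref, hepatic_multiplier=0.5)
        assert eff["CL_hepatic"] == pytest.approx(default_params.CL_hep / 2)


class TestVirtualPopulation:
    def test_stage_bounds_and_uniform_mean(self):
        pop = pbpk.generate_virtual_population("CKD3b", 1000, seed=2)
        egfr = np.array([p.egfr for p in pop])
        assert egfr.min() >= 30.0 and egfr.max() <= 44.0
        se = (44 - 30) / math.sqrt(12) / math.sqrt(1000)
        assert abs(egfr.mean() - 37.0) < 3 * se

    def test_single_individual_deterministic(self):
        a = pbpk.generate_virtual_population("CKD2", 1, seed=5)[0]
        b = pbpk.generate_virtual_population("CKD2", 1, seed=5)[0]
        assert a == b

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            pbpk.generate_virtual_population("CKD5", 10, seed=0)


class TestCalibration:
    def test_zero_noise_recovery_within_five_percent(self, default_params):
        plan = PKObservationPlan(true_parameters=default_params,
                                 doses_mg=(7.5, 15.0), noise_cv=0.0,
                                 n_subjects_per_dose=1, seed=0,
                                 sampling_times_h=(0.25, 0.5, 1, 2, 3, 4, 6,
                                                   8, 12, 24))
        obs = generate_pk_observations(plan)
        start = replace(default_params, ka=default_params.ka * 1.4,
                        Vc=default_params.Vc * 0.7,
                        CL_sec=default_params.CL_sec * 1.2)
        fitted, report = pbpk.calibrate_healthy(start, obs, seed=1, n_starts=1,
                                                sim_dt=0.05)
        assert fitted.CL_sec == pytest.approx(default_params.CL_sec, rel=0.05)
        assert fitted.cl_renal_ref == pytest.approx(
            default_params.cl_renal_ref, rel=0.05)
        assert fitted.Vc == pytest.approx(default_params.Vc, rel=0.05)
        assert report["objective"] < 1e-4

    def test_noisy_recovery_within_fifteen_percent_across_seeds(
            self, default_params):
        for seed in (7, 8, 9, 10, 11):
            plan = PKObservationPlan(true_parameters=default_params,
                                     noise_cv=0.2, n_subjects_per_dose=12,
                                     seed=seed,
                                     sampling_times_h=(0.25, 0.5, 1, 2, 3, 4,
                                                       6, 8, 12, 24))
            obs = generate_pk_observations(plan)
            start = replace(default_params, ka=default_params.ka * 0.7,
                            Vc=default_params.Vc * 1.3)
            fitted, _ = pbpk.calibrate_healthy(start, obs, seed=seed,
                                               n_starts=1, sim_dt=0.2)
            assert fitted.CL_sec == pytest.approx(default_params.CL_sec,
                                                  rel=0.15)
            assert fitted.cl_renal_ref == pytest.approx(
                default_params.cl_renal_ref, rel=0.15)

    def test_bounds_excluding_truth_reported_as_active(self, default_params):
        plan = PKObservationPlan(true_parameters=default_params,
                                 doses_mg=(7.5, 15.0), noise_cv=0.0,
                                 n_subjects_per_dose=1, seed=0,
                                 sampling_times_h=(0.5, 1, 2, 4, 8, 24))
        obs = generate_pk_observations(plan)
        bounds = {"Vc": (2.0, default_params.Vc * 0.6)}
        fitted, report = pbpk.calibrate_healthy(default_params, obs,
                                                bounds=bounds, seed=0,
                                                n_starts=1, sim_dt=0.2)
        assert "Vc" in report["bound_active"]
        assert fitted.Vc == pytest.approx(default_params.Vc * 0.6, rel=1e-3)

    def test_single_dose_observations_rejected(self, default_params):
        obs = pd.DataFrame({"dose_mg": [7.5] * 3, "time_h": [1, 2, 4],
                            "conc_umol_L": [0.3, 0.2, 0.1]})
        with pytest.raises(ValueError, match="two doses"):
            pbpk.calibrate_healthy(default_params, obs)


class TestEvaluationMetrics:
    def _frames(self, ratio):
        t = [1.0, 2.0, 4.0]
        obs = pd.DataFrame({"study": 1, "time_h": t, "conc_umol_L": [0.4, 0.3, 0.2]})
        pred = obs.copy()
        pred["conc_umol_L"] = obs["conc_umol_L"] * ratio
        return pred, obs

    def test_perfect_prediction_gives_unit_metrics(self):
        pred, obs = self._frames(1.0)
        m = pbpk.evaluate_model(pred, obs)
        assert m.mrd == pytest.approx(1.0)
        assert m.gmfe_abs == pytest.approx(1.0)
        assert m.frac_within_1p25fold == 1.0

    def test_single_tenfold_pair_gives_mrd_ten(self):
        obs = pd.DataFrame({"time_h": [1.0], "conc_umol_L": [0.1]})
        pred = pd.DataFrame({"time_h": [1.0], "conc_umol_L": [1.0]})
        assert pbpk.evaluate_model(pred, obs).mrd == pytest.approx(10.0)

    def test_signed_vs_absolute_fold_error_on_reciprocal_pair(self):
        """Two studies at 2x and 0.5x: absolute GMFE is 2, signed is 1."""
        t = [1.0, 2.0]
        obs = pd.DataFrame({"study": [1, 1, 2, 2], "time_h": t * 2,
                            "conc_umol_L": [0.4, 0.2, 0.4, 0.2]})
        pred = obs.copy()
        pred.loc[pred["study"] == 1, "conc_umol_L"] *= 2.0
        pred.loc[pred["study"] == 2, "conc_umol_L"] *= 0.5
        m = pbpk.evaluate_model(pred, obs)
        assert m.gmfe_abs == pytest.approx(2.0)
        assert m.gmfr_signed == pytest.approx(1.0)

    def test_nonpositive_pairs_dropped_and_counted(self):
        obs = pd.DataFrame({"time_h": [1.0, 2.0], "conc_umol_L": [0.0, 0.2]})
        pred = pd.DataFrame({"time_h": [1.0, 2.0], "conc_umol_L": [0.1, 0.4]})
        m = pbpk.evaluate_model(pred, obs)
        assert m.n_dropped == 1 and m.n_conc_pairs == 1

    def test_printed_literal_mrd_variant_omits_square_root(self):
        obs = pd.DataFrame({"time_h": [1.0], "conc_umol_L": [0.1]})
        pred = pd.DataFrame({"time_h": [1.0], "conc_umol_L": [1.0]})
        literal = pbpk.evaluate_model(pred, obs, mrd_sqrt=False).mrd
        assert literal == pytest.approx(10.0)  # x = 1 either way for one pair
        obs2 = pd.DataFrame({"time_h": [1.0, 2.0], "conc_umol_L": [0.1, 0.1]})
        pred2 = pd.DataFrame({"time_h": [1.0, 2.0], "conc_umol_L": [1.0, 0.1]})
        assert pbpk.evaluate_model(pred2, obs2, mrd_sqrt=False).mrd < \
            pbpk.evaluate_model(pred2, obs2).mrd


class TestSensitivity:
    def test_elasticities_match_analytic_limits(self, default_params, ref):
        sens = pbpk.sensitivity_analysis(default_params, ref,
                                         Regimen(dose_mg=7.5), rel_step=0.02,
                                         dt=0.1)
        assert sens["F"]["auc_last"] == pytest.approx(1.0, abs=0.01)
        cl_sum = (sens["CL_sec"]["auc_last"] + sens["CL_hep"]["auc_last"]
                  + sens["CL_bile"]["auc_last"] + sens["fu"]["auc_last"])
        assert cl_sum == pytest.approx(-1.0, abs=0.02)
        assert abs(sens["Vc"]["auc_last"]) < 0.02

    def test_step_bounds_enforced(self, default_params):
        with pytest.raises(ValueError, match="rel_step"):
            pbpk.sensitivity_analysis(default_params, rel_step=0.9)


class TestParameters:
    def test_invariant_violations_named(self):
        with pytest.raises(ValueError, match="renal share"):
            replace(pbpk.default_parameters(), CL_hep=10.0).validate()
        with pytest.raises(ValueError, match="secretion"):
            replace(pbpk.default_parameters(), CL_sec=30.0).validate()
        with pytest.raises(ValueError, match="must be > 0"):
            replace(pbpk.default_parameters(), Vc=-1.0).validate()

    def test_parameter_file_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.txt"
        pbpk.write_parameters(default_params, path)
        assert pbpk.read_parameters(path) == default_params

    def test_unknown_parameter_key_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("nonsense = 1.0\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            pbpk.read_parameters(path)
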