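"""Response functions and joint least-squares fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrquant.binding_models import (
    ec50_from_fit,
    fit_binding,
    logistic_response,
    occupancy,
    one_phase_decay,
    specific_binding,
)
from tcrquant.synthetic_data import (
    GroundTruth,
    simulate_dissociation,
    simulate_dose_response,
)


class TestResponseFunctions:
    @pytest.mark.parametrize(
        "conc,kd,expected",
        [(50.0, 50.0, 0.5), (0.0, 50.0, 0.0), (150.0, 50.0, 0.75)],
    )
    def test_occupancy_analytic_points(self, conc, kd, expected):
        assert occupancy(conc, kd) == pytest.approx(expected)

    def test_occupancy_rejects_nonpositive_kd(self):
        with pytest.raises(ValueError):
            occupancy(10.0, 0.0)

    @given(st.floats(0.0, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_occupancy_bounded_unit_interval(self, conc, kd):
        assert 0.0 <= occupancy(conc, kd) < 1.0

    def test_occupancy_monotone_in_concentration(self):
        c = np.logspace(-3, 4, 100)
        y = occupancy(c, 25.0)
        assert np.all(np.diff(y) > 0)

    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0])
    def test_specific_binding_midpoint_invariant_under_hill(self, h):
        # response at conc = kd is bmax/2 for any Hill slope
        assert specific_binding(50.0, 800.0, 50.0, h) == pytest.approx(400.0)

    def test_hill_slope_steepens_above_midpoint(self):
        assert specific_binding(100.0, 800.0, 50.0, 4.0) > specific_binding(100.0, 800.0, 50.0, 1.0)

    def test_one_site_equals_bmax_times_occupancy(self):
        c = np.logspace(-2, 3, 30)
        np.testing.assert_allclose(specific_binding(c, 700.0, 20.0, 1.0), 700.0 * occupancy(c, 20.0))

    def test_decay_boundary_and_half_life(self):
        plateau, span, koff = 100.0, 800.0, 0.85
        assert one_phase_decay(0.0, plateau, span, koff) == pytest.approx(plateau + span)
        assert one_phase_decay(np.log(2) / koff, plateau, span, koff) == pytest.approx(plateau + span / 2)
        assert one_phase_decay(1e6, plateau, span, koff) == pytest.approx(plateau)

    def test_decay_monotone_in_time(self):
        t = np.linspace(0, 10, 50)
        assert np.all(np.diff(one_phase_decay(t, 10.0, 500.0, 0.5)) < 0)

    def test_logistic_midpoint(self):
        assert logistic_response(19.5, 0.0, 1000.0, 19.5, 1.3) == pytest.approx(500.0)


class TestFitBinding:
    def test_one_site_zero_noise_roundtrip(self, one_site_clean):
        fit = fit_binding(one_site_clean, "one_site")
        assert fit.converged
        assert fit.params["A"]["bmax"] == pytest.approx(1000.0, rel=1e-6)
        assert fit.params["A"]["kd"] == pytest.approx(50.0, rel=1e-6)

    @pytest.mark.parametrize(
        "truth_kind,params,family",
        [
            ("binding", {"bmax": 1200.0, "kd": 30.0, "h": 1.6}, "hill"),
            ("logistic", {"bottom": 50.0, "top": 900.0, "ec50": 19.5}, "logistic3"),
            ("logistic", {"bottom": 50.0, "top": 900.0, "ec50": 19.5, "hill": 1.3}, "logistic4"),
        ],
    )
    def test_zero_noise_roundtrips(self, truth_kind, params, family):
        truth = GroundTruth(truth_kind, params, noise_cv=0.0, seed=3)
        fit = fit_binding(simulate_dose_response(truth, condition_label="A"), family)
        for name, val in params.items():
            assert fit.params["A"][name] == pytest.approx(val, rel=1e-6), name

    def test_decay_zero_noise_roundtrip(self):
        truth = GroundTruth("decay", {"plateau": 100.0, "span": 800.0, "koff": 0.85}, noise_cv=0.0, seed=3)
        ds = simulate_dissociation(truth, np.linspace(0, 6, 8))
        fit = fit_binding(ds, "decay")
        assert fit.params["sim"]["koff"] == pytest.approx(0.85, rel=1e-6)

    def test_shared_kd_gains_one_df_at_zero_noise(self):
        t1 = GroundTruth("binding", {"bmax": 1000.0, "kd": 40.0}, noise_cv=0.0, seed=1)
        t2 = GroundTruth("binding", {"bmax": 1500.0, "kd": 40.0}, noise_cv=0.0, seed=2)
        a = simulate_dose_response(t1, condition_label="A")
        b = simulate_dose_response(t2, condition_label="B")
        free = fit_binding([a, b], "one_site", share=set())
        shared = fit_binding([a, b], "one_site", share={"kd"})
        assert free.ss_resid == pytest.approx(0.0, abs=1e-12)
        assert shared.ss_resid == pytest.approx(0.0, abs=1e-12)
        assert shared.df == free.df + 1

    def test_joint_fit_full_sharing_matches_single_dataset_objective(self, one_site_truth):
        a = simulate_dose_response(one_site_truth, condition_label="A")
        b_rec = a.records.copy()
        b = type(a)(condition_label="B", records=b_rec)
        single = fit_binding(a, "one_site")
        joint = fit_binding([a, b], "one_site", share={"bmax", "kd"})
        assert joint.params["A"]["kd"] == pytest.approx(single.params["A"]["kd"], rel=1e-8)

    def test_noisy_kd_recovery_within_ten_percent_median(self):
        errs = []
        for seed in range(200):
            truth = GroundTruth("binding", {"bmax": 1000.0, "kd": 50.0}, noise_cv=0.1, seed=seed)
            ds = simulate_dose_response(truth, n_reps=3, condition_label="A")
            fit = fit_binding(ds, "one_site", n_starts=3)
            errs.append(abs(fit.params["A"]["kd"] / 50.0 - 1.0))
        assert np.median(errs) < 0.10

    def test_fitted_ss_matches_grid_search_oracle(self):
        # independent coarse-to-fine grid search over (bmax, kd)
        truth = GroundTruth("binding", {"bmax": 900.0, "kd": 25.0}, noise_cv=0.1, seed=11)
        ds = simulate_dose_response(truth, condition_label="A")
        fit = fit_binding(ds, "one_site")
        c, y = ds.concentrations, ds.responses
        best = np.inf
        for kd in np.geomspace(1.0, 600.0, 4000):
            occ = c / (kd + c)
            bmax = float(np.dot(occ, y) / np.dot(occ, occ))  # profile bmax analytically
            best = min(best, float(np.sum((bmax * occ - y) ** 2)))
        assert fit.ss_resid <= best * (1 + 1e-3)

    def test_underdetermined_rejected(self, one_site_truth):
        ds = simulate_dose_response(one_site_truth, doses=[1.0, 2.0, 4.0, 8.0], n_reps=1)
        with pytest.raises(ValueError, match="under-determined"):
            fit_binding(ds, "logistic4")

    def test_too_few_distinct_doses_rejected(self, one_site_truth):
        ds = simulate_dose_response(one_site_truth, doses=[1.0, 10.0, 100.0], n_reps=4)
        with pytest.raises(ValueError, match="distinct"):
            fit_binding(ds, "one_site")

    def test_degenerate_constant_responses_flagged_nonidentifiable(self, one_site_clean):
        rec = one_site_clean.records.copy()
        rec["response"] = 500.0
        ds = type(one_site_clean)(condition_label="A", records=rec)
        fit = fit_binding(ds, "one_site")
        assert not fit.identifiable
        assert fit.params["A"]["bmax"] == pytest.approx(500.0)
        assert np.isnan(fit.params["A"]["kd"])


class TestEC50:
    def test_zero_noise_ec50_exact(self):
        truth = GroundTruth("logistic", {"bottom": 0.0, "top": 1000.0, "ec50": 19.5, "hill": 1.0}, noise_cv=0.0, seed=1)
        fit = fit_binding(simulate_dose_response(truth, condition_label="A"), "logistic4")
        est, se = ec50_from_fit(fit)
        assert est == pytest.approx(19.5, rel=1e-6)
        assert se == pytest.approx(0.0, abs=1e-6)

    def test_logistic4_hill_fixed_one_nests_logistic3(self):
        truth = GroundTruth("logistic", {"bottom": 20.0, "top": 800.0, "ec50": 40.0}, noise_cv=0.05, seed=5)
        ds = simulate_dose_response(truth, condition_label="A")
        f3 = fit_binding(ds, "logistic3")
        f4 = fit_binding(ds, "logistic4", fixed={"hill": 1.0})
        assert f4.params["A"]["ec50"] == pytest.approx(f3.params["A"]["ec50"], rel=1e-6)
        assert f3.df == f4.df

    def test_noisy_ec50_recovery_within_fifteen_percent_median(self):
        errs = []
        for seed in range(100):
            truth = GroundTruth(
                "logistic", {"bottom": 0.0, "top": 1000.0, "ec50": 19.5, "hill": 1.0}, noise_cv=0.1, seed=seed
            )
            ds = simulate_dose_response(truth, n_reps=3, condition_label="A")
            fit = fit_binding(ds, "logistic3", n_starts=3)
            est, _ = ec50_from_fit(fit)
            errs.append(abs(est / 19.5 - 1.0))
        assert np.median(errs) < 0.15

    def test_requires_logistic_family(self, one_site_clean):
        fit = fit_binding(one_site_clean, "one_site")
        with pytest.raises(ValueError):
            ec50_from_fit(fit)
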