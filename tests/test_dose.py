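"""Log-logistic surface fitting, charge bins, half-max charge inference."""

import numpy as np
import pandas as pd
import pytest

from vnspupil import (assign_charge_bins, binwise_tests, compare_full_vs_reduced,
                      compare_half_max, fit_surface, half_max_charge,
                      surface_full, surface_reduced)
from vnspupil import synth
from vnspupil.synth import (FULL_GRID, GroundTruthParams, SurfaceTruth,
                            generate_protocol, generate_trial_scalars, null_truth)


def grid_trials(reps=3, grid=FULL_GRID, seed=0):
    protocol = generate_protocol(grid, repetitions=reps, seed=seed)
    A = np.array([e.amplitude for e in protocol])
    W = np.array([e.width for e in protocol])
    R = np.array([e.rate for e in protocol])
    return pd.DataFrame({"amplitude_ma": A, "width_ms": W, "rate_hz": R,
                         "charge_uc": A * W})


class TestFitSurface:
    def test_noiseless_full_surface_recovered_to_1e3(self):
        truth = dict(s=10.0, a1=0.4, b1=2.0, a2=0.3, b2=2.0, a3=9.0, b3=2.0)
        t = grid_trials(reps=3)
        t["response_pupil"] = surface_full(t["amplitude_ma"], t["width_ms"],
                                           t["rate_hz"], **truth)
        fit = fit_surface(t, model="full")
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-3)
        assert fit.variance_explained == pytest.approx(100.0, abs=1e-6)

    def test_noiseless_reduced_surface_recovered(self):
        t = grid_trials(reps=2)
        t["response_pupil"] = surface_reduced(t["charge_uc"], t["rate_hz"],
                                              10.0, 0.15, 2.0, 9.0, 2.0)
        fit = fit_surface(t, model="reduced")
        assert fit.params["a1"] == pytest.approx(0.15, rel=1e-3)
        assert fit.params["s"] == pytest.approx(10.0, rel=1e-3)

    def test_constant_responses_explain_no_variance(self):
        t = grid_trials(reps=2)
        t["response_pupil"] = 5.0
        fit = fit_surface(t, model="reduced")
        assert abs(fit.variance_explained) < 1.0

    def test_monotone_in_every_factor(self):
        truth = GroundTruthParams()
        protocol = generate_protocol(FULL_GRID, repetitions=5, seed=1)
        t = generate_trial_scalars(protocol, truth, seed=2)
        fit = fit_surface(t, model="full")
        for a in (0.1, 0.3, 0.5, 0.7, 0.9):
            for w in (0.1, 0.2, 0.4, 0.8):
                pred = [float(surface_full(a, w, r, **fit.params))
                        for r in (5.0, 10.0, 20.0)]
                assert pred == sorted(pred)
        grid = pd.DataFrame({"amplitude_ma": np.linspace(0.1, 0.9, 9),
                             "width_ms": 0.2, "rate_hz": 10.0})
        pred = fit.predict(grid.assign(charge_uc=grid["amplitude_ma"] * 0.2))
        assert np.all(np.diff(pred) >= -1e-12)

    def test_reduced_model_depends_only_on_charge(self):
        t = grid_trials(reps=1)
        t["response_pupil"] = surface_reduced(t["charge_uc"], t["rate_hz"],
                                              8.0, 0.2, 2.0, 9.0, 2.0)
        fit = fit_surface(t, model="reduced")
        same_charge = pd.DataFrame({
            "amplitude_ma": [0.2, 0.8], "width_ms": [0.8, 0.2],
            "rate_hz": [10.0, 10.0], "charge_uc": [0.16, 0.16]})
        p = fit.predict(same_charge)
        assert p[0] == pytest.approx(p[1], rel=1e-12)

    def test_multistart_best_not_worse_than_any_start(self):
        truth = GroundTruthParams()
        protocol = generate_protocol(FULL_GRID, repetitions=2, seed=3)
        t = generate_trial_scalars(protocol, truth, seed=4)
        fit = fit_surface(t, model="reduced")
        best_cost = 0.5 * fit.ss_res
        assert all(best_cost <= c + 1e-9 for c in fit.start_losses)

    def test_artifact_rows_excluded(self):
        t = grid_trials(reps=1)
        t["response_pupil"] = surface_reduced(t["charge_uc"], t["rate_hz"],
                                              8.0, 0.2, 2.0, 9.0, 2.0)
        t["artifact"] = False
        t.loc[t.index[:5], "artifact"] = True
        t.loc[t.index[:5], "response_pupil"] = np.nan
        fit = fit_surface(t, model="reduced")
        assert fit.n_trials == len(t) - 5


class TestFullVsReduced:
    def test_charge_equivalent_truth_gives_matching_variance(self):
        # responses built from charge only: the separable full surface can
        # approximate but never exactly represent a charge sigmoid (only
        # power laws factor through a product), leaving a small structural
        # gap; at trial-level noise the two fits must agree within ~1.5% VE
        # and the full model must not *beat* the reduced one materially
        truth = GroundTruthParams()  # reduced-form pupil surface
        protocol = generate_protocol(FULL_GRID, repetitions=15, seed=5)
        t = generate_trial_scalars(protocol, truth, seed=6)
        rep = compare_full_vs_reduced(t)
        assert abs(rep["difference"]) < 1.5
        assert rep["difference"] < 0.5

    def test_charge_violation_detected(self):
        # width-only dependence cannot be expressed through charge alone
        t = grid_trials(reps=10, seed=7)
        rng = np.random.default_rng(8)
        t["response_pupil"] = (10.0 / (1 + (t["width_ms"] / 0.3) ** -4)
                               + rng.normal(0, 1.0, len(t)))
        rep = compare_full_vs_reduced(t)
        assert rep["difference"] > 2.0


class TestChargeBins:
    def test_log_spaced_edges_and_extreme_assignment(self):
        t = grid_trials(reps=1)
        bins = assign_charge_bins(t, n_bins=5)
        edges = bins.edges
        np.testing.assert_allclose(np.diff(np.log10(edges)),
                                   np.diff(np.log10(edges))[0], rtol=1e-9)
        assert edges[0] == pytest.approx(0.01)
        assert edges[-1] == pytest.approx(0.72)
        cmin = t["charge_uc"].idxmin()
        cmax = t["charge_uc"].idxmax()
        assert bins.assignment[cmin] == 1
        assert bins.assignment[cmax] == 5

    def test_every_amplitude_width_combination_mapped(self):
        t = grid_trials(reps=1)
        bins = assign_charge_bins(t, n_bins=5)
        mapping = bins.mapping_table(t)
        assert len(mapping) == 20  # 5 amplitudes x 4 widths
        assert mapping["charge_bin"].between(1, 5).all()
        assert bins.assignment.notna().all()

    def test_degenerate_single_charge_warns(self):
        t = pd.DataFrame({"charge_uc": np.full(10, 0.1)})
        with pytest.warns(UserWarning, match="single occupied bin"):
            bins = assign_charge_bins(t, n_bins=5)
        assert bins.assignment.nunique() == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            assign_charge_bins(grid_trials(), n_bins=1)

    def test_labels_no_effect_optimal_off_target(self):
        bins = assign_charge_bins(grid_trials(), n_bins=5)
        assert bins.labels == ["no-effect", "optimal", "optimal", "optimal",
                               "off-target"]


class TestBinwiseTests:
    def test_strong_effect_bins_significant(self):
        truth = GroundTruthParams(scalar_noise_sd=1.0)
        protocol = generate_protocol(FULL_GRID, repetitions=20, seed=9)
        t = generate_trial_scalars(protocol, truth, seed=10)
        bins = assign_charge_bins(t, n_bins=5)
        res = binwise_tests(t, bins, mode="vs_zero", q=0.05)
        tab = res.table
        upper = tab.loc[tab["charge_bin"] >= 3]
        assert upper["significant"].all()
        assert (tab.loc[tab["significant"], "stars"] != "").all()

    def test_null_generator_rarely_rejects(self):
        protocol = generate_protocol(FULL_GRID, repetitions=2, seed=0)
        n_any = 0
        for seed in range(40):
            t = generate_trial_scalars(protocol, null_truth(), seed=seed)
            bins = assign_charge_bins(t, n_bins=5)
            res = binwise_tests(t, bins, mode="vs_zero", q=0.05)
            n_any += int(res.table["significant"].any())
        assert n_any <= 6  # ~5% familywise under the global null

    def test_vs_lowest_bin_mode_skips_lowest(self):
        truth = GroundTruthParams()
        protocol = generate_protocol(FULL_GRID, repetitions=5, seed=11)
        t = generate_trial_scalars(protocol, truth, seed=12)
        bins = assign_charge_bins(t, n_bins=5)
        res = binwise_tests(t, bins, response="response_calcium",
                            mode="vs_lowest_bin", q=0.05)
        lowest = res.table.loc[res.table["charge_bin"] == 1]
        assert lowest["p"].isna().all()  # reference bin never tested vs itself


class TestHalfMax:
    def test_noiseless_estimate_exact_with_zero_sd(self):
        t = grid_trials(reps=2)
        t["response_pupil"] = surface_reduced(t["charge_uc"], t["rate_hz"],
                                              10.0, 0.2, 2.0, 9.0, 2.0)
        hm = half_max_charge(t, n_boot=50, seed=0)
        assert hm["estimate_uc"] == pytest.approx(0.2, rel=1e-4)
        assert hm["bootstrap_sd_uc"] < 1e-3

    def test_bootstrap_sd_tracks_replicate_sd(self):
        """The bootstrap SD of the half-max charge must match the SD of the
        estimate across independent synthetic replicates (30%)."""
        # moderate noise keeps the estimator in its regular regime, where
        # the bootstrap approximation is expected to hold
        truth = GroundTruthParams(scalar_noise_sd=1.0, trial_lognormal_sigma=0.2)
        protocol = generate_protocol(FULL_GRID, repetitions=5, seed=13)
        estimates = []
        for seed in range(40):
            t = generate_trial_scalars(protocol, truth, seed=100 + seed)
            fit = fit_surface(t, model="reduced")
            estimates.append(fit.params["a1"])
        replicate_sd = np.std(estimates)
        t = generate_trial_scalars(protocol, truth, seed=200)
        hm = half_max_charge(t, n_boot=400, seed=0)
        assert hm["bootstrap_sd_uc"] == pytest.approx(replicate_sd, rel=0.3)

    def test_compare_half_max_identical_draws_p_one(self):
        draws = np.random.default_rng(0).normal(0.15, 0.02, 400)
        assert compare_half_max(draws, draws) == pytest.approx(1.0)

    def test_compare_half_max_separated_draws_floor(self):
        d1 = np.full(400, 0.64)
        d2 = np.full(400, 0.15)
        assert compare_half_max(d1, d2) == pytest.approx(2.0 / 400)

    def test_compare_half_max_calibrated_under_null(self):
        # same-truth draw sets: p should be roughly uniform, rarely tiny
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(200):
            d1 = rng.normal(0.15, 0.02, 250)
            d2 = rng.normal(0.15, 0.02, 250)
            ps.append(compare_half_max(d1, d2))
        assert np.mean(np.asarray(ps) < 0.05) < 0.12
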