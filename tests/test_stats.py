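"""Sequential polynomial regression, BH-FDR, cluster permutation test,
phase-locked spectral power."""

import numpy as np
import pytest
from scipy import stats as spstats

from vnspupil import (bh_fdr, cluster_permutation_map, phase_locked_power,
                      sequential_poly_regression)
from vnspupil.synth import GroundTruthParams, IMAGING_GRID, \
    generate_image_stack, generate_protocol


class TestSequentialPoly:
    def test_linear_truth_selects_order_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 300)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.5, 300)
        res = sequential_poly_regression(y, x)
        assert res.selected_order == 1
        assert res.f_pvalues[0] < 1e-6
        assert res.f_pvalues[1] > 0.05

    def test_inverted_u_selects_order_two(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        y = -(x - 5.0) ** 2 + rng.normal(0, 0.5, 300)
        res = sequential_poly_regression(y, x)
        assert res.selected_order == 2
        assert res.selected_order_bic == 2

    def test_f_statistics_match_nested_ols_oracle(self):
        # brute-force nested OLS on the raw (non-orthogonalized) design
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = 120
            x = rng.uniform(-3, 3, n)
            y = rng.normal(0, 1, n) + rng.uniform(-1, 1) * x
            res = sequential_poly_regression(y, x)

            def ss_res(order):
                X = np.column_stack([x ** k for k in range(order + 1)])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ beta
                return r @ r

            ss = [ss_res(k) for k in range(3)]
            mse_full = ss[2] / (n - 3)
            for k in (1, 2):
                f_oracle = (ss[k - 1] - ss[k]) / mse_full
                assert res.f_stats[k - 1] == pytest.approx(f_oracle, abs=1e-8)

    def test_orthogonalized_fit_reproduces_raw_fitted_values(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 200)
        y = 1.0 + 0.5 * x - 0.2 * x ** 2 + rng.normal(0, 0.3, 200)
        res = sequential_poly_regression(y, x)
        X = np.column_stack([np.ones_like(x), x, x ** 2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.fitted, X @ beta, atol=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sequential_poly_regression(np.arange(10.0), np.full(10, 2.0))


class TestBHFDR:
    def test_all_ones_no_rejections(self):
        adj, rej = bh_fdr(np.ones(20), q=0.05)
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_pvalue_identity(self):
        adj, rej = bh_fdr([0.01], q=0.05)
        assert rej[0]
        assert adj[0] == pytest.approx(0.01)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        # oracle: explicit step-up rule — reject all p(i) with
        # p(i) <= max{ p(j) : p(j) <= q j/m }
        rng = np.random.default_rng(4)
        for _ in range(1000):
            m = rng.integers(1, 25)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.3, 3)
            _, rej = bh_fdr(p, q=0.05)
            order = np.argsort(p)
            ps = p[order]
            thresh = 0.05 * (np.arange(1, m + 1) / m)
            passing = np.flatnonzero(ps <= thresh)
            oracle = np.zeros(m, dtype=bool)
            if passing.size:
                oracle[order[: passing.max() + 1]] = True
            np.testing.assert_array_equal(rej, oracle)

    def test_nan_excluded_from_family(self):
        adj, rej = bh_fdr([0.01, np.nan, 0.04], q=0.05)
        assert np.isnan(adj[1]) and not rej[1]
        assert rej[0]


class TestClusterPermutation:
    def test_planted_effect_recovered_with_high_jaccard(self):
        protocol = generate_protocol(IMAGING_GRID, repetitions=1, seed=0)
        stack, mask = generate_image_stack(GroundTruthParams(), protocol,
                                           shape=(48, 48), seed=1,
                                           mask_pixels=600, effect_size=1.2)
        res = cluster_permutation_map(stack, n_perm=500, cluster_alpha=0.01,
                                      seed=2)
        inter = np.logical_and(res.significant_mask, mask).sum()
        union = np.logical_or(res.significant_mask, mask).sum()
        assert inter / union > 0.8
        assert res.n_significant >= 0.75 * mask.sum()

    def test_single_pixel_effect_rejected_by_cluster_size(self):
        rng = np.random.default_rng(5)
        stack = rng.normal(0, 1, (30, 32, 32))
        # clearly suprathreshold isolated pixel (t ~ 4); its cluster sum
        # cannot beat the null maximum over 1024 pixels' noise clusters
        stack[:, 16, 16] += 0.75
        res = cluster_permutation_map(stack, n_perm=500, cluster_alpha=0.01,
                                      seed=6)
        assert not res.significant_mask[16, 16]

    def test_null_stack_rarely_significant(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            stack = rng.normal(0, 1, (12, 32, 32))
            res = cluster_permutation_map(stack, n_perm=300,
                                          cluster_alpha=0.01, seed=seed)
            hits += int(res.n_significant > 0)
        assert hits <= 2

    def test_pvalues_have_permutation_floor(self):
        rng = np.random.default_rng(7)
        stack = rng.normal(0, 1, (20, 16, 16))
        stack[:, 4:10, 4:10] += 2.0
        res = cluster_permutation_map(stack, n_perm=200, seed=8)
        assert min(res.cluster_p) >= 1.0 / 201.0
        assert max(res.cluster_p) <= 1.0

    def test_agrees_with_mne_reference_on_strong_effect(self):
        # cross-check against the reference cluster permutation machinery
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(9)
        stack = rng.normal(0, 1, (24, 24, 24))
        stack[:, 6:14, 6:14] += 1.0
        res = cluster_permutation_map(stack, n_perm=800, cluster_alpha=0.01,
                                      seed=10)
        thresh = res.threshold_t
        X = stack.reshape(24, -1)
        from scipy.sparse import coo_matrix
        import mne

        adj = mne.stats.combine_adjacency(24, 24)
        _, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            X.reshape(24, 24, 24), threshold=thresh, n_permutations=800,
            adjacency=adj, tail=0, seed=11, out_type="mask", verbose=False)
        mne_mask = np.zeros((24, 24), dtype=bool)
        for cl, p in zip(clusters, pvals):
            if p < 0.01:
                mne_mask |= cl.reshape(24, 24)
        ours = res.significant_mask
        inter = np.logical_and(ours, mne_mask).sum()
        union = np.logical_or(ours, mne_mask).sum()
        assert union > 0
        assert inter / union > 0.8

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            cluster_permutation_map(np.zeros((4, 8, 8)), n_perm=10)


class TestPhaseLockedPower:
    def _epochs_with_tone(self, rate_hz, n_trials=20, fs=50.0,
                          epoch=(-10.0, 20.0), seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(epoch[0], epoch[1], 1 / fs)
        out = []
        for _ in range(n_trials):
            x = rng.normal(0, 1.0, t.size)
            during = (t >= 0) & (t < 10.0)
            x[during] += 2.0 * np.sin(2 * np.pi * rate_hz * t[during])
            out.append(x)
        return np.asarray(out), t

    def test_injected_tone_detected_at_train_rate_only(self):
        epochs, t = self._epochs_with_tone(10.0)
        res = phase_locked_power(epochs, 10.0, fs=50.0, epoch_start=t[0])
        assert res.phase_locked_power > 100.0  # % change vs baseline
        off = phase_locked_power(epochs, 5.0, fs=50.0, epoch_start=t[0])
        assert off.phase_locked_power < 0.3 * res.phase_locked_power

    def test_stationary_noise_scalar_near_zero(self):
        rng = np.random.default_rng(1)
        epochs = rng.normal(0, 1, (40, 1500))
        res = phase_locked_power(epochs, 10.0, fs=50.0, epoch_start=-10.0)
        assert abs(res.phase_locked_power) < 15.0

    def test_baseline_change_near_zero_per_frequency(self):
        rng = np.random.default_rng(2)
        epochs = rng.normal(0, 1, (40, 1500))
        res = phase_locked_power(epochs, 10.0, fs=50.0, epoch_start=-10.0)
        base = (res.times >= -5.5) & (res.times < -0.5)
        np.testing.assert_allclose(res.power_change[:, base].mean(axis=1),
                                   0.0, atol=1e-9)

    def test_spectrogram_peak_within_one_bin_of_tone(self):
        epochs, t = self._epochs_with_tone(20.0, fs=50.0)
        res = phase_locked_power(epochs, 20.0, fs=50.0, epoch_start=t[0])
        during = (res.times >= 0) & (res.times < 10)
        prof = res.power_change[:, during].mean(axis=1)
        peak_f = res.freqs[np.argmax(prof)]
        assert abs(peak_f - 20.0) <= res.freqs[1] - res.freqs[0]

    def test_rate_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            phase_locked_power(np.zeros((10, 500)), 25.0, fs=50.0,
                               epoch_start=-5.0)

    def test_grounded_sessions_show_phase_locking_ungrounded_do_not(self):
        from vnspupil import AnalysisConfig, condition_session, epoch as do_epoch
        from vnspupil import synth
        from vnspupil.session import SessionMeta

        cfg = AnalysisConfig()
        protocol = synth.generate_protocol(((0.5,), (0.4,), (10.0,)),
                                           repetitions=8, seed=0,
                                           intertrain=(40.0, 45.0), t_start=40.0)
        scalars = {}
        for grounded in (True, False):
            truth = synth.GroundTruthParams(blink_rate_per_min=0.0)
            rec, _ = synth.generate_session(
                protocol, truth, seed=20, pupil_rate=50.0,
                meta=SessionMeta(grounded=grounded))
            cond = condition_session(rec, cfg)
            ep = do_epoch(cond["eye_x"], rec.events, (-10.0, 20.0))
            res = phase_locked_power(ep.data, 10.0, fs=50.0, epoch_start=-10.0)
            scalars[grounded] = res.phase_locked_power
        assert scalars[True] > 100.0
        assert scalars[False] < 0.3 * scalars[True]
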