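"""Inferential machinery: peak lags, correlation nulls, controls, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from laglayer import (
    EncodingConfig,
    NeuralRecording,
    SyntheticConfig,
    ValidationError,
    bh_fdr,
    bootstrap_electrode_means,
    generate_neural_dataset,
    levene_peak_lag_spread,
    lag_layer_correlation,
    orthogonalize_layer,
    paired_ttest_layers,
    peak_lags,
    pearson_exact_p,
    permutation_test_layer_index,
    phase_randomize,
    select_electrodes,
)


class TestPeakLags:
    def test_unique_maximum(self):
        lags = np.array([-50.0, 0.0, 150.0, 300.0])
        m = np.array([[0.1, 0.2, 0.9, 0.3]])
        assert peak_lags(m, lags)[0] == 150.0

    def test_ties_break_toward_earliest_lag(self):
        lags = np.array([-25.0, 0.0, 25.0])
        m = np.array([[0.5, 0.1, 0.5]])
        assert peak_lags(m, lags)[0] == -25.0

    def test_all_missing_row_rejected(self):
        with pytest.raises(ValidationError):
            peak_lags(np.array([[np.nan, np.nan]]), np.array([0.0, 25.0]))


class TestLagLayerCorrelation:
    def test_linear_lags_give_pearson_one(self):
        layers = np.arange(1, 11)
        r_p, r_s = lag_layer_correlation(10.0 * layers + 5, layers)
        assert r_p == pytest.approx(1.0)
        assert r_s == pytest.approx(1.0)

    def test_convex_monotone_lags_spearman_one_pearson_below(self):
        layers = np.arange(1, 11)
        r_p, r_s = lag_layer_correlation((layers ** 3).astype(float), layers)
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_matches_hand_computed_covariance_formula(self):
        layers = np.arange(1, 6, dtype=float)
        lags = np.array([10.0, 30.0, 20.0, 50.0, 40.0])
        cov = np.mean((layers - layers.mean()) * (lags - lags.mean()))
        r_manual = cov / (layers.std() * lags.std())
        r_p, _ = lag_layer_correlation(lags, layers)
        assert r_p == pytest.approx(r_manual, abs=1e-12)

    def test_zero_variance_lags_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r_p, r_s = lag_layer_correlation(np.zeros(5), np.arange(5))
        assert np.isnan(r_p) and np.isnan(r_s)


class TestPearsonExactP:
    def test_r_zero_gives_p_one(self):
        for n in (4, 10, 48):
            assert pearson_exact_p(0.0, n) == pytest.approx(1.0)

    def test_monotone_in_abs_r_and_n(self):
        ps_r = [pearson_exact_p(r, 20) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps_r, ps_r[1:]))
        ps_n = [pearson_exact_p(0.5, n) for n in (5, 10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ps_n, ps_n[1:]))

    def test_matches_t_distribution_mapping(self):
        r, n = 0.6, 25
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p_t = 2 * sps.t.sf(t, df=n - 2)
        assert pearson_exact_p(r, n) == pytest.approx(p_t, rel=1e-9)

    def test_matches_monte_carlo_null_small_n(self):
        """Simulation oracle: tail mass of the null correlation at n=5."""
        g = np.random.default_rng(0)
        n_sim = 200_000
        x = g.standard_normal((n_sim, 5))
        y = g.standard_normal((n_sim, 5))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r_null = (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1)
        )
        frac = (np.abs(r_null) >= 0.9).mean()
        se = np.sqrt(frac * (1 - frac) / n_sim)
        assert abs(pearson_exact_p(0.9, 5) - frac) < 3 * se

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            pearson_exact_p(0.5, 3)


class TestPermutationTest:
    def test_perfect_order_hits_the_add_one_floor(self):
        lags = np.arange(12, dtype=float) * 25
        K = 20_000
        p = permutation_test_layer_index(lags, np.arange(1, 13), K=K, seed=0)
        assert p == pytest.approx(1 / (K + 1))

    def test_exhaustive_four_layers_matches_enumeration(self):
        """Brute-force oracle over all 24 permutations."""
        from itertools import permutations

        lags = np.array([10.0, 40.0, 20.0, 30.0])
        layers = np.arange(1, 5, dtype=float)
        r_obs = np.corrcoef(layers, lags)[0, 1]
        count = sum(
            abs(np.corrcoef(np.asarray(perm, dtype=float), lags)[0, 1]) >= abs(r_obs) - 1e-12
            for perm in permutations(layers)
        )
        expected = count / 24
        p = permutation_test_layer_index(lags, layers, exhaustive=True)
        assert p == pytest.approx(expected)

    def test_sampled_converges_to_exhaustive(self):
        lags = np.array([10.0, 40.0, 20.0, 30.0])
        layers = np.arange(1, 5, dtype=float)
        exact = permutation_test_layer_index(lags, layers, exhaustive=True)
        sampled = permutation_test_layer_index(lags, layers, K=50_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 50_000)
        assert abs(sampled - exact) < 4 * se + 1e-4

    def test_reproducible_under_seed(self):
        lags = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0])
        a = permutation_test_layer_index(lags, np.arange(6), K=1000, seed=9)
        b = permutation_test_layer_index(lags, np.arange(6), K=1000, seed=9)
        assert a == b

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_p_always_in_add_one_range(self, seed):
        g = np.random.default_rng(seed)
        lags = g.normal(size=8)
        p = permutation_test_layer_index(lags, np.arange(8), K=200, seed=seed)
        assert 1 / 201 <= p <= 1.0


class TestBootstrap:
    def test_constant_values_resample_to_constant(self):
        out = bootstrap_electrode_means(np.full(10, 0.3), B=500, seed=0)
        np.testing.assert_allclose(out["boot_means"], 0.3)

    def test_bootstrap_consistency(self, rng):
        vals = rng.normal(0.5, 0.2, size=40)
        out = bootstrap_electrode_means(vals, B=5000, seed=1)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(out["boot_means"].mean() - out["observed_mean"]) < 3 * se

    def test_seed_reproducibility(self, rng):
        vals = rng.normal(size=12)
        a = bootstrap_electrode_means(vals, B=1000, seed=5)
        b = bootstrap_electrode_means(vals, B=1000, seed=5)
        assert a["p_two_tailed"] == b["p_two_tailed"]

    def test_small_b_warns(self):
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_electrode_means(np.arange(5.0), B=50, seed=0)


class TestOrthogonalize:
    def test_layer_projected_from_itself_is_zero(self, rng):
        X = rng.standard_normal((20, 6))
        out = orthogonalize_layer(X, X)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_already_orthogonal_rows_unchanged(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        M = np.array([[0.0, 3.0], [4.0, 0.0]])
        np.testing.assert_allclose(orthogonalize_layer(X, M), X, atol=1e-12)

    @given(arrays(np.float64, (7, 5), elements=st.floats(-10, 10)))
    @settings(max_examples=30, deadline=None)
    def test_per_word_inner_product_zero(self, X):
        g = np.random.default_rng(0)
        M = g.standard_normal(X.shape) + 0.1
        out = orthogonalize_layer(X, M)
        dots = np.einsum("wd,wd->w", out, M)
        scale = np.maximum(1.0, np.abs(X).max() * np.abs(M).max())
        assert np.all(np.abs(dots) < 1e-10 * scale * X.shape[1] + 1e-10)

    def test_zero_norm_reference_passes_through_with_warning(self):
        X = np.ones((2, 3))
        M = np.vstack([np.zeros(3), np.ones(3)])
        with pytest.warns(UserWarning, match="zero-norm"):
            out = orthogonalize_layer(X, M)
        np.testing.assert_array_equal(out[0], X[0])
        np.testing.assert_allclose(out[1], 0.0, atol=1e-12)


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal(512)
        y = phase_randomize(x, seed=4)
        np.testing.assert_allclose(np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)),
                                   atol=1e-8)

    def test_autocorrelation_preserved(self, rng):
        """Wiener-Khinchin: equal amplitude spectra imply equal (circular)
        autocorrelations."""
        x = np.convolve(rng.standard_normal(1024), np.ones(20) / 20, mode="same")
        y = phase_randomize(x, seed=8)

        def circ_acf(v):
            f = np.fft.rfft(v)
            return np.fft.irfft(f * np.conj(f), n=v.size)

        np.testing.assert_allclose(circ_acf(y), circ_acf(x), atol=1e-6)

    def test_constant_signal_unchanged(self):
        x = np.full(64, 2.5)
        np.testing.assert_allclose(phase_randomize(x, seed=1), x, atol=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            phase_randomize(np.zeros(4), seed=0)


class TestBhFdr:
    def test_single_small_p_rejected(self):
        q_values, reject = bh_fdr(np.array([0.005]), q=0.01)
        assert reject[0] and q_values[0] == pytest.approx(0.005)

    def test_all_ones_none_rejected(self):
        _, reject = bh_fdr(np.ones(7), q=0.05)
        assert not reject.any()

    def test_matches_textbook_step_up_enumeration(self):
        """Brute-force oracle: classic step-up on 10 hand-picked p values."""
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216])
        q = 0.05
        n = p.size
        order = np.argsort(p)
        thresh = q * (np.arange(1, n + 1)) / n
        passing = np.flatnonzero(p[order] <= thresh)
        expected = np.zeros(n, dtype=bool)
        if passing.size:
            expected[order[: passing.max() + 1]] = True
        _, reject = bh_fdr(p, q=q)
        np.testing.assert_array_equal(reject, expected)

    def test_empty_input(self):
        q_values, reject = bh_fdr(np.array([]))
        assert q_values.size == 0 and reject.size == 0


class TestLevene:
    def test_equal_spread_after_shift_gives_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f, p = levene_peak_lag_spread(a, a + 100.0)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tenfold_spread_detected(self):
        g = np.random.default_rng(2)
        a = g.normal(0, 10, 48)
        b = g.normal(0, 1, 48)
        _, p = levene_peak_lag_spread(a, b)
        assert p < 0.01

    def test_matches_manual_formula_on_toy(self):
        """Brute-force oracle on a 6-point toy (mean-centered variant)."""
        a = np.array([1.0, 4.0, 6.0])
        b = np.array([2.0, 2.5, 3.0])
        za = np.abs(a - a.mean())
        zb = np.abs(b - b.mean())
        n, k = 6, 2
        zbar = np.concatenate([za, zb]).mean()
        num = (n - k) * (3 * (za.mean() - zbar) ** 2 + 3 * (zb.mean() - zbar) ** 2)
        den = (k - 1) * (((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum())
        f_manual = num / den
        p_manual = sps.f.sf(f_manual, k - 1, n - k)
        f, p = levene_peak_lag_spread(a, b)
        assert f == pytest.approx(f_manual, rel=1e-9)
        assert p == pytest.approx(p_manual, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            levene_peak_lag_spread(np.ones(5), np.full(5, 3.0))


class TestPairedTTest:
    def test_identical_conditions_give_t_zero_p_one(self, rng):
        A = rng.normal(size=(4, 10))
        out = paired_ttest_layers(A, A.copy())
        np.testing.assert_allclose(out["t"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)
        assert not out["reject"].any()

    def test_constant_shift_zero_noise_flagged_degenerate(self, rng):
        A = rng.normal(size=(2, 8))
        with pytest.warns(UserWarning, match="zero variance"):
            out = paired_ttest_layers(A, A + 5.0)
        assert out["degenerate"].all()
        assert not out["reject"].any()

    def test_power_at_one_sd_shift(self):
        """Simulated shift of 1 SD with 40 electrodes is detected in > 80%
        of layer tests across seeds."""
        rejections = 0
        total = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            A = g.normal(0, 1, size=(6, 40))
            B = A + 1.0 + g.normal(0, 1, size=(6, 40))
            out = paired_ttest_layers(A, B, q=0.01)
            rejections += out["reject"].sum()
            total += 6
        assert rejections / total > 0.8

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValidationError):
            paired_ttest_layers(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)))


class TestSelectElectrodes:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SyntheticConfig(n_words=80, n_layers=2, embed_dim=12, n_electrodes=1,
                              sampling_rate=256.0, snr=6.0, lag_map=[0.0, 0.0],
                              word_spacing=400.0, seed=21)
        ds = generate_neural_dataset(cfg)
        g = np.random.default_rng(99)
        noise = g.standard_normal((2, ds.recording.n_samples)) * ds.recording.signal.std()
        rec = NeuralRecording(
            signal=np.vstack([ds.recording.signal, noise]),
            sampling_rate=ds.recording.sampling_rate,
        )
        static = ds.embeddings.values[:, 0, :]
        ec = EncodingConfig(lag_min=-100, lag_max=100, lag_step=50, window=100,
                            pca_k=8)
        events = ds.events.assign_folds(10)
        return rec, events, static, ec

    def test_planted_electrode_selected_noise_not(self, planted):
        rec, events, static, ec = planted
        res = select_electrodes(rec, events, static, config=ec, n_perm=500,
                                q_threshold=0.01, seed=5)
        assert res.selected[0]
        assert not res.selected[1:].any()
        assert res.null_max.size == 500

    def test_duplicated_electrodes_get_identical_p(self, planted):
        rec, events, static, ec = planted
        dup = NeuralRecording(signal=np.vstack([rec.signal[:1], rec.signal[:1]]),
                              sampling_rate=rec.sampling_rate)
        res = select_electrodes(dup, events, static, config=ec, n_perm=120, seed=6)
        assert res.p_values[0] == res.p_values[1]
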