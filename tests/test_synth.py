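"""Synthetic-data generators: spectra, readouts, category clouds, determinism."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repgeom import (
    analytic_participation_ratio,
    compute_eigenspectrum,
    effective_dimensionality,
    evaluate_prototypes,
    fit_prototypes,
    gen_category_clouds,
    gen_feature_maps,
    gen_neural_responses,
    gen_power_law_features,
    global_average_pool,
    power_law_spectrum,
    split_half_reliability,
)
from repgeom._rng import derive_seed, sample_uniform_ball


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        a = gen_power_law_features(50, 10, 1.0, seed=3)
        b = gen_power_law_features(50, 10, 1.0, seed=3)
        assert np.array_equal(a.values, b.values)
        ra = gen_neural_responses(a, 5, 3, 1.0, 2, seed=4)
        rb = gen_neural_responses(b, 5, 3, 1.0, 2, seed=4)
        assert np.array_equal(ra.values, rb.values)
        ca = gen_category_clouds(3, 4, 2, 6, 1.0, 1.0, seed=5)
        cb = gen_category_clouds(3, 4, 2, 6, 1.0, 1.0, seed=5)
        assert np.array_equal(ca.features.values, cb.features.values)

    @given(seed=st.integers(0, 2**31 - 1), name=st.text(max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_derived_seeds_valid_and_stable(self, seed, name):
        s = derive_seed(seed, name)
        assert 0 <= s < 2**31
        assert s == derive_seed(seed, name)


class TestPowerLawFeatures:
    def test_isotropic_spectrum_gives_full_ed(self):
        fm = gen_power_law_features(4000, 10, alpha=0.0, seed=1)
        ed = effective_dimensionality(compute_eigenspectrum(fm))
        assert ed == pytest.approx(10.0, rel=0.05)

    def test_steep_spectrum_collapses_to_one(self):
        fm = gen_power_law_features(4000, 10, alpha=8.0, seed=1)
        ed = effective_dimensionality(compute_eigenspectrum(fm))
        assert ed == pytest.approx(1.0, abs=0.05)

    def test_ed_matches_truncated_harmonic_sums(self):
        # analytic participation ratio of lambda_i = 1/i, i = 1..100
        i = np.arange(1, 101)
        expected = (np.sum(1.0 / i)) ** 2 / np.sum(1.0 / i**2)
        fm = gen_power_law_features(5000, 100, alpha=1.0, seed=2)
        ed = effective_dimensionality(compute_eigenspectrum(fm))
        assert ed == pytest.approx(expected, rel=0.10)
        assert analytic_participation_ratio(power_law_spectrum(100, 1.0)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_top_eigenvalues_converge_to_target(self):
        n_channels = 20
        fm = gen_power_law_features(50 * n_channels, n_channels, alpha=1.0, seed=9)
        est = compute_eigenspectrum(fm).lambdas[:10]
        target = power_law_spectrum(n_channels, 1.0)[:10]
        assert np.all(np.abs(est - target) / target < 0.10)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            gen_power_law_features(0, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            gen_power_law_features(10, 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            gen_power_law_features(10, 5, -1.0, seed=0)


class TestNeuralResponses:
    def test_infinite_snr_gives_identical_repeats(self):
        fm = gen_power_law_features(100, 10, 0.5, seed=1)
        rec = gen_neural_responses(fm, 8, 5, np.inf, 3, seed=2)
        assert np.array_equal(rec.values[:, :, 0], rec.values[:, :, 1])
        rel = split_half_reliability(rec, corrected=False, seed=0)
        assert rel.per_unit_ceiling == pytest.approx(np.ones(8), abs=1e-12)

    def test_single_repeat_rejected_by_reliability(self):
        fm = gen_power_law_features(50, 10, 0.5, seed=1)
        rec = gen_neural_responses(fm, 4, 3, 1.0, 1, seed=2)
        from repgeom import ReliabilityUnavailableError

        with pytest.raises(ReliabilityUnavailableError):
            split_half_reliability(rec)

    def test_unit_snr_reliability_law(self):
        # corr of two noisy copies of the same signal = snr / (snr + 1)
        fm = gen_power_law_features(2000, 50, 0.5, seed=3)
        rec = gen_neural_responses(fm, 40, 20, snr=1.0, n_repeats=2, seed=4)
        rel = split_half_reliability(rec, corrected=False, seed=5)
        assert np.mean(rel.per_unit_ceiling) == pytest.approx(0.5, abs=0.05)

    def test_heldout_r2_approaches_snr_fraction(self):
        # full-rank linear regression on the features recovers the signal;
        # held-out R^2 is bounded by the per-repeat noise fraction snr/(snr+1)
        snr = 1.0
        fm = gen_power_law_features(3000, 20, 0.0, seed=6)
        rec = gen_neural_responses(fm, 10, 20, snr, 1, seed=7)
        x, y = fm.values, rec.values[:, :, 0]
        tr, te = slice(0, 2000), slice(2000, 3000)
        beta, *_ = np.linalg.lstsq(
            np.c_[x[tr], np.ones(2000)], y[tr], rcond=None
        )
        pred = np.c_[x[te], np.ones(1000)] @ beta
        sse = np.square(y[te] - pred).sum(0)
        sst = np.square(y[te] - y[te].mean(0)).sum(0)
        r2 = 1 - sse / sst
        assert np.mean(r2) == pytest.approx(snr / (snr + 1.0), abs=0.05)

    def test_signal_dims_exceeding_channels_rejected(self):
        fm = gen_power_law_features(50, 10, 0.5, seed=1)
        with pytest.raises(ValueError):
            gen_neural_responses(fm, 4, 11, 1.0, 2, seed=2)


class TestCategoryClouds:
    def test_zero_radius_collapses_to_centroids(self):
        data = gen_category_clouds(4, 10, 3, 8, radius=0.0, separation=2.0, seed=1)
        for c in data.class_ids:
            m = data.class_matrix(c)
            assert np.allclose(m, m[0])
        model = fit_prototypes(data)
        res = evaluate_prototypes(model, data)
        assert res.accuracy == 1.0 and res.mrr == 1.0

    def test_zero_separation_is_chance_level(self):
        M = 5
        data = gen_category_clouds(M, 40, 4, 10, radius=1.0, separation=0.0, seed=2)
        model = fit_prototypes(data)
        res = evaluate_prototypes(model, data)
        # indistinguishable classes: accuracy near 1/M (binomial 3-sigma)
        n = M * 40
        assert abs(res.accuracy - 1 / M) < 3 * np.sqrt((1 / M) * (1 - 1 / M) / n) + 0.05

    def test_expected_centroid_separation(self):
        sep = 3.0
        data = gen_category_clouds(40, 2, 16, 32, radius=0.0, separation=sep, seed=3)
        cents = np.stack([data.class_matrix(c)[0] for c in data.class_ids])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        mean_pairwise = d[np.triu_indices(40, 1)].mean()
        assert mean_pairwise == pytest.approx(sep, rel=0.10)

    def test_samples_live_in_shared_latent_subspace(self):
        data = gen_category_clouds(6, 20, latent_dim=3, ambient_dim=12,
                                   radius=1.0, separation=1.0, seed=4)
        x = data.features.values
        rank = np.linalg.matrix_rank(x - x.mean(0), tol=1e-8)
        assert rank <= 3

    def test_ball_samples_within_radius(self):
        rng = np.random.default_rng(0)
        pts = sample_uniform_ball(rng, 500, 5, radius=2.5)
        assert np.all(np.linalg.norm(pts, axis=1) <= 2.5 + 1e-12)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            gen_category_clouds(1, 10, 2, 4, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            gen_category_clouds(3, 10, 5, 4, 1.0, 1.0, seed=0)


class TestFeatureMaps:
    def test_unit_extent_pooling_identity(self):
        maps = gen_feature_maps(5, 3, 1, 1, seed=1)
        pooled = global_average_pool(maps)
        assert pooled.values == pytest.approx(maps.values[:, :, 0, 0])

    def test_constant_map_pools_to_constant(self):
        maps = gen_feature_maps(3, 2, 4, 4, seed=1)
        maps.values[:] = 7.25
        assert global_average_pool(maps).values == pytest.approx(
            np.full((3, 2), 7.25)
        )
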