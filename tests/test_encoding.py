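"""Cross-validated encoding pipeline, noise ceiling, normalization, RSA."""
import numpy as np
import pytest
from scipy import stats

from repgeom import (
    EncodingResult,
    FeatureMatrix,
    NeuralRecordingSet,
    ReliabilitySet,
    fit_cv_encoder,
    gen_neural_responses,
    gen_power_law_features,
    normalized_encoding_score,
    pca_reduce,
    rsa_score,
    split_half_reliability,
)


def _linear_recordings(features: FeatureMatrix, n_units: int, seed: int) -> NeuralRecordingSet:
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((features.n_channels, n_units))
    return NeuralRecordingSet(
        (features.values @ w)[:, :, None], stimulus_ids=list(features.stimulus_ids)
    )


class TestPcaReduce:
    def test_full_rank_projection_preserves_distances(self, small_features):
        reduced = pca_reduce(small_features, small_features, n_components=8)
        from scipy.spatial.distance import pdist

        assert pdist(reduced.values) == pytest.approx(pdist(small_features.values), rel=1e-9)

    def test_component_cap(self, small_features):
        assert pca_reduce(small_features, small_features, 1).n_channels == 1
        # requesting more components than the reference supports uses the rank
        assert pca_reduce(small_features, small_features, 1000).n_channels <= 8

    def test_channel_mismatch_rejected(self, small_features, rng):
        other = FeatureMatrix(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError, match="channel mismatch"):
            pca_reduce(small_features, other)

    def test_encoding_score_invariant_under_full_rank_reduction(self):
        fm = gen_power_law_features(120, 10, 0.5, seed=1)
        rec = _linear_recordings(fm, 6, seed=2)
        raw = fit_cv_encoder(fm, rec, variant="ols_fmri", n_folds=5, seed=3)
        red = fit_cv_encoder(
            pca_reduce(fm, fm, 10), rec, variant="ols_fmri", n_folds=5, seed=3
        )
        assert red.median_r == pytest.approx(raw.median_r, abs=1e-9)


class TestCvEncoder:
    def test_exact_linear_mapping_recovered(self):
        fm = gen_power_law_features(200, 12, 0.5, seed=4)
        rec = _linear_recordings(fm, 8, seed=5)
        res = fit_cv_encoder(fm, rec, variant="pls_monkey", n_components=12, seed=6)
        assert np.all(res.per_unit_r > 0.999)
        assert res.n_folds == 10

    def test_pure_noise_has_null_level_correlations(self):
        fm = gen_power_law_features(400, 10, 0.5, seed=7)
        rng = np.random.default_rng(8)
        rec = NeuralRecordingSet(
            rng.standard_normal((400, 20, 1)), stimulus_ids=list(fm.stimulus_ids)
        )
        res = fit_cv_encoder(fm, rec, seed=9)
        assert abs(res.median_r) < 3.0 / np.sqrt(400)

    def test_fold_mean_vs_concatenate_agree_on_clean_data(self):
        fm = gen_power_law_features(150, 8, 0.5, seed=10)
        rec = _linear_recordings(fm, 5, seed=11)
        a = fit_cv_encoder(fm, rec, n_components=8, seed=12, aggregate="fold_mean")
        b = fit_cv_encoder(fm, rec, n_components=8, seed=12, aggregate="concatenate")
        assert a.median_r == pytest.approx(b.median_r, abs=1e-3)

    def test_unit_reordering_invariance(self):
        fm = gen_power_law_features(100, 6, 0.5, seed=13)
        rec = gen_neural_responses(fm, 9, 4, 2.0, 2, seed=14)
        res = fit_cv_encoder(fm, rec, seed=15)
        perm = np.random.default_rng(0).permutation(9)
        rec_perm = NeuralRecordingSet(
            rec.values[:, perm], stimulus_ids=rec.stimulus_ids
        )
        res_perm = fit_cv_encoder(fm, rec_perm, seed=15)
        assert np.sort(res_perm.per_unit_r) == pytest.approx(np.sort(res.per_unit_r))
        assert res_perm.median_r == pytest.approx(res.median_r)

    def test_orthogonal_feature_rotation_invariance_at_full_rank(self):
        fm = gen_power_law_features(100, 6, 0.5, seed=16)
        rec = _linear_recordings(fm, 4, seed=17)
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((6, 6)))
        fm_rot = FeatureMatrix(fm.values @ q, stimulus_ids=list(fm.stimulus_ids))
        a = fit_cv_encoder(fm, rec, variant="ols_fmri", seed=18)
        b = fit_cv_encoder(fm_rot, rec, variant="ols_fmri", seed=18)
        assert b.per_unit_r == pytest.approx(a.per_unit_r, abs=1e-8)

    def test_misaligned_stimuli_rejected(self):
        fm = gen_power_law_features(50, 6, 0.5, seed=19)
        rec = NeuralRecordingSet(np.random.default_rng(0).standard_normal((50, 3, 1)))
        rec.stimulus_ids = list(reversed(rec.stimulus_ids))
        with pytest.raises(ValueError, match="aligned"):
            fit_cv_encoder(fm, rec)

    def test_ols_variant_defaults(self):
        fm = gen_power_law_features(90, 6, 0.5, seed=20)
        rec = _linear_recordings(fm, 4, seed=21)
        res = fit_cv_encoder(fm, rec, variant="ols_fmri", seed=22)
        assert res.n_folds == 9 and res.n_pls_components is None
        assert np.all(res.per_unit_r > 0.999)


class TestSplitHalfReliability:
    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(23)
        rec = NeuralRecordingSet(rng.standard_normal((500, 10, 4)))
        rel = split_half_reliability(rec, corrected=False, seed=24)
        assert abs(np.mean(rel.per_unit_ceiling)) < 0.05

    def test_unit_snr_gives_half_reliability(self):
        fm = gen_power_law_features(2000, 30, 0.5, seed=25)
        rec = gen_neural_responses(fm, 30, 15, snr=1.0, n_repeats=2, seed=26)
        rel = split_half_reliability(rec, corrected=False, seed=27)
        assert np.mean(rel.per_unit_ceiling) == pytest.approx(0.5, abs=0.05)

    def test_spearman_brown_correction(self):
        fm = gen_power_law_features(1000, 20, 0.5, seed=28)
        rec = gen_neural_responses(fm, 10, 8, snr=1.0, n_repeats=2, seed=29)
        raw = split_half_reliability(rec, corrected=False, seed=30)
        cor = split_half_reliability(rec, corrected=True, seed=30)
        expected = 2 * raw.per_unit_ceiling / (1 + raw.per_unit_ceiling)
        assert cor.per_unit_ceiling == pytest.approx(expected, abs=1e-12)


class TestNormalizedScore:
    @pytest.mark.parametrize(
        "median_r, ceiling, expected",
        [(0.6, 0.6, 1.0), (0.0, 0.5, 0.0), (0.3, 0.6, 0.25)],
    )
    def test_squared_quotient(self, median_r, ceiling, expected):
        res = EncodingResult(
            per_unit_r=np.array([median_r]), median_r=median_r, n_folds=10,
            n_pls_components=25, variant="pls_monkey", aggregate="fold_mean",
        )
        rel = ReliabilitySet(
            per_unit_ceiling=np.array([ceiling]), n_splits=10, corrected=False
        )
        assert normalized_encoding_score(res, rel) == pytest.approx(expected)

    def test_nonpositive_ceiling_rejected(self):
        res = EncodingResult(
            per_unit_r=np.array([0.5]), median_r=0.5, n_folds=10,
            n_pls_components=25, variant="pls_monkey", aggregate="fold_mean",
        )
        rel = ReliabilitySet(
            per_unit_ceiling=np.array([-0.1]), n_splits=10, corrected=False
        )
        with pytest.raises(ValueError):
            normalized_encoding_score(res, rel)

    def test_monotone_in_median_r(self):
        rel = ReliabilitySet(np.array([0.7]), n_splits=10, corrected=False)
        scores = [
            normalized_encoding_score(
                EncodingResult(np.array([r]), r, 10, 25, "pls_monkey", "fold_mean"),
                rel,
            )
            for r in np.linspace(0.0, 0.7, 8)
        ]
        assert np.all(np.diff(scores) > 0)


class TestRsa:
    def test_self_similarity_is_one(self, small_features):
        rec = NeuralRecordingSet(
            small_features.values[:, :, None],
            stimulus_ids=list(small_features.stimulus_ids),
        )
        assert rsa_score(small_features, rec) == pytest.approx(1.0)

    def test_channel_permutation_invariance(self, small_features, rng):
        perm = rng.permutation(small_features.n_channels)
        rec = NeuralRecordingSet(
            small_features.values[:, perm][:, :, None],
            stimulus_ids=list(small_features.stimulus_ids),
        )
        assert rsa_score(small_features, rec) == pytest.approx(1.0)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        x = rng.standard_normal((5, 7))
        y = rng.standard_normal((5, 4))
        fm = FeatureMatrix(x)
        rec = NeuralRecordingSet(y[:, :, None], stimulus_ids=list(fm.stimulus_ids))
        # brute-force: per-pair Pearson dissimilarities, then Spearman
        def rdm_upper(a):
            vals = []
            for i in range(5):
                for j in range(i + 1, 5):
                    vals.append(1 - stats.pearsonr(a[i], a[j]).statistic)
            return np.array(vals)

        expected, _ = stats.spearmanr(rdm_upper(x), rdm_upper(y))
        assert rsa_score(fm, rec) == pytest.approx(float(expected), abs=1e-12)

    def test_constant_row_rejected(self, rng):
        x = rng.standard_normal((4, 5))
        x[2] = 1.0
        fm = FeatureMatrix(x)
        rec = NeuralRecordingSet(
            rng.standard_normal((4, 3, 1)), stimulus_ids=list(fm.stimulus_ids)
        )
        with pytest.raises(ValueError, match="constant"):
            rsa_score(fm, rec)
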