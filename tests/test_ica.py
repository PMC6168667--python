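"""Infomax decomposition and the five-criterion component classifier."""

import numpy as np
import pandas as pd
import pytest

from ppigate import (ClassifierConfig, ComponentScores, classify_components,
                     fit_ica, remove_components, score_autocorrelation,
                     score_components, score_focal_topography,
                     score_focal_trial, score_reference_correlation, score_snr)
from ppigate.erp import EpochSet
from ppigate.ica import ICADecomposition

from oracles import amari_index, max_zscore_oracle

RATE = 512.0
NS = 1024  # samples per (-1000, 1000) ms epoch at 512 Hz


def make_epochs(data):
    data = np.asarray(data, dtype=float)
    return EpochSet(data, np.array(["P"] * data.shape[0], dtype=object),
                    [f"ch{i}" for i in range(data.shape[1])], RATE)


def make_dec(epoch_acts, mixing=None):
    """Decomposition with prescribed component activations (comps × epochs
    × samples) and mixing (identity unless given)."""
    acts = np.asarray(epoch_acts, dtype=float)
    c, e, ns = acts.shape
    mixing = np.eye(c) if mixing is None else np.asarray(mixing, dtype=float)
    unmixing = np.linalg.inv(mixing)
    return ICADecomposition(unmixing, mixing, acts.reshape(c, -1),
                            [f"ch{i}" for i in range(c)], e, ns, RATE,
                            (-1000.0, 1000.0), (-650.0, -150.0), 0, 0)


class TestFitICA:
    def test_separates_known_two_channel_mixture(self):
        rng = np.random.default_rng(3)
        n = 10_000
        S = np.vstack([rng.laplace(size=n), rng.normal(size=n)])
        A = np.array([[1.0, 0.6], [-0.4, 1.2]])
        dec = fit_ica(make_epochs((A @ S)[None]), seed=0)
        assert amari_index(dec.unmixing @ A) < 0.05

    def test_whitened_sources_give_scaled_permutation(self):
        rng = np.random.default_rng(4)
        n = 10_000
        S = np.vstack([rng.laplace(size=n), rng.laplace(size=n)])
        dec = fit_ica(make_epochs(S[None]), seed=0)
        assert amari_index(dec.unmixing @ np.eye(2)) < 0.05

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        X = rng.laplace(size=(1, 4, NS)) + rng.normal(size=(1, 4, NS))
        X = np.cumsum(X, axis=-1) * 0.1 + rng.laplace(size=(1, 4, NS))
        a = fit_ica(make_epochs(X), seed=11)
        b = fit_ica(make_epochs(X), seed=11)
        assert a.unmixing.tobytes() == b.unmixing.tobytes()
        assert a.activations.tobytes() == b.activations.tobytes()

    def test_reconstruction_completeness_and_activation_identity(self):
        rng = np.random.default_rng(6)
        X = rng.laplace(size=(3, 5, NS))
        ep = make_epochs(X.transpose(1, 0, 2))
        dec = fit_ica(ep, seed=0)
        concat = ep.data.transpose(1, 0, 2).reshape(3, -1)
        np.testing.assert_allclose(dec.unmixing @ concat, dec.activations)
        np.testing.assert_allclose(dec.mixing @ dec.activations, concat,
                                   rtol=1e-6, atol=1e-6 * np.abs(concat).max())
        np.testing.assert_allclose(dec.unmixing @ dec.mixing, np.eye(3), atol=1e-6)

    def test_rank_deficient_data_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 1, NS))
        X = np.concatenate([x, 2 * x, x + 2 * x], axis=1)
        with pytest.raises(ValueError, match="rank"):
            fit_ica(make_epochs(X), seed=0)


class TestAutocorrelation:
    def test_sine_matches_cosine_closed_form(self):
        t = np.arange(NS) / RATE
        act = np.tile(np.sin(2 * np.pi * 5.0 * t), (10, 1))
        dec = make_dec(act[None])
        r = score_autocorrelation(dec, lag_ms=20.0)
        lag_s = np.round(0.020 * RATE) / RATE  # 20 ms rounds to 10 samples
        assert r[0] == pytest.approx(np.cos(2 * np.pi * 5.0 * lag_s), abs=0.01)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(8)
        dec = make_dec(rng.normal(size=(1, 10, NS)))
        assert abs(score_autocorrelation(dec)[0]) < 0.1

    def test_constant_activation_is_one_by_convention(self):
        dec = make_dec(np.full((1, 5, NS), 2.5))
        assert score_autocorrelation(dec)[0] == 1.0

    def test_sub_sample_lag_rejected(self):
        dec = make_dec(np.zeros((1, 5, NS)))
        with pytest.raises(ValueError, match="lag"):
            score_autocorrelation(dec, lag_ms=0.5)


class TestFocalTopography:
    def test_uniform_topography_scores_zero(self):
        mixing = np.eye(5)
        mixing[:, 0] = 1.0  # component 0 projects equally to every channel
        dec = make_dec(np.random.default_rng(9).normal(size=(5, 5, NS)), mixing)
        assert score_focal_topography(dec)[0] == pytest.approx(0.0)

    def test_single_dominant_channel_flagged(self):
        rng = np.random.default_rng(10)
        n_ch = 20
        weights = np.zeros(n_ch)
        weights[3] = 10.0
        mixing = rng.normal(0, 0.1, (n_ch, n_ch)) + np.eye(n_ch)
        mixing[:, 0] = weights
        dec = make_dec(rng.normal(size=(n_ch, 5, 64)), mixing)
        z = score_focal_topography(dec)
        assert z[0] == pytest.approx(max_zscore_oracle(weights))
        assert z[0] > 3.5

    def test_two_large_weights_match_oracle(self):
        rng = np.random.default_rng(11)
        n_ch = 20
        weights = np.zeros(n_ch)
        weights[[2, 9]] = 8.0
        mixing = rng.normal(0, 0.1, (n_ch, n_ch)) + np.eye(n_ch)
        mixing[:, 0] = weights
        dec = make_dec(rng.normal(size=(n_ch, 5, 64)), mixing)
        assert score_focal_topography(dec)[0] == pytest.approx(max_zscore_oracle(weights))


class TestFocalTrial:
    def test_identical_epochs_score_zero(self):
        act = np.tile(np.random.default_rng(12).normal(size=NS), (40, 1))
        dec = make_dec(act[None])
        assert score_focal_trial(dec)[0] == pytest.approx(0.0)

    def test_one_huge_epoch_flagged(self):
        # the z threshold of 10 needs sqrt(n_epochs - 1) > 10, i.e. the
        # design's ~170 trials; at 40 epochs max z is only ~6.2
        rng = np.random.default_rng(13)
        act = rng.normal(size=(170, NS))
        act[17] *= 100.0
        z = score_focal_trial(make_dec(act[None]))[0]
        per_epoch = np.abs(act).max(axis=1)
        assert z == pytest.approx(max_zscore_oracle(per_epoch))
        assert z > 10.0

    def test_mild_outlier_not_flagged(self):
        rng = np.random.default_rng(14)
        act = rng.normal(size=(40, NS))
        act[5] *= 2.0
        z = score_focal_trial(make_dec(act[None]))[0]
        assert z == pytest.approx(max_zscore_oracle(np.abs(act).max(axis=1)))
        assert z < 10.0


class TestSNR:
    def test_post_only_component_is_infinite(self):
        act = np.zeros((5, NS))
        act[:, 600:700] = 3.0  # post-stimulus only (sample 512 = 0 ms)
        ratio = score_snr(make_dec(act[None]))[0]
        assert np.isinf(ratio)

    def test_stationary_component_near_one(self):
        rng = np.random.default_rng(15)
        ratio = score_snr(make_dec(rng.normal(size=(1, 40, NS))))[0]
        assert 0.8 < ratio < 1.25

    def test_pre_stimulus_only_component_below_one(self):
        act = np.zeros((5, NS))
        act[:, 100:300] = 3.0  # entirely pre-stimulus
        ratio = score_snr(make_dec(act[None]))[0]
        assert ratio < 1.0


class TestReferenceCorrelation:
    def test_component_equal_to_reference_is_one(self):
        rng = np.random.default_rng(16)
        act = rng.normal(size=(1, 10, NS))
        refs = {"EOG": act[0]}
        r = score_reference_correlation(make_dec(act), refs)
        assert r[0] == pytest.approx(1.0)

    def test_orthogonal_component_near_zero(self):
        rng = np.random.default_rng(17)
        act = rng.normal(size=(1, 10, NS))
        refs = {"EOG": rng.normal(size=(10, NS))}
        assert score_reference_correlation(make_dec(act), refs)[0] < 0.05

    def test_partial_mixture_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(18)
        eog = rng.normal(size=(10, NS))
        comp = 0.3 * eog + rng.normal(size=(10, NS)) * eog.std()
        r = score_reference_correlation(make_dec(comp[None]), {"EOG": eog})[0]
        expected = abs(np.corrcoef(comp.reshape(-1), eog.reshape(-1))[0, 1])
        assert r == pytest.approx(expected)

    def test_zero_variance_reference_skipped(self):
        rng = np.random.default_rng(19)
        act = rng.normal(size=(1, 5, NS))
        r = score_reference_correlation(make_dec(act), {"EMG1": np.zeros((5, NS))})
        assert r[0] == 0.0


class TestClassifyAndRemove:
    def _scores(self, flags_by_comp):
        n = len(flags_by_comp)
        cols = ["flag_autocorr", "flag_focal_topo", "flag_focal_trial",
                "flag_snr", "flag_ref_corr"]
        df = pd.DataFrame({"component": np.arange(n)})
        for j, col in enumerate(cols):
            df[col] = [bool(f[j]) for f in flags_by_comp]
        return ComponentScores(df, 0.0)

    def test_union_rule(self):
        scores = classify_components(self._scores([
            (0, 0, 0, 0, 0),    # kept
            (0, 0, 0, 0, 1),    # removed: reference correlation only
            (1, 0, 0, 0, 0),    # removed: autocorrelation only
        ]))
        np.testing.assert_array_equal(scores.final_artifact, [False, True, True])

    def test_vote_rule_requires_majority(self):
        scores = classify_components(self._scores([
            (1, 1, 0, 0, 0),
            (1, 1, 1, 0, 0),
        ]), combine="vote")
        np.testing.assert_array_equal(scores.final_artifact, [False, True])

    def test_classification_invariant_to_sign_and_scale(self):
        rng = np.random.default_rng(20)
        acts = rng.laplace(size=(3, 20, NS))
        mixing = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        refs = {"EOG": rng.normal(size=(20, NS))}
        dec = make_dec(acts, mixing)
        # flip and rescale component 1 consistently (same decomposition)
        acts2 = acts.copy()
        acts2[1] *= -4.0
        mixing2 = mixing.copy()
        mixing2[:, 1] /= -4.0
        dec2 = make_dec(acts2, mixing2)
        a = score_components(dec, refs).table
        b = score_components(dec2, refs).table
        for col in ("autocorr_r", "focal_topo_z", "focal_trial_z",
                    "snr_ratio", "max_ref_corr", "final_artifact"):
            np.testing.assert_allclose(
                a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float),
                rtol=1e-9, atol=1e-9)

    def test_removing_nothing_reproduces_input(self):
        rng = np.random.default_rng(21)
        X = rng.laplace(size=(4, 3, NS))
        ep = make_epochs(X)
        dec = fit_ica(ep, seed=0)
        scores = classify_components(self._scores([(0,) * 5] * 3))
        out = remove_components(ep, dec, scores)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-6 * np.abs(X).max())

    def test_removing_channel_unique_source_zeroes_channel(self):
        rng = np.random.default_rng(22)
        acts = rng.normal(size=(3, 5, NS))
        dec = make_dec(acts)  # identity mixing: component k lives on channel k
        ep = make_epochs(acts.transpose(1, 0, 2))
        scores = classify_components(self._scores([(0,) * 5, (0, 0, 0, 0, 1), (0,) * 5]))
        out = remove_components(ep, dec, scores)
        np.testing.assert_allclose(out.data[:, 1, :], 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data[:, 0, :], ep.data[:, 0, :], atol=1e-9)

    def test_removing_everything_is_an_error(self):
        rng = np.random.default_rng(23)
        acts = rng.normal(size=(2, 5, NS))
        dec = make_dec(acts)
        ep = make_epochs(acts.transpose(1, 0, 2))
        scores = classify_components(self._scores([(1, 0, 0, 0, 0)] * 2))
        with pytest.raises(ValueError, match="all components"):
            remove_components(ep, dec, scores)
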