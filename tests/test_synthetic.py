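"""Ground-truth generators: determinism, bounds, variance bookkeeping and
generative/analytic consistency."""

import numpy as np
import pytest

import faceenc as fe
from faceenc.io import validate_events
from faceenc.preproc import SubjectRecord, validate_channel_table
from faceenc.synthetic import (GroundTruth, _sparse_weights, drop_blocks,
                               per_face_frames, region_channels,
                               simulate_features, simulate_response,
                               simulate_subject_raw, standard_events)
from conftest import SEED, make_channels


class TestStimulusStructure:
    def test_standard_events_shape(self, events):
        assert len(events) == 13
        assert (events["duration"] == 30.0).all()
        assert (events["condition"].value_counts()["music"]) == 7
        validate_events(events)

    def test_features_bounded_and_shaped(self, features_full):
        assert features_full.values.shape == (13, 60, 48)
        assert features_full.values.min() >= 0.0
        assert features_full.values.max() <= 1.0

    def test_face_free_block_all_zero(self, features_full):
        b = features_full.block_meta.index[
            features_full.block_meta["block_index"] == 9][0]
        assert np.all(features_full.values[b] == 0.0)
        others = np.delete(features_full.values, b, axis=0)
        assert (others > 0).all()  # logistic squashing never reaches 0

    def test_deterministic_under_seed(self, events):
        a = simulate_features(events, seed=42)
        b = simulate_features(events, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_features(events, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_lag1_autocorrelation_high(self, features):
        v = features.values
        x, y = v[:, :-1, :], v[:, 1:, :]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).mean() / np.sqrt((xc ** 2).mean() * (yc ** 2).mean())
        assert r > 0.5


class TestPerFaceFrames:
    def test_max_over_faces_recovers_bins(self, features, events):
        times, per_face = per_face_frames(features, events, fps=10.0,
                                          n_faces=3, seed=SEED)
        scores, no_face = fe.aggregate_faces(per_face)
        assert not no_face.any()
        # frame at block-relative time t carries the value of bin floor(2t)
        onset = {r.block_index: r.onset for r in events.itertuples()}
        for fi in (0, 1234, 3599):
            meta_idx = fi // 300
            row = features.block_meta.iloc[meta_idx]
            rel = times[fi] - onset[row["block_index"]]
            b = min(int(rel * 2), 59)
            np.testing.assert_allclose(scores[fi],
                                       features.values[meta_idx, b])

    def test_faceless_probability(self, features, events):
        times, per_face = per_face_frames(features, events, fps=5.0,
                                          n_faces=2, p_no_face=0.5, seed=SEED)
        _, no_face = fe.aggregate_faces(per_face)
        assert 0.3 < no_face.mean() < 0.7


class TestSimulateResponse:
    def test_zero_weights_unit_noise(self, features, config):
        zero = np.zeros((48, 3))
        truth = GroundTruth(weights={"speech": zero, "music": zero},
                            coupling_snr=1.0, ar_coef=0.3)
        Y, meta = simulate_response(features, truth, config.lags,
                                    n_contacts=3, seed=SEED)
        assert Y.shape == (720, 3)
        assert abs(Y.var() - 1.0) < 0.15
        assert abs(Y.mean()) < 0.1

    def test_noiseless_limit_exact(self, features, config, rng):
        amps = {f: 0.3 for f in config.basic_group}
        W = _sparse_weights(rng, config.feature_names, amps, config.lags)
        truth = GroundTruth(weights={"speech": W, "music": W},
                            coupling_snr=np.inf, ar_coef=0.0)
        Y, _ = simulate_response(features, truth, config.lags, seed=SEED)
        design = fe.build_design_matrix(features, config.lags)
        np.testing.assert_allclose(Y[:, 0], design.X @ W.reshape(-1),
                                   atol=1e-12)
        fit = fe.crossval_fit(design.X, Y[:, 0], 1e-6)
        assert fit.mean_r > 0.99

    def test_snr_variance_bookkeeping(self, features, config, rng):
        """At snr 1, realized signal/noise variance ratio is within 10%."""
        amps = {f: 0.3 for f in config.feature_names[:10]}
        W = _sparse_weights(rng, config.feature_names, amps, config.lags)
        truth = GroundTruth(weights={"speech": W, "music": W},
                            coupling_snr=1.0, ar_coef=0.3)
        design = fe.build_design_matrix(features, config.lags)
        s = design.X @ W.reshape(-1)
        rep = []
        for seed in range(10):
            Y, _ = simulate_response(features, truth, config.lags, seed=seed)
            rep.append((Y[:, 0] - s).var())
        v_noise = np.mean(rep)
        v_sig_per_cond = [
            s[(design.row_meta["condition"] == c).to_numpy()].var()
            for c in ("speech", "music")]
        assert abs(np.mean(v_sig_per_cond) / v_noise - 1.0) < 0.1

    def test_dimension_mismatch_rejected(self, features, config):
        truth = GroundTruth(weights={"speech": np.zeros((48, 2)),
                                     "music": np.zeros((48, 2))},
                            coupling_snr=1.0, ar_coef=0.3)
        with pytest.raises(ValueError, match="48"):
            simulate_response(features, truth, config.lags, seed=0)


class TestSimulateRaw:
    def _flat_envelope_recording(self, level=2.0, seed=SEED):
        channels = make_channels(["a", "b"], "pSTC")
        env = np.full((2, 50), level)
        t = np.linspace(0, 10, 50)
        return fe.simulate_raw(env, t, 1024.0, 10.0, channels, seed=seed,
                               line_rel=0.0, background_rel=0.05)

    def test_constant_envelope_low_cv(self):
        rec = self._flat_envelope_recording()
        amp = fe.extract_hfb(rec, (110.0, 140.0), 4)
        win = np.ones(256) / 256
        smooth = np.convolve(amp.data[:, 0], win, mode="valid")[512:-512]
        assert smooth.std() / smooth.mean() < 0.2

    def test_zero_envelope_background_only(self):
        channels = make_channels(["a"], "pSTC")
        t = np.linspace(0, 10, 50)
        loud = fe.simulate_raw(np.full((1, 50), 5.0), t, 1024.0, 10.0,
                               channels, seed=SEED)
        silent = fe.simulate_raw(np.zeros((1, 50)), t, 1024.0, 10.0,
                                 channels, seed=SEED)
        amp_loud = fe.extract_hfb(loud, (110.0, 140.0), 4).data.mean()
        amp_silent = fe.extract_hfb(silent, (110.0, 140.0), 4).data.mean()
        assert amp_silent < 0.05 * amp_loud

    def test_too_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            fe.simulate_raw(np.ones((1, 10)), np.linspace(0, 1, 10), 200.0,
                            1.0, make_channels(["a"]), seed=0)

    def test_sinusoid_envelope_end_to_end(self, config):
        """Full preprocessing recovers a slow sinusoidal modulation with
        pooled correlation > 0.8 (the end-to-end closed loop)."""
        events = standard_events(n_blocks=3, gap=2.0)
        t_env = np.arange(0.25, 100.0, 0.5)
        g = 1.0 + 0.45 * np.sin(2 * np.pi * 0.2 * t_env)
        env = (g ** 2)[None, :].repeat(2, axis=0)
        channels = make_channels(["a", "b"], "pSTC")
        rec = fe.simulate_raw(env, t_env, 2048.0, 100.0, channels, seed=SEED)
        epochs = fe.preprocess(rec, events,
                               fe.PipelineConfig(excluded_blocks=()))
        resp = fe.bin_response(epochs, 0.5, n_bins=60)
        onsets = events["onset"].to_numpy()
        target = np.stack([
            1.0 + 0.45 * np.sin(2 * np.pi * 0.2 * (on + np.arange(0.25, 30, 0.5)))
            for on in onsets])
        # normalized HFB vs the z-scored envelope, per block (the baseline
        # z-score leaves arbitrary per-block offsets)
        resp_blocks = resp.Y[:, 0].reshape(3, 60)
        z = lambda x: (x - x.mean(axis=1, keepdims=True)) / x.std(
            axis=1, keepdims=True)
        r = np.corrcoef(z(resp_blocks).ravel(), z(target).ravel())[0, 1]
        assert r > 0.8


class TestCohorts:
    def test_cohort_deterministic_and_valid(self, config):
        a = fe.simulate_cohort(n_subjects=4, seed=SEED)
        b = fe.simulate_cohort(n_subjects=4, seed=SEED)
        assert [s.id for s in a.subjects] == [s.id for s in b.subjects]
        np.testing.assert_array_equal(a.features.values, b.features.values)
        for ba, bb in zip(a.bundles, b.bundles):
            np.testing.assert_array_equal(ba.response.Y, bb.response.Y)
        validate_events(a.events)
        for bundle in a.bundles:
            validate_channel_table(bundle.response.channels)
        assert a.features.values.min() >= 0 and a.features.values.max() <= 1

    def test_ages_and_groups_consistent(self):
        study = fe.simulate_cohort(n_subjects=10, age_range=(5.0, 50.0),
                                   seed=SEED)
        for s in study.subjects:
            assert 5.0 <= s.age <= 50.0
            assert s.group == ("childhood" if s.age <= 12
                               else "post_childhood")

    def test_truth_weights_age_structured(self, config):
        study = fe.simulate_cohort(n_subjects=8, age_slope=0.02,
                                   base_complex=0.1, jitter_sd=0.0,
                                   seed=SEED)
        guilt = config.feature_names.index("guilt")
        amps = [np.abs(study.truths[s.id].weights["speech"][guilt]).sum()
                for s in study.subjects]
        ages = [s.age for s in study.subjects]
        np.testing.assert_allclose(amps, 0.1 + 0.02 * np.asarray(ages),
                                   atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            fe.simulate_cohort(n_subjects=2, seed=0)
        with pytest.raises(ValueError, match="age range"):
            fe.simulate_cohort(n_subjects=5, age_range=(30.0, 30.0), seed=0)

    def test_group_contrast_structure(self, config):
        study = fe.simulate_group_contrast(n_childhood=3, n_post=4, seed=SEED)
        groups = [s.group for s in study.subjects]
        assert groups.count("childhood") == 3
        for s in study.subjects:
            W = study.truths[s.id].weights["speech"]
            if s.group == "childhood":
                assert np.all(W == 0.0)
            else:
                assert np.abs(W).sum() > 0

    def test_raw_subject_recoverable(self, features_full, features, events,
                                     config, rng):
        """Generative/analytic consistency through the raw chain: the
        normalized HFB correlates with the known modulation target."""
        amps = {f: 0.25 for f in config.basic_group}
        W = _sparse_weights(rng, config.feature_names, amps, config.lags)
        truth = GroundTruth(weights={"speech": W, "music": W},
                            coupling_snr=4.0, ar_coef=0.3)
        subject = SubjectRecord("s1", 25.0, "post_childhood")
        gap_events = standard_events(gap=2.0)
        rec = simulate_subject_raw(subject, gap_events, features_full, truth,
                                   config.lags, n_contacts=2, n_other=2,
                                   seed=SEED)
        assert rec.fs == 2048.0
        epochs = fe.preprocess(rec, gap_events, config)
        resp = fe.bin_response(epochs, 0.5, n_bins=60)
        design = fe.build_design_matrix(features, config.lags)
        s = design.X @ W.reshape(-1)
        r = np.corrcoef(resp.Y[:, 0], s)[0, 1]
        assert r > 0.5
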