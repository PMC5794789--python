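import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import inhaleraudio as ia
from inhaleraudio.classifier import (ClassModel, ClassModelSet, FrameLabelSeq,
                                     TrainingError, adapt_inhalation_model,
                                     classify_frames, classify_recording,
                                     estimate_noise, form_events,
                                     initial_classify_euclidean, load_models,
                                     save_models, smooth_labels, train)
from inhaleraudio.features import FeatureMatrix


def _fm(values, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values, list(names), np.arange(values.shape[0]) * 0.02)


def _spherical_models(means, prior=None, names=None, var=1.0):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, d = means.shape
    priors = prior or [1.0 / k] * k
    return ClassModelSet(
        {i + 1: ClassModel(i + 1, means[i], var * np.eye(d), priors[i])
         for i in range(k)},
        names or [f"f{i}" for i in range(d)])


class TestTraining:
    def test_recovers_cluster_means(self):
        rng = np.random.default_rng(20)
        a = rng.normal([0.0, 0.0], 0.5, (500, 2))
        b = rng.normal([5.0, 5.0], 0.5, (500, 2))
        feats = _fm(np.vstack([a, b]))
        labels = np.repeat([1, 3], 500)
        models = train(feats, labels)
        assert np.allclose(models.models[1].mean, [0, 0], atol=0.1)
        assert np.allclose(models.models[3].mean, [5, 5], atol=0.1)

    def test_priors_are_frame_frequencies(self):
        rng = np.random.default_rng(21)
        feats = _fm(rng.normal(size=(1000, 2)))
        labels = np.repeat([1, 2, 3, 4], [100, 300, 100, 500])
        models = train(feats, labels)
        priors = [models.models[c].prior for c in (1, 2, 3, 4)]
        assert priors == pytest.approx([0.1, 0.3, 0.1, 0.5])

    def test_singular_duplicate_feature_still_classifiable(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=(200, 1))
        feats = _fm(np.hstack([x, x]))  # rank-deficient covariance
        labels = np.repeat([1, 3], 100)
        models = train(feats, labels)
        out = classify_frames(models, feats)  # Cholesky must succeed
        assert out.labels.size == 200

    def test_undersized_class_raises(self):
        feats = _fm(np.random.default_rng(23).normal(size=(10, 4)))
        labels = np.array([1] * 7 + [3] * 3)
        with pytest.raises(TrainingError, match="class 3"):
            train(feats, labels)


class TestNoiseEstimation:
    def test_lowest_40_percent_selected(self):
        # strictly increasing energy over 20 frames -> frames 0..7 define noise
        d = 3
        values = np.column_stack([
            np.arange(20.0), np.zeros(20), np.arange(20.0) * 2])
        feats = _fm(values, names=["rms_energy", "a", "b"])
        models = _spherical_models([[50, 0, 0], [60, 0, 0]],
                                   names=["rms_energy", "a", "b"])
        out = estimate_noise(models, feats)
        expected = values[:8].mean(axis=0)  # floor(0.4 * 20) = 8
        assert np.allclose(out.models[1].mean, expected)
        assert np.allclose(out.models[2].mean, [60, 0, 0])  # untouched

    def test_background_recording_mean_close_to_overall(self):
        rng = np.random.default_rng(24)
        values = rng.normal(0.0, 1.0, (200, 2))
        energy = np.abs(rng.normal(1.0, 0.01, 200))
        feats = _fm(values)
        models = _spherical_models([[9, 9], [20, 20]])
        out = estimate_noise(models, feats, energy=energy)
        sd = values.std(axis=0)
        assert np.all(np.abs(out.models[1].mean - values.mean(axis=0))
                      <= sd / np.sqrt(80) * 3)

    def test_short_recording_unchanged(self):
        feats = _fm(np.random.default_rng(25).normal(size=(10, 2)))
        models = _spherical_models([[0, 0], [5, 5]])
        with pytest.warns(UserWarning, match="too short"):
            out = estimate_noise(models, feats,
                                 energy=np.ones(10))
        assert np.allclose(out.models[1].mean, models.models[1].mean)


class TestInitialClassification:
    def test_nearest_mean_1d(self):
        models = _spherical_models([[0.0], [10.0], [20.0], [30.0]])
        out = initial_classify_euclidean(models, _fm([[12.0]]))
        assert out.labels[0] == 2

    def test_tie_goes_to_lower_class(self):
        models = _spherical_models([[0.0], [10.0], [20.0], [30.0]])
        out = initial_classify_euclidean(models, _fm([[15.0]]))
        assert out.labels[0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(26)
        means = rng.normal(size=(4, 3))
        models = _spherical_models(means)
        x = rng.normal(size=(300, 3))
        out = initial_classify_euclidean(models, _fm(x))
        brute = 1 + np.array([
            int(np.argmin([np.sqrt(np.sum((xi - m) ** 2)) for m in means]))
            for xi in x])
        assert np.array_equal(out.labels, brute)


class TestAdaptation:
    def test_half_shift_closed_form(self):
        delta = np.array([1.0, -2.0])
        mu3 = np.array([10.0, 10.0])
        models = _spherical_models([[-50, -50], [-40, -40], mu3, [60, 60]])
        frames = _fm(np.tile(mu3 + delta, (20, 1)))
        out = adapt_inhalation_model(models, frames)
        assert np.allclose(out.models[3].mean, mu3 + delta / 2.0)
        assert np.allclose(out.models[2].mean, [-40, -40])

    def test_no_inhalation_frames_no_change(self):
        models = _spherical_models([[0, 0], [10, 10], [50, 50], [90, 90]])
        frames = _fm(np.zeros((5, 2)))
        with pytest.warns(UserWarning, match="no adaptation"):
            out = adapt_inhalation_model(models, frames)
        assert np.allclose(out.models[3].mean, [50, 50])

    def test_second_pass_halves_remaining_gap(self):
        delta = np.array([4.0, 0.0])
        mu3 = np.array([10.0, 0.0])
        models = _spherical_models([[-90, 0], [-50, 0], mu3, [90, 0]])
        frames = _fm(np.tile(mu3 + delta, (20, 1)))
        once = adapt_inhalation_model(models, frames)
        twice = adapt_inhalation_model(once, frames)
        assert np.allclose(once.models[3].mean, mu3 + delta / 2)
        assert np.allclose(twice.models[3].mean, mu3 + 0.75 * delta)

    def test_adaptation_moves_mean_toward_centroid(self):
        rng = np.random.default_rng(27)
        models = _spherical_models(rng.normal(0, 5, size=(4, 3)))
        x = rng.normal(models.models[3].mean + 2.0, 0.2, (50, 3))
        out = adapt_inhalation_model(models, _fm(x))
        centroid = x.mean(axis=0)
        before = np.linalg.norm(models.models[3].mean - centroid)
        after = np.linalg.norm(out.models[3].mean - centroid)
        assert after < before


class TestQda:
    def test_reduces_to_nearest_mean_for_shared_spherical(self):
        rng = np.random.default_rng(28)
        models = _spherical_models(rng.normal(size=(4, 3)))
        x = _fm(rng.normal(size=(200, 3)))
        assert np.array_equal(classify_frames(models, x).labels,
                              initial_classify_euclidean(models, x).labels)

    def test_narrow_class_wins_at_shared_mean(self):
        models = ClassModelSet(
            {1: ClassModel(1, np.array([0.0]), np.array([[1.0]]), 0.5),
             2: ClassModel(2, np.array([0.0]), np.array([[9.0]]), 0.5)},
            ["f0"])
        out = classify_frames(models, _fm([[0.0]]))
        assert out.labels[0] == 1

    def test_matches_brute_force_densities(self):
        rng = np.random.default_rng(29)
        d = 3
        models = {}
        for c in range(1, 5):
            a = rng.normal(size=(d, d))
            cov = a @ a.T + 0.5 * np.eye(d)
            models[c] = ClassModel(c, rng.normal(size=d), cov, 0.25)
        mset = ClassModelSet(models, [f"f{i}" for i in range(d)])
        x = rng.normal(size=(200, d))
        out = classify_frames(mset, _fm(x))

        def density(xi, m):
            diff = xi - m.mean
            inv = np.linalg.inv(m.cov)
            det = np.linalg.det(m.cov)
            return (np.exp(-0.5 * diff @ inv @ diff)
                    / np.sqrt(2 * np.pi * det) * m.prior)

        brute = 1 + np.array([
            int(np.argmax([density(xi, models[c]) for c in range(1, 5)]))
            for xi in x])
        assert np.array_equal(out.labels, brute)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(30)
        feats = _fm(rng.normal(size=(300, 3)))
        labels = np.repeat([1, 2, 3], 100)
        models = train(feats, labels)
        save_models(tmp_path / "m.json", models)
        back = load_models(tmp_path / "m.json")
        out_a = classify_frames(models, feats).labels
        out_b = classify_frames(back, feats).labels
        assert np.array_equal(out_a, out_b)


class TestSmoothing:
    @pytest.mark.parametrize("seq,expected", [
        ([3, 3, 4, 3, 3], [3, 3, 3, 3, 3]),
        ([2, 2, 2, 2], [2, 2, 2, 2]),
        ([1, 1, 1, 4, 4, 4, 1, 1, 1], [1, 1, 1, 4, 4, 4, 1, 1, 1]),
    ])
    def test_median_filter_cases(self, seq, expected):
        out = smooth_labels(FrameLabelSeq(np.array(seq),
                                          np.arange(len(seq)) * 0.02))
        assert out.labels.tolist() == expected

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_median_never_invents_classes(self, seq):
        labels = FrameLabelSeq(np.array(seq), np.arange(len(seq)) * 0.02)
        out = smooth_labels(labels).labels
        x = np.array(seq)
        half = 2
        padded = np.concatenate([np.repeat(x[0], half), x,
                                 np.repeat(x[-1], half)])
        for i, v in enumerate(out):
            assert v in padded[i:i + 5]


class TestEventFormation:
    def _seq(self, labels):
        return FrameLabelSeq(np.array(labels), np.arange(len(labels)) * 0.02)

    def test_four_inhalation_frames_dropped(self):
        events = form_events(self._seq([1, 3, 3, 3, 3, 1]))
        assert events == []

    def test_five_inhalation_frames_kept(self):
        events = form_events(self._seq([1, 3, 3, 3, 3, 3, 1]))
        assert len(events) == 1
        ev = events[0]
        assert ev.class_id == 3 and ev.n_frames == 5
        # first-frame start to last-frame end: 4 steps + one frame length
        assert ev.end_s - ev.start_s == pytest.approx(4 * 0.02 + 0.04)

    def test_short_actuation_kept(self):
        events = form_events(self._seq([1, 1, 4, 4, 1, 1]))
        assert len(events) == 1 and events[0].class_id == 4


class TestRecordingPipeline:
    def test_synthetic_recording_event_sequence(self, corpus):
        scenarios, recordings = corpus
        import warnings
        from inhaleraudio.corpus import train_from_recordings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_from_recordings(
                [(s, t) for s, t, _ in recordings[:8]])
            sig, track, _ = recordings[10]
            _, events = classify_recording(sig, models)
        got = [(e.class_id, e.start_s) for e in events]
        true = [(c, s) for s, e, c in sorted(track.entries)]
        assert [c for c, _ in sorted(got, key=lambda t: t[1])] == \
            [c for c, _ in true]
        for (gc, gs), (tc, ts) in zip(sorted(got, key=lambda t: t[1]), true):
            assert abs(gs - ts) <= 3 * 0.02 + 1e-9

    def test_pure_noise_recording_has_no_events(self, corpus):
        import warnings
        _, recordings = corpus
        from inhaleraudio.corpus import train_from_recordings
        rng = np.random.default_rng(31)
        noise = ia.AudioSignal(1e-3 * rng.normal(size=48000 * 3), 48000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_from_recordings(
                [(s, t) for s, t, _ in recordings[:8]])
            _, events = classify_recording(noise, models)
        assert events == []

    def test_deterministic(self, corpus):
        import warnings
        _, recordings = corpus
        from inhaleraudio.corpus import train_from_recordings
        sig, _, _ = recordings[9]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_from_recordings(
                [(s, t) for s, t, _ in recordings[:8]])
            a, ev_a = classify_recording(sig, models)
            b, ev_b = classify_recording(sig, models)
        assert np.array_equal(a.labels, b.labels)
        assert ev_a == ev_b
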