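"""Shared fixtures: small deterministic signals and the synthetic corpus.

The end-to-end corpus (40 recordings) is expensive to build, so it is
generated once per session and shared by the evaluation tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import inhaleraudio as ia
from inhaleraudio.corpus import (inhalation_flow_from_events,
                                 recording_features, train_from_recordings)
from inhaleraudio.classifier import classify_features
from inhaleraudio.technique import event_metrics

CORPUS_SEED = 20180201
CORPUS_SIZE = 40


def tone(freq: float, fs: float, duration: float, amp: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def corpus():
    """40 labelled synthetic recordings at 15-25 dB SNR with ground truth."""
    scenarios = ia.make_scenarios(CORPUS_SIZE, master_seed=CORPUS_SEED,
                                  snr_range_db=(15.0, 25.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recordings = [ia.synth_recording(sc) for sc in scenarios]
    return scenarios, recordings


@pytest.fixture(scope="session")
def corpus_evaluation(corpus):
    """Hold-out evaluation: train on the first half, test on the second.

    Returns (event metrics on the test half, per-recording PIFR round-trip
    accuracies on the test half).
    """
    scenarios, recordings = corpus
    half = CORPUS_SIZE // 2
    train_recs = [(s, t) for s, t, _ in recordings[:half]]
    test_recs = recordings[half:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = train_from_recordings(train_recs)
        pred_events, true_events, pred_frames, true_frames = [], [], [], []
        pifr_accuracies = []
        for sig, track, truth in test_recs:
            feats, frame_labels = recording_features(sig, track)
            seq, events = classify_features(models, feats)
            pred_events.append(events)
            true_events.append(track)
            pred_frames.append(seq.labels)
            true_frames.append(frame_labels)
            pifr, _ = inhalation_flow_from_events(sig, events)
            pifr_accuracies.append(
                ia.flow_accuracy(pifr if pifr is not None else 0.0,
                                 truth.pifr_lmin))
        metrics = event_metrics(pred_events, true_events,
                                pred_frames, true_frames)
    return metrics, np.asarray(pifr_accuracies)
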