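"""Corpus-level helpers: training from labelled recordings and evaluation.

These glue functions tie the per-recording pipeline together for whole
directories (or in-memory lists) of labelled recordings, as used by the
command-line interface and the end-to-end evaluation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classifier import (ClassModelSet, classify_features, preprocess, train)
from .features import FeatureMatrix, FeatureRegistry, extract_features
from .flow import (FlowModel, default_power_model, estimate_flow_profile,
                   estimate_pifr, estimate_volume, extract_flow_features)
from .signal_io import (INHALATION, AudioSignal, LabelTrack, labels_to_frames,
                        load_wav, read_labels)
from .technique import EventMetrics, event_metrics


def load_recording(wav_path: str | Path,
                   labels_path: str | Path | None = None,
                   ) -> tuple[AudioSignal, LabelTrack | None]:
    sig = load_wav(wav_path)
    track = read_labels(labels_path) if labels_path is not None else None
    return sig, track


def find_corpus(corpus_dir: str | Path) -> list[tuple[Path, Path]]:
    """Pair ``*.wav`` with ``*_labels.csv`` files in a directory."""
    corpus_dir = Path(corpus_dir)
    pairs = []
    for wav in sorted(corpus_dir.glob("*.wav")):
        lab = corpus_dir / f"{wav.stem}_labels.csv"
        if lab.exists():
            pairs.append((wav, lab))
    return pairs


def recording_features(sig: AudioSignal, track: LabelTrack | None,
                       registry: FeatureRegistry | None = None,
                       ) -> tuple[FeatureMatrix, np.ndarray | None]:
    """Stage-1 features plus (optionally) the frame labels of a recording."""
    frames = preprocess(sig)
    feats = extract_features(frames, registry or FeatureRegistry())
    labels = labels_to_frames(track, frames) if track is not None else None
    return feats, labels


def train_from_recordings(recordings: list[tuple[AudioSignal, LabelTrack]],
                          registry: FeatureRegistry | None = None,
                          ridge: float = 1e-6) -> ClassModelSet:
    """Pool labelled frames over recordings and fit the class models."""
    all_feats = []
    all_labels = []
    names = None
    times_offset = 0.0
    for sig, track in recordings:
        feats, labels = recording_features(sig, track, registry)
        names = feats.names
        all_feats.append(feats.values)
        all_labels.append(labels)
        times_offset += sig.duration
    pooled = FeatureMatrix(np.vstack(all_feats), list(names),
                           np.arange(sum(f.shape[0] for f in all_feats),
                                     dtype=float))
    return train(pooled, np.concatenate(all_labels), ridge=ridge)


def evaluate_classifier(models: ClassModelSet,
                        recordings: list[tuple[AudioSignal, LabelTrack]],
                        registry: FeatureRegistry | None = None,
                        ) -> EventMetrics:
    """Run the testing procedure on each recording and aggregate metrics."""
    pred_events, true_events, pred_frames, true_frames = [], [], [], []
    for sig, track in recordings:
        feats, labels = recording_features(sig, track, registry)
        seq, events = classify_features(models, feats)
        pred_events.append(events)
        true_events.append(track)
        pred_frames.append(seq.labels)
        true_frames.append(labels)
    return event_metrics(pred_events, true_events, pred_frames, true_frames)


def inhalation_flow_from_events(sig: AudioSignal, events,
                                model: FlowModel | None = None,
                                ) -> tuple[float | None, float | None]:
    """PIFR and volume from the detected inhalation events of a recording.

    Each detected inhalation span is analysed separately -- an actuation
    inside the breath splits the inhalation into two events, and keeping
    the actuation frames out of the analysed audio keeps its broadband
    leakage out of the harmonic bands.  The reed fundamental is estimated
    on the longest span and reused for the shorter ones.  PIFR is the
    maximum over spans; volume is the sum.  Returns (None, None) when no
    inhalation was detected or no reed sound is found.
    """
    model = model or default_power_model()
    spans = [(e.start_s, e.end_s) for e in events if e.class_id == INHALATION]
    spans = [(s, e) for s, e in spans if e - s >= 0.15]
    if not spans:
        return None, None
    segments = []
    for s, e in spans:
        i0, i1 = int(s * sig.fs), int(e * sig.fs)
        segments.append(AudioSignal(sig.samples[i0:i1], sig.fs, sig.source_id))
    longest = max(segments, key=lambda x: x.duration)
    f0 = extract_flow_features(longest).f0
    if f0 is None:
        return None, None
    pifr_best: float | None = None
    volume_total = 0.0
    for seg in segments:
        feats = extract_flow_features(seg, f0=f0)
        pifr = estimate_pifr(feats, model)
        if pifr is not None:
            pifr_best = pifr if pifr_best is None else max(pifr_best, pifr)
        profile = estimate_flow_profile(feats, model)
        if profile.times.size >= 2:
            volume_total += estimate_volume(profile)
    if pifr_best is None:
        return None, None
    return pifr_best, volume_total
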