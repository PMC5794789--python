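"""Frame-by-frame sound-event classification with per-class Gaussian models.

Training fits one Gaussian (mean, full covariance, prior) per class from
labelled frames.  Testing on a new recording runs four steps:

1. noise estimation -- the noise-class model is re-estimated from the frames
   with the lowest 40% RMS energy of *this* recording;
2. model adaptation -- an initial nearest-mean (Euclidean) classification
   picks out inhalation-like frames, and the inhalation mean is moved to the
   average of the trained mean and those frames' centroid (this absorbs the
   pitch/loudness variability across Flo-Tone mouthpieces);
3. frame-by-frame quadratic-discriminant classification: argmax over classes
   of the Gaussian density times the class prior, computed in the log domain;
4. event formation -- an order-5 median filter smooths the label sequence,
   maximal same-class runs become events, and inhalation/exhalation runs
   shorter than five frames (100 ms) are discarded as noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg

from .features import FeatureMatrix, FeatureRegistry, extract_features, rms_energy
from .signal_io import (ACTUATION, EXHALATION, INHALATION, NOISE, AudioSignal,
                        FrameMatrix, bandpass, frame_signal)

DEFAULT_RIDGE = 1e-6
MIN_EVENT_FRAMES = 5          # 100 ms at the 20 ms frame rate
MEDIAN_ORDER = 5
NOISE_ENERGY_FRACTION = 0.4


class TrainingError(ValueError):
    pass


@dataclass
class ClassModel:
    class_id: int
    mean: np.ndarray
    cov: np.ndarray
    prior: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if not 0.0 < self.prior <= 1.0:
            raise ValueError("prior must be in (0, 1]")


@dataclass
class ClassModelSet:
    models: dict[int, ClassModel]
    feature_names: list[str]
    ridge: float = DEFAULT_RIDGE
    feature_scale: np.ndarray | None = None   # pooled per-feature SD

    def __post_init__(self) -> None:
        dims = {m.mean.size for m in self.models.values()}
        if len(dims) != 1:
            raise ValueError("all class models must share one dimension")
        total = sum(m.prior for m in self.models.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if self.feature_scale is not None:
            self.feature_scale = np.asarray(self.feature_scale,
                                            dtype=np.float64)

    @property
    def dim(self) -> int:
        return next(iter(self.models.values())).mean.size

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.models)

    def copy(self) -> "ClassModelSet":
        return ClassModelSet(
            {c: ClassModel(c, m.mean.copy(), m.cov.copy(), m.prior)
             for c, m in self.models.items()},
            list(self.feature_names), self.ridge,
            None if self.feature_scale is None else self.feature_scale.copy())


@dataclass
class FrameLabelSeq:
    labels: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


@dataclass
class SoundEvent:
    class_id: int
    start_s: float
    end_s: float
    n_frames: int


def _regularised_cov(x: np.ndarray, ridge: float,
                     scale: np.ndarray | None = None) -> np.ndarray:
    """Sample covariance plus a small ridge so Cholesky always succeeds.

    The ridge is scaled per dimension by the pooled feature SDs (``scale``)
    because the raw features span wildly different magnitudes (spectral
    centroid in kHz against RMS near 1e-2); an isotropic trace-scaled ridge
    would drown the small-magnitude features and disable them as
    discriminators.  Falls back to trace/d scaling when no pooled scale is
    available.
    """
    d = x.shape[1]
    cov = np.cov(x, rowvar=False, bias=False) if x.shape[0] > 1 else np.zeros((d, d))
    cov = np.atleast_2d(cov)
    if scale is not None:
        return cov + ridge * np.diag(np.maximum(scale, 1e-12) ** 2)
    tr = max(np.trace(cov) / d, 1e-12)
    return cov + ridge * tr * np.eye(d)


def train(features: FeatureMatrix, frame_labels: np.ndarray,
          ridge: float = DEFAULT_RIDGE) -> ClassModelSet:
    """Fit per-class Gaussians; priors are class frame frequencies."""
    frame_labels = np.asarray(frame_labels)
    if frame_labels.size != features.n_frames:
        raise ValueError("label/frame count mismatch")
    d = features.values.shape[1]
    classes = sorted(np.unique(frame_labels))
    n_total = frame_labels.size
    pooled_sd = features.values.std(axis=0)
    pooled_sd = np.where(pooled_sd > 0, pooled_sd,
                         max(float(pooled_sd.max()), 1.0) * 1e-6)
    models: dict[int, ClassModel] = {}
    for cls in classes:
        x = features.values[frame_labels == cls]
        if x.shape[0] < d + 2:
            raise TrainingError(
                f"class {cls} has only {x.shape[0]} frames; need >= {d + 2}")
        models[int(cls)] = ClassModel(
            int(cls), x.mean(axis=0), _regularised_cov(x, ridge, pooled_sd),
            x.shape[0] / n_total)
    return ClassModelSet(models, list(features.names), ridge,
                         feature_scale=pooled_sd)


def estimate_noise(models: ClassModelSet, features: FeatureMatrix,
                   energy: np.ndarray | None = None) -> ClassModelSet:
    """Re-estimate the noise model from this recording's quietest frames.

    The frames holding the lowest 40% of RMS energy values re-define the
    noise-class mean and covariance; priors and the other classes are kept.
    Recordings shorter than 13 frames are left unchanged with a warning.
    """
    if energy is None:
        if "rms_energy" not in features.names:
            raise ValueError("no rms_energy column and no energy array given")
        energy = features.column("rms_energy")
    energy = np.asarray(energy, dtype=np.float64)
    n = features.n_frames
    k = int(np.floor(NOISE_ENERGY_FRACTION * n))
    if n < 13 or k < 5:
        warnings.warn(f"recording of {n} frames too short for noise "
                      "estimation; models unchanged")
        return models
    quiet = np.argsort(energy, kind="stable")[:k]
    x = features.values[quiet]
    out = models.copy()
    old = out.models[NOISE]
    out.models[NOISE] = ClassModel(
        NOISE, x.mean(axis=0),
        _regularised_cov(x, models.ridge, models.feature_scale), old.prior)
    return out


def initial_classify_euclidean(models: ClassModelSet,
                               features: FeatureMatrix) -> FrameLabelSeq:
    """Nearest class mean in Euclidean distance; ties go to the lowest id."""
    ids = models.class_ids
    means = np.stack([models.models[c].mean for c in ids])
    d2 = ((features.values[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    choice = np.argmin(d2, axis=1)  # argmin takes the first (lowest id) on ties
    labels = np.asarray(ids)[choice]
    return FrameLabelSeq(labels, features.frame_times)


def adapt_inhalation_model(models: ClassModelSet,
                           features: FeatureMatrix) -> ClassModelSet:
    """Shift the inhalation mean halfway toward this recording's inhalation
    frames, as found by the initial Euclidean classification.

    Leaves the covariance and every other class untouched; a recording with
    no inhalation-like frames leaves the models unchanged (with a warning).
    """
    initial = initial_classify_euclidean(models, features)
    mask = initial.labels == INHALATION
    if not np.any(mask):
        warnings.warn("no inhalation-like frames found; no adaptation")
        return models
    centroid = features.values[mask].mean(axis=0)
    out = models.copy()
    m = out.models[INHALATION]
    out.models[INHALATION] = replace(m, mean=(m.mean + centroid) / 2.0)
    return out


def _log_scores(models: ClassModelSet, x: np.ndarray) -> np.ndarray:
    """Log of (Gaussian density * prior) per class, (n_frames, n_classes)."""
    scores = np.empty((x.shape[0], len(models.class_ids)))
    for j, cls in enumerate(models.class_ids):
        m = models.models[cls]
        try:
            chol = linalg.cholesky(m.cov, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(f"covariance of class {cls} is not positive "
                             "definite") from exc
        z = linalg.solve_triangular(chol, (x - m.mean).T, lower=True)
        maha = np.sum(z ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        scores[:, j] = -0.5 * (maha + logdet) + np.log(m.prior)
    return scores


def classify_frames(models: ClassModelSet,
                    features: FeatureMatrix) -> FrameLabelSeq:
    """Quadratic-discriminant frame classification (log-domain argmax of
    prior-weighted Gaussian density); ties go to the lowest class id."""
    scores = _log_scores(models, features.values)
    choice = np.argmax(scores, axis=1)
    labels = np.asarray(models.class_ids)[choice]
    return FrameLabelSeq(labels, features.frame_times)


def smooth_labels(labels: FrameLabelSeq, order: int = MEDIAN_ORDER) -> FrameLabelSeq:
    """Sliding median of the class-id sequence, edges padded by replication."""
    if order % 2 == 0:
        raise ValueError("median order must be odd")
    x = labels.labels
    if x.size == 0:
        return labels
    half = order // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, order)
    smoothed = np.median(windows, axis=1).astype(np.int64)
    return FrameLabelSeq(smoothed, labels.frame_times)


def form_events(labels: FrameLabelSeq, frame_len_s: float = 0.04,
                min_frames: int = MIN_EVENT_FRAMES) -> list[SoundEvent]:
    """Concatenate maximal same-class runs into events.

    Inhalation and exhalation runs shorter than ``min_frames`` (five frames,
    100 ms) are treated as noise and dropped; actuation events are kept at
    any length (real actuation bursts can be a couple of frames long).
    """
    x = labels.labels
    times = labels.frame_times
    events: list[SoundEvent] = []
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[j + 1] == x[i]:
            j += 1
        cls = int(x[i])
        n_run = j - i + 1
        if cls in (EXHALATION, INHALATION) and n_run >= min_frames:
            events.append(SoundEvent(cls, float(times[i]),
                                     float(times[j] + frame_len_s), n_run))
        elif cls == ACTUATION:
            events.append(SoundEvent(cls, float(times[i]),
                                     float(times[j] + frame_len_s), n_run))
        i = j + 1
    return events


def classify_features(models: ClassModelSet, features: FeatureMatrix,
                      energy: np.ndarray | None = None,
                      frame_len_s: float = 0.04,
                      adapt: bool = True,
                      ) -> tuple[FrameLabelSeq, list[SoundEvent]]:
    """Steps 1-4 of the testing procedure on a precomputed feature matrix.

    ``features`` may hold more columns than the model uses; the model's
    feature subset is taken by name.  ``energy`` supplies per-frame RMS for
    the noise-estimation rule when the model subset excludes it.
    """
    if energy is None and "rms_energy" in features.names:
        energy = features.column("rms_energy")
    sub = features.subset(models.feature_names) \
        if features.names != models.feature_names else features
    m1 = estimate_noise(models, sub, energy=energy)
    m2 = adapt_inhalation_model(m1, sub) if adapt else m1
    raw = classify_frames(m2, sub)
    smooth = smooth_labels(raw)
    events = form_events(smooth, frame_len_s=frame_len_s)
    return smooth, events


def classify_recording(sig: AudioSignal, models: ClassModelSet,
                       band: tuple[float, float] = (140.0, 22000.0),
                       frame_len_s: float = 0.04, step_s: float = 0.02,
                       registry: FeatureRegistry | None = None,
                       ) -> tuple[FrameLabelSeq, list[SoundEvent]]:
    """Full pipeline: band-pass, frame, extract features, classify, form events."""
    frames = preprocess(sig, band=band, frame_len_s=frame_len_s, step_s=step_s)
    if registry is None:
        registry = FeatureRegistry(list(models.feature_names)) \
            if set(models.feature_names) <= set(FeatureRegistry().names) \
            else FeatureRegistry()
    feats = extract_features(frames, registry)
    energy = feats.column("rms_energy") if "rms_energy" in feats.names \
        else rms_energy(frames.frames)
    return classify_features(models, feats, energy=energy,
                             frame_len_s=frame_len_s)


def preprocess(sig: AudioSignal, band: tuple[float, float] = (140.0, 22000.0),
               frame_len_s: float = 0.04, step_s: float = 0.02) -> FrameMatrix:
    """Stage-1 pre-processing: band-pass then 40/20 ms DC-free frames."""
    filtered = bandpass(sig, band[0], band[1])
    return frame_signal(filtered, frame_len_s, step_s, remove_dc=True)


def events_to_labeltrack(events: list[SoundEvent]) -> "LabelTrack":
    """Convert detected events to a label track, clipping the 20 ms span
    overlap that adjacent events inherit from the frame overlap."""
    from .signal_io import LabelTrack
    ordered = sorted(events, key=lambda e: e.start_s)
    entries = []
    for k, ev in enumerate(ordered):
        end = ev.end_s
        if k + 1 < len(ordered):
            end = min(end, ordered[k + 1].start_s)
        if end > ev.start_s:
            entries.append((ev.start_s, end, ev.class_id))
    return LabelTrack(entries)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_models(path: str | Path, models: ClassModelSet) -> None:
    doc = {
        "feature_names": models.feature_names,
        "ridge": models.ridge,
        "feature_scale": None if models.feature_scale is None
        else models.feature_scale.tolist(),
        "classes": {
            str(c): {"mean": m.mean.tolist(), "cov": m.cov.tolist(),
                     "prior": m.prior}
            for c, m in models.models.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_models(path: str | Path) -> ClassModelSet:
    doc = json.loads(Path(path).read_text())
    models = {
        int(c): ClassModel(int(c), np.array(v["mean"]), np.array(v["cov"]),
                           float(v["prior"]))
        for c, v in doc["classes"].items()
    }
    scale = doc.get("feature_scale")
    return ClassModelSet(models, list(doc["feature_names"]),
                         float(doc.get("ridge", DEFAULT_RIDGE)),
                         None if scale is None else np.array(scale))
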