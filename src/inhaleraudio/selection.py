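"""Sequential forward feature selection under a weighted performance measure.

The selection criterion combines event-level sensitivity (S) and positive
predictive value (P) of the three inhaler sound classes:

    J(X) = w_A (S_A + P_A) + w_I (S_I + P_I) + w_E (S_E + P_E)

with weights 0.2 (actuation), 0.2 (inhalation) and 0.1 (exhalation); a
perfect classifier scores J = 100.  The greedy wrapper adds, at each step,
the feature that maximises J of the full classification pipeline on held-out
validation recordings, and stops when the best improvement falls below a
small threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainingError, classify_features, train
from .features import FeatureMatrix
from .signal_io import ACTUATION, EXHALATION, INHALATION
from .technique import EventMetrics, event_metrics

DEFAULT_WEIGHTS = {"A": 0.2, "I": 0.2, "E": 0.1}
IMPROVEMENT_THRESHOLD = 0.01  # J percentage points


@dataclass
class SelectionResult:
    selected: list[str]
    J_trajectory: list[float]
    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def best_subset(self) -> list[str]:
        """Features up to (and including) the trajectory argmax."""
        k = int(np.argmax(self.J_trajectory)) + 1
        return self.selected[:k]


def weighted_J(s_a: float, p_a: float, s_i: float, p_i: float,
               s_e: float, p_e: float,
               weights: dict[str, float] | None = None) -> float:
    """Weighted performance measure in percent."""
    weights = weights or DEFAULT_WEIGHTS
    vals = (s_a, p_a, s_i, p_i, s_e, p_e)
    for v in vals:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"sensitivity/PPV {v} outside [0, 100]")
    return (weights["A"] * (s_a + p_a)
            + weights["I"] * (s_i + p_i)
            + weights["E"] * (s_e + p_e))


def metrics_to_J(metrics: EventMetrics,
                 weights: dict[str, float] | None = None) -> float:
    return weighted_J(
        metrics.sensitivity[ACTUATION], metrics.ppv[ACTUATION],
        metrics.sensitivity[INHALATION], metrics.ppv[INHALATION],
        metrics.sensitivity[EXHALATION], metrics.ppv[EXHALATION],
        weights=weights)


def _evaluate_subset(names: list[str],
                     train_features: FeatureMatrix,
                     train_labels: np.ndarray,
                     val_recordings: list[tuple[FeatureMatrix, np.ndarray, list]],
                     ridge: float,
                     weights: dict[str, float] | None) -> float:
    models = train(train_features.subset(names), train_labels, ridge=ridge)
    pred_events, true_events, pred_frames, true_frames = [], [], [], []
    for feats, frame_labels, events in val_recordings:
        energy = (feats.column("rms_energy")
                  if "rms_energy" in feats.names else None)
        labels, evs = classify_features(models, feats, energy=energy)
        pred_events.append(evs)
        true_events.append(events)
        pred_frames.append(labels.labels)
        true_frames.append(frame_labels)
    return metrics_to_J(
        event_metrics(pred_events, true_events, pred_frames, true_frames),
        weights=weights)


def sequential_forward_selection(
        train_features: FeatureMatrix,
        train_labels: np.ndarray,
        val_recordings: list[tuple[FeatureMatrix, np.ndarray, list]],
        candidate_names: list[str] | None = None,
        ridge: float = 1e-6,
        weights: dict[str, float] | None = None,
        improvement_threshold: float = IMPROVEMENT_THRESHOLD,
        max_features: int | None = None) -> SelectionResult:
    """Greedy forward wrapper selection maximising J on validation recordings.

    ``val_recordings`` holds per-recording tuples of (feature matrix, true
    frame labels, true events).  Candidate features whose single-class data
    is degenerate (training fails) are skipped.  Deterministic for fixed
    inputs; ties between candidates go to the earlier registry position.
    """
    candidates = list(candidate_names or train_features.names)
    if not candidates:
        raise ValueError("no candidate features")
    val_classes = set()
    for _, frame_labels, _ in val_recordings:
        val_classes.update(np.unique(frame_labels).tolist())
    if len(val_classes) < 2:
        raise ValueError("validation recordings contain a single class only")

    selected: list[str] = []
    trajectory: list[float] = []
    current_J = -np.inf
    limit = max_features or len(candidates)
    while candidates and len(selected) < limit:
        best_name, best_J = None, -np.inf
        for name in candidates:
            try:
                j = _evaluate_subset(selected + [name], train_features,
                                     train_labels, val_recordings,
                                     ridge, weights)
            except TrainingError:
                continue
            if j > best_J:
                best_name, best_J = name, j
        if best_name is None:
            break
        if selected and best_J - current_J < improvement_threshold:
            break
        selected.append(best_name)
        trajectory.append(best_J)
        candidates.remove(best_name)
        current_J = best_J
    return SelectionResult(selected, trajectory,
                           dict(weights or DEFAULT_WEIGHTS))
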