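"""Critical user-technique errors, evaluation metrics and agreement statistics.

Two critical pMDI errors are assessed per recording:

* poor actuation coordination -- no actuation onset falls inside a detected
  inhalation event;
* inhaling too fast -- peak inspiratory flow rate strictly above 90 L/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import SoundEvent
from .signal_io import ACTUATION, EXHALATION, INHALATION, LabelTrack

PIFR_TOO_FAST_LMIN = 90.0
EVENT_CLASSES = (EXHALATION, INHALATION, ACTUATION)


@dataclass
class TechniqueReport:
    """Per-recording user-technique findings."""

    recording_id: str
    events: list[SoundEvent]
    pifr_lmin: float | None
    volume_l: float | None
    poor_coordination: bool
    too_fast: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class EventMetrics:
    """Event-level sensitivity/PPV per class plus frame accuracy, in %."""

    sensitivity: dict[int, float]
    ppv: dict[int, float]
    frame_accuracy: float
    counts: dict[int, tuple[int, int, int]] = field(default_factory=dict)  # TP, FN, FP


def _as_triples(events: Iterable) -> list[tuple[int, float, float]]:
    out = []
    for ev in events:
        if isinstance(ev, SoundEvent):
            out.append((ev.class_id, ev.start_s, ev.end_s))
        else:
            s, e, c = ev  # LabelTrack entry order
            out.append((int(c), float(s), float(e)))
    return out


def assess_coordination(events: Iterable) -> tuple[bool, list[str]]:
    """Return (poor?, flags).

    Coordination is good iff at least one actuation onset lies within the
    closed span [onset, end] of some inhalation event.  Missing actuation or
    inhalation events are flagged and count as poor coordination.
    """
    triples = _as_triples(events)
    inhalations = [(s, e) for c, s, e in triples if c == INHALATION]
    actuations = [s for c, s, e in triples if c == ACTUATION]
    flags = []
    if not actuations:
        flags.append("no-actuation")
    if not inhalations:
        flags.append("no-inhalation")
    good = any(s0 <= a <= e0 for a in actuations for s0, e0 in inhalations)
    return (not good), flags


def assess_speed(pifr_lmin: float) -> bool:
    """True iff the inhalation was too fast (PIFR strictly over 90 L/min)."""
    if pifr_lmin < 0:
        raise ValueError("PIFR must be non-negative")
    return pifr_lmin > PIFR_TOO_FAST_LMIN


def assess_recording(recording_id: str, events: Sequence,
                     pifr_lmin: float | None,
                     volume_l: float | None = None) -> TechniqueReport:
    poor, flags = assess_coordination(events)
    if pifr_lmin is None:
        too_fast = False
        flags = flags + ["no-flow-estimate"]
    else:
        too_fast = assess_speed(pifr_lmin)
    return TechniqueReport(recording_id, list(events), pifr_lmin, volume_l,
                           poor, too_fast, flags)


def _match_events(pred: list[tuple[float, float]],
                  true: list[tuple[float, float]]) -> int:
    """One-to-one greedy matching by largest time overlap; returns TP count."""
    if not pred or not true:
        return 0
    overlap = np.zeros((len(pred), len(true)))
    for i, (ps, pe) in enumerate(pred):
        for j, (ts, te) in enumerate(true):
            overlap[i, j] = max(0.0, min(pe, te) - max(ps, ts))
    tp = 0
    used_p: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(
        np.argsort(-overlap, axis=None), overlap.shape))[0]
    for i, j in order:
        if overlap[i, j] <= 1e-9:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(int(i))
        used_t.add(int(j))
        tp += 1
    return tp


def event_metrics(predicted_events: Sequence[Iterable],
                  labelled_events: Sequence[Iterable],
                  predicted_frames: Sequence[np.ndarray],
                  labelled_frames: Sequence[np.ndarray]) -> EventMetrics:
    """Aggregate event sensitivity/PPV and frame accuracy over recordings.

    ``predicted_events[k]`` / ``labelled_events[k]`` are the events of
    recording k (SoundEvents or LabelTrack entries); the frame sequences are
    index-aligned label arrays for the same recordings.
    """
    if len(predicted_events) != len(labelled_events):
        raise ValueError("recording count mismatch")
    tp = {c: 0 for c in EVENT_CLASSES}
    fn = {c: 0 for c in EVENT_CLASSES}
    fp = {c: 0 for c in EVENT_CLASSES}
    for pred, true in zip(predicted_events, labelled_events):
        pred_t = _as_triples(pred)
        true_t = _as_triples(true if not isinstance(true, LabelTrack)
                             else true.entries)
        for c in EVENT_CLASSES:
            p = [(s, e) for cc, s, e in pred_t if cc == c]
            t = [(s, e) for cc, s, e in true_t if cc == c]
            m = _match_events(p, t)
            tp[c] += m
            fn[c] += len(t) - m
            fp[c] += len(p) - m
    sens = {}
    ppv = {}
    for c in EVENT_CLASSES:
        sens[c] = 100.0 * tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 100.0
        ppv[c] = 100.0 * tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 100.0
    correct = 0
    total = 0
    for p, t in zip(predicted_frames, labelled_frames):
        p = np.asarray(p)
        t = np.asarray(t)
        if p.size != t.size:
            raise ValueError("frame sequence length mismatch")
        correct += int(np.sum(p == t))
        total += p.size
    acc = 100.0 * correct / total if total else 100.0
    counts = {c: (tp[c], fn[c], fp[c]) for c in EVENT_CLASSES}
    return EventMetrics(sens, ppv, acc, counts)


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for two raters on dichotomous (or categorical) ratings.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement.
    Both raters constant *and identical* gives kappa = 1 by convention;
    constant but unequal raters leave kappa undefined and raise.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size:
        raise ValueError("rating vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two rated items")
    cats = np.unique(np.concatenate([a, b]))
    if np.unique(a).size == 1 and np.unique(b).size == 1:
        if a[0] == b[0]:
            return 1.0
        raise ValueError("kappa undefined: raters constant but unequal")
    p_o = np.mean(a == b)
    p_e = sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_from_table(table: np.ndarray) -> float:
    """Cohen's kappa from a square contingency table (rows rater A)."""
    t = np.asarray(table, dtype=np.float64)
    n = t.sum()
    p_o = np.trace(t) / n
    p_e = float(np.sum(t.sum(axis=1) * t.sum(axis=0)) / n ** 2)
    if abs(1.0 - p_e) < 1e-12:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: raters constant but unequal")
    return float((p_o - p_e) / (1.0 - p_e))


def cohort_summary(before: Mapping[str, Sequence[TechniqueReport]],
                   after: Mapping[str, Sequence[TechniqueReport]],
                   ) -> pd.DataFrame:
    """Percentage of subjects with each critical error on >= 1 recording,
    before and after tuition."""
    phases = {"before": before, "after": after}
    rows = {}
    for error, attr in (("poor_coordination", "poor_coordination"),
                        ("too_fast", "too_fast")):
        rows[error] = {}
        for phase, reports in phases.items():
            subjects = list(reports)
            if not subjects:
                continue
            flagged = sum(
                any(getattr(r, attr) for r in reports[s]) for s in subjects)
            rows[error][phase] = 100.0 * flagged / len(subjects)
    df = pd.DataFrame(rows).T
    return df.reindex(columns=[p for p in ("before", "after") if p in df.columns])
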