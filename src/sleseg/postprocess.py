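"""Rule-based correction of predicted SLE labels.

The classifier emits a per-sample probability series; events are obtained by
thresholding and then algorithmically corrected in a fixed order:

1. predicted events shorter than 0.1 s are dropped (most are interictal
   discharges or noise misclassified as SLEs),
2. consecutive events separated by less than 0.2 s are merged into one,
3. each event's endpoint is snapped to its final interior extremum (last
   strict local minimum or maximum of the signal within the event).

``corrected_accuracy`` is the per-sample agreement between the corrected
predictions and the reference labels, the quantity monitored during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Event, EventList, LabelSeries, Recording

__all__ = [
    "PostprocessConfig",
    "EventCorrector",
    "binarize",
    "labels_to_events",
    "events_to_labels",
    "drop_short",
    "merge_close",
    "snap_end_to_final_extremum",
    "correct",
    "corrected_accuracy",
]


@dataclass(frozen=True)
class PostprocessConfig:
    binarize_threshold: float = 0.5
    min_duration_s: float = 0.1
    merge_gap_s: float = 0.2
    extremum_neighborhood: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.min_duration_s <= 0 or self.merge_gap_s <= 0:
            raise ValueError("durations must be > 0")
        if self.extremum_neighborhood < 1:
            raise ValueError("extremum neighborhood must be >= 1")


def binarize(probabilities: np.ndarray, threshold: float = 0.5, rate_hz: float = 125.0) -> LabelSeries:
    """Label = 1 iff probability >= threshold (ties label positive)."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return LabelSeries((p >= threshold).astype(np.uint8), rate_hz)


def labels_to_events(labels: LabelSeries, total_window_s: float | None = None) -> EventList:
    """Maximal runs of ones become half-open events."""
    lab = labels.labels
    if total_window_s is None:
        total_window_s = len(lab) / labels.sampling_rate_hz
    padded = np.concatenate([[0], lab, [0]]).astype(np.int8)
    d = np.diff(padded)
    onsets = np.where(d == 1)[0]
    offsets = np.where(d == -1)[0]
    evs = [Event(int(a), int(b)) for a, b in zip(onsets, offsets)]
    return EventList(evs, labels.sampling_rate_hz, total_window_s)


def events_to_labels(events: EventList, length: int) -> LabelSeries:
    lab = np.zeros(length, dtype=np.uint8)
    for e in events:
        lab[e.onset : e.offset] = 1
    return LabelSeries(lab, events.sampling_rate_hz)


def drop_short(events: EventList, min_duration_s: float = 0.1) -> EventList:
    """Remove events strictly shorter than ``min_duration_s``."""
    keep = [e for e in events if e.duration_s(events.sampling_rate_hz) >= min_duration_s]
    return EventList(keep, events.sampling_rate_hz, events.total_window_s)


def merge_close(events: EventList, merge_gap_s: float = 0.2) -> EventList:
    """Fuse consecutive events whose gap is strictly below ``merge_gap_s``.

    Applied transitively: a chain of close events collapses to one spanning
    event.
    """
    gap_n = merge_gap_s * events.sampling_rate_hz
    merged: list[Event] = []
    for e in events:
        if merged and (e.onset - merged[-1].offset) < gap_n:
            merged[-1] = Event(merged[-1].onset, e.offset)
        else:
            merged.append(e)
    return EventList(merged, events.sampling_rate_hz, events.total_window_s)


def _last_interior_extremum(x: np.ndarray) -> int | None:
    """Index (into ``x``) of the last strict local extremum, or None."""
    if x.size < 3:
        return None
    interior = x[1:-1]
    is_min = (interior < x[:-2]) & (interior < x[2:])
    is_max = (interior > x[:-2]) & (interior > x[2:])
    idx = np.where(is_min | is_max)[0]
    if idx.size == 0:
        return None
    return int(idx[-1]) + 1


def snap_end_to_final_extremum(events: EventList, rec: Recording) -> EventList:
    """Move each event's offset to just past its final interior extremum.

    Events without an interior strict extremum (e.g. monotone signal) are
    left unchanged; onsets never move.
    """
    if abs(rec.sampling_rate_hz - events.sampling_rate_hz) > 1e-9:
        raise ValueError("recording rate differs from event rate")
    out: list[Event] = []
    for e in events:
        seg = rec.samples[e.onset : e.offset]
        k = _last_interior_extremum(seg)
        if k is None:
            out.append(e)
        else:
            out.append(Event(e.onset, e.onset + k + 1))
    return EventList(out, events.sampling_rate_hz, events.total_window_s)


def correct(
    probabilities: np.ndarray,
    rec: Recording,
    config: PostprocessConfig = PostprocessConfig(),
) -> EventList:
    """Full correction pipeline: threshold, drop, merge, snap.

    ``rec`` must be the label-rate (downsampled) recording the probabilities
    were predicted on; it supplies the waveform for endpoint snapping.
    """
    if len(probabilities) != rec.n_samples:
        raise ValueError("probability series not aligned to recording")
    labels = binarize(probabilities, config.binarize_threshold, rec.sampling_rate_hz)
    events = labels_to_events(labels, rec.duration_s)
    events = drop_short(events, config.min_duration_s)
    events = merge_close(events, config.merge_gap_s)
    return snap_end_to_final_extremum(events, rec)


def corrected_accuracy(predicted: EventList, truth: LabelSeries) -> float:
    """Per-sample agreement between corrected predictions and reference labels."""
    n = len(truth)
    if abs(predicted.sampling_rate_hz - truth.sampling_rate_hz) > 1e-9:
        raise ValueError("label rates differ")
    if int(round(predicted.total_window_s * predicted.sampling_rate_hz)) != n:
        raise ValueError("label lengths differ")
    pred = events_to_labels(predicted, n)
    return float(np.mean(pred.labels == truth.labels))


class EventCorrector(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping :func:`correct`.

    ``transform`` expects an iterable of ``(probabilities, recording)`` pairs
    and returns the corrected :class:`EventList` per pair.
    """

    def __init__(
        self,
        binarize_threshold: float = 0.5,
        min_duration_s: float = 0.1,
        merge_gap_s: float = 0.2,
    ):
        self.binarize_threshold = binarize_threshold
        self.min_duration_s = min_duration_s
        self.merge_gap_s = merge_gap_s

    def fit(self, X=None, y=None):  # noqa: D102 - nothing to fit
        return self

    @property
    def config_(self) -> PostprocessConfig:
        return PostprocessConfig(self.binarize_threshold, self.min_duration_s, self.merge_gap_s)

    def transform(self, X) -> list[EventList]:
        return [correct(p, rec, self.config_) for p, rec in X]
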