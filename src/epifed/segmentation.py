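"""Multi-timescale sliding-window segmentation, balanced training-sample
generation, and ROC-based bi-timescale selection.

Windows are half-open ``[start, start + scale)`` in seconds. A window's label
is the annotation state covering at least half of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .evaluation import roc_auc
from .spikes import encode_segment
from .types import EEGRecording

TIMESCALES_S = (1.0, 2.0, 4.0, 8.0)


@dataclass
class Segment:
    window: np.ndarray  # (scale_s * fs, n_channels)
    label: Optional[str]
    subject_id: str
    start_s: float
    fs: float


@dataclass
class SegmentSet:
    scale_s: float
    segments: list[Segment] = field(default_factory=list)
    stride_s: dict[str, float] = field(default_factory=dict)

    def labels(self) -> list[Optional[str]]:
        return [s.label for s in self.segments]

    def by_label(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class BiTimescaleChoice:
    scales: tuple[float, float]
    auc_by_scale: dict[float, float]


def segment(recording: EEGRecording, scale_s: float, stride_s: float) -> SegmentSet:
    """Slide a ``scale_s`` window with stride ``stride_s`` over the recording.

    Returns every window fully inside the recording; a recording shorter than
    one window yields an empty set.
    """
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    n_win = int(round(scale_s * recording.fs))
    if abs(scale_s * recording.fs - n_win) > 1e-6:
        raise ValueError("scale_s * fs must be integral")
    out = SegmentSet(scale_s=scale_s, stride_s={"all": stride_s})
    dur = recording.duration_s
    k = 0
    while True:
        start_s = k * stride_s
        if start_s + scale_s > dur + 1e-9:
            break
        i0 = int(round(start_s * recording.fs))
        window = recording.signal[i0 : i0 + n_win]
        if window.shape[0] < n_win:
            break
        out.segments.append(
            Segment(
                window=window,
                label=recording.state_at(start_s, start_s + scale_s),
                subject_id=recording.subject_id,
                start_s=start_s,
                fs=recording.fs,
            )
        )
        k += 1
    return out


def _interval_windows(
    recording: EEGRecording, start_s: float, end_s: float, scale_s: float, stride_s: float
) -> list[Segment]:
    """Windows fully inside one annotation interval at the given stride."""
    n_win = int(round(scale_s * recording.fs))
    segs: list[Segment] = []
    k = 0
    while True:
        ws = start_s + k * stride_s
        if ws + scale_s > end_s + 1e-9:
            break
        i0 = int(round(ws * recording.fs))
        win = recording.signal[i0 : i0 + n_win]
        if win.shape[0] < n_win:
            break
        segs.append(
            Segment(win, recording.state_at(ws, ws + scale_s), recording.subject_id, ws, recording.fs)
        )
        k += 1
    return segs


def _count_windows(lengths: Sequence[float], scale_s: float, stride_s: float) -> int:
    total = 0
    for L in lengths:
        if L + 1e-9 >= scale_s:
            total += int(np.floor((L - scale_s) / stride_s + 1e-9)) + 1
    return total


def generate_training_samples(
    recordings: Iterable[EEGRecording],
    scale_s: float,
    classes: tuple[str, str] = ("preictal", "interictal"),
) -> SegmentSet:
    """Exactly class-balanced segments at one timescale.

    The majority class is segmented without overlap (stride = scale); the
    minority class uses the largest stride producing at least as many windows
    (overlapping sliding window), then is truncated to the majority count.
    """
    recordings = list(recordings)
    intervals: dict[str, list[tuple[EEGRecording, float, float]]] = {c: [] for c in classes}
    for rec in recordings:
        for a in rec.annotations:
            if a.state in intervals:
                intervals[a.state].append((rec, a.start_s, a.end_s))
    for c in classes:
        if not intervals[c]:
            raise ValueError(f"class {c!r} absent from the provided recordings")

    loop_segs = {
        c: [
            seg
            for rec, s, e in intervals[c]
            for seg in _interval_windows(rec, s, e, scale_s, scale_s)
        ]
        for c in classes
    }
    majority = max(classes, key=lambda c: len(loop_segs[c]))
    minority = classes[0] if majority == classes[1] else classes[1]
    n_target = len(loop_segs[majority])
    if n_target == 0:
        raise ValueError("no complete windows at this timescale")

    lengths_min = [e - s for _, s, e in intervals[minority]]

    def n_at(stride: float) -> int:
        return _count_windows(lengths_min, scale_s, stride)

    # largest stride with count >= n_target (count is nonincreasing in stride)
    if n_at(scale_s) >= n_target:
        stride_min = scale_s
    else:
        lo, hi = 1e-6, scale_s
        if n_at(lo) < n_target:
            raise ValueError(
                f"minority class {minority!r} too short to balance "
                f"{n_target} majority windows at scale {scale_s}s"
            )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if n_at(mid) >= n_target:
                lo = mid
            else:
                hi = mid
        stride_min = lo

    out = SegmentSet(scale_s=scale_s, stride_s={majority: scale_s, minority: stride_min})
    out.segments.extend(loop_segs[majority])
    minority_segs: list[Segment] = []
    for _ in range(8):  # guard against float drift between count and loop
        minority_segs = []
        for rec, s, e in intervals[minority]:
            minority_segs.extend(_interval_windows(rec, s, e, scale_s, stride_min))
        if len(minority_segs) >= n_target:
            break
        stride_min *= 1.0 - 1e-6
        out.stride_s[minority] = stride_min
    out.segments.extend(minority_segs[:n_target])

    n_maj = sum(1 for sg in out.segments if sg.label == majority)
    n_min = sum(1 for sg in out.segments if sg.label == minority)
    assert n_maj == n_min == n_target, "balancing failed"
    return out


def probe_features(seg: Segment, kappa: float = 2.0, mode: str = "crossing") -> np.ndarray:
    """Cheap per-segment features for the timescale probe: mean spike rate
    (runs per second), spike duration, log variance, and the seizure
    probability. Defaults match the pipeline's encoder settings."""
    rep = encode_segment(seg.window, kappa=kappa, mode=mode)
    dur = seg.window.shape[0] / seg.fs
    return np.array(
        [
            rep.spike_count.mean() / dur,
            rep.spike_duration.mean(),
            np.log(seg.window.var() + 1e-12),
            rep.probability,
        ]
    )


def default_probe_evaluator(
    segments: list[Segment],
    labels: np.ndarray,
    validation_split: float,
    seed: int,
) -> float:
    """Validation ROC AUC of a logistic probe on spike-rate/variance features."""
    X = np.vstack([probe_features(s) for s in segments])
    y = np.asarray(labels)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=validation_split, random_state=seed, stratify=y
    )
    if len(np.unique(y_va)) < 2:
        raise ValueError("degenerate validation split: one class only")
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit((X_tr - mu) / sd, y_tr)
    scores = clf.predict_proba((X_va - mu) / sd)[:, 1]
    return roc_auc(scores, y_va)[0]


def select_bi_timescale(
    train_sets: dict[float, SegmentSet],
    probe_evaluator: Optional[Callable[[float, SegmentSet], float]] = None,
    validation_split: float = 0.2,
    seed: int = 42,
    positive_label: str = "preictal",
) -> BiTimescaleChoice:
    """Pick the two timescales with the highest validation AUC.

    ``probe_evaluator(scale, segment_set) -> auc`` may be injected (e.g. a
    stub in tests); the default fits a logistic probe per scale. Ties prefer
    the shorter scale.
    """
    aucs: dict[float, float] = {}
    for scale in sorted(train_sets):
        sset = train_sets[scale]
        if probe_evaluator is not None:
            aucs[scale] = float(probe_evaluator(scale, sset))
            continue
        labeled = [s for s in sset.segments if s.label is not None]
        y = np.array([1 if s.label == positive_label else 0 for s in labeled])
        per_class = min((y == 1).sum(), (y == 0).sum())
        if per_class < 20:
            raise ValueError(
                f"scale {scale}: need >= 20 segments per class, got {per_class}"
            )
        aucs[scale] = default_probe_evaluator(labeled, y, validation_split, seed)
    ranked = sorted(aucs, key=lambda s: (-aucs[s], s))
    chosen = tuple(sorted(ranked[:2]))
    return BiTimescaleChoice(scales=chosen, auc_by_scale=aucs)
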