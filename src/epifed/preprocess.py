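"""Filtering, per-window normalization, and correlative channel selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, signal

__all__ = [
    "butterworth_bandpass",
    "normalize_per_window",
    "screening_design",
    "select_channels",
    "ChannelSelectionResult",
    "preprocess_recording",
]

# First row of the 12-run Plackett-Burman design (cyclic construction);
# handles up to 11 two-level factors.
_PB12_ROW = np.array([1, -1, 1, -1, -1, -1, 1, 1, 1, -1, 1])


def butterworth_bandpass(
    x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass, channelwise.

    Zero-phase application avoids phase distortion of the brief transients the
    spiking encoder keys on. Band edges must lie strictly inside (0, fs/2).
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low_hz}, high={high_hz}, fs={fs}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    out = signal.sosfiltfilt(sos, x, axis=0)
    return out[:, 0] if squeeze else out


def normalize_per_window(
    x: np.ndarray, fs: float, window_s: float = 1.0, eps: float = 1e-12
) -> np.ndarray:
    """Z-score each non-overlapping ``window_s`` block of each channel.

    Blocks with SD below ``eps`` (flat signal) are zeroed. A trailing partial
    block is normalized the same way over its own samples.
    """
    n = int(round(window_s * fs))
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    out = np.empty_like(x)
    for start in range(0, x.shape[0], n):
        block = x[start : start + n]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        z = np.where(sd > eps, (block - mu) / np.where(sd > eps, sd, 1.0), 0.0)
        out[start : start + n] = z
    return out[:, 0] if squeeze else out


def screening_design(n_factors: int) -> np.ndarray:
    """Two-level screening design matrix (rows = runs, entries +/-1).

    Uses the 12-run Plackett-Burman design for up to 11 factors, otherwise the
    smallest Sylvester Hadamard matrix with enough columns (fractional
    two-level design in the DoE/Taguchi minimum-experiments spirit).
    """
    if n_factors < 1:
        raise ValueError("need at least one factor")
    if n_factors <= 11:
        rows = [np.roll(_PB12_ROW, i) for i in range(11)]
        design = np.vstack(rows + [-np.ones(11, dtype=int)])
        return design[:, :n_factors].astype(int)
    size = 4
    while size - 1 < n_factors:
        size *= 2
    h = linalg.hadamard(size)
    return h[:, 1 : n_factors + 1].astype(int)


@dataclass
class ChannelSelectionResult:
    kept_channels: list[int]
    accuracy_trace: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    main_effects: dict[int, float] = field(default_factory=dict)


def select_channels(
    n_channels: int,
    evaluator: Callable[[Sequence[int]], float],
    tolerance: float = 0.0,
) -> ChannelSelectionResult:
    """Two-phase correlative channel selection.

    Phase 1 (screening): evaluate the subsets given by a two-level fractional
    design (channel in/out per run) and rank channels by their main effect on
    accuracy. Phase 2 (wrapper): backward elimination in ascending main-effect
    order; a channel is dropped iff accuracy does not decrease by more than
    ``tolerance``; iteration stops when no further removal survives. Never
    returns an empty set; removal ties favour keeping the lowest index.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    trace: list[tuple[tuple[int, ...], float]] = []

    def _eval(subset: Sequence[int]) -> float:
        key = tuple(sorted(subset))
        try:
            acc = float(evaluator(list(key)))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed on channel set {key}") from exc
        trace.append((key, acc))
        return acc

    if n_channels == 1:
        acc = _eval([0])
        return ChannelSelectionResult([0], trace, {0: 0.0})

    design = screening_design(n_channels)
    accs = np.empty(design.shape[0])
    for r, row in enumerate(design):
        subset = [i for i in range(n_channels) if row[i] > 0]
        if not subset:
            subset = list(range(n_channels))
        accs[r] = _eval(subset)
    effects = {
        q: float(accs[design[:, q] > 0].mean() - accs[design[:, q] < 0].mean())
        for q in range(n_channels)
    }

    # ascending effect; among ties try removing the HIGHEST index first so the
    # lowest-indexed channel is the one retained at full reduction
    kept = list(range(n_channels))
    current = _eval(kept)
    improved = True
    while improved and len(kept) > 1:
        improved = False
        order = sorted(kept, key=lambda q: (effects[q], -q))
        for q in order:
            if len(kept) == 1:
                break
            candidate = [c for c in kept if c != q]
            acc = _eval(candidate)
            if acc >= current - tolerance:
                kept = candidate
                current = acc
                improved = True
    return ChannelSelectionResult(sorted(kept), trace, effects)


def preprocess_recording(recording, low_hz=0.5, high_hz=40.0, order=2, window_s=1.0):
    """Bandpass + per-window normalization applied to an EEGRecording copy."""
    from .types import EEGRecording

    filtered = butterworth_bandpass(recording.signal, recording.fs, low_hz, high_hz, order)
    normed = normalize_per_window(filtered, recording.fs, window_s)
    return EEGRecording(
        subject_id=recording.subject_id,
        signal=normed,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        annotations=list(recording.annotations),
    )
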