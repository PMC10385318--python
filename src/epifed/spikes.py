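"""Spiking encoder: binary spike sequences, per-channel spike statistics,
the seizure-indicator rule, and logical-AND fine tuning.

A "spike" is a maximal run of consecutive 1s in the encoded matrix; the
per-channel spike count is the number of such runs and the spike duration is
their mean length in samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeRepresentation",
    "compute_thresholds",
    "encode_spikes",
    "spike_run_stats",
    "seizure_indicator",
    "fine_tune",
    "surrogate_spike_gradient",
    "encode_segment",
]


def compute_thresholds(segment: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (up, down) thresholds ``mu +/- kappa*sigma``.

    The encoder compares samples against the mean point ``(up + down)/2 = mu``.
    ``sigma`` is the population SD over the segment; a constant channel yields
    ``up == down == mu``.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment is empty")
    mu = segment.mean(axis=0)
    sd = segment.std(axis=0)
    return mu + kappa * sd, mu - kappa * sd


def encode_spikes(
    segment: np.ndarray,
    thresholds: tuple[np.ndarray, np.ndarray],
    mode: str = "mean",
    offset: float = 0.0,
) -> np.ndarray:
    """Binary encoding of a segment.

    mode="mean" (default, literal rule): ``E[t, q] = 1`` iff the sample is >=
    the mean point of the up/down thresholds (equality encodes 1 — the
    "otherwise" branch).  mode="crossing": spike iff the sample crosses either
    threshold, i.e. ``|x - mu| >= kappa*sigma``.

    ``offset`` shifts the comparison point by ``offset * half_width`` (half
    the up-down gap); it is the trainable quantity differentiated through
    :func:`surrogate_spike_gradient` during GCNN training.
    """
    up, down = thresholds
    segment = np.asarray(segment, dtype=float)
    mu = (np.asarray(up) + np.asarray(down)) / 2.0
    half = (np.asarray(up) - np.asarray(down)) / 2.0
    if mode == "mean":
        return (segment >= mu + offset * half).astype(np.int8)
    if mode == "crossing":
        return (np.abs(segment - mu) >= (1.0 + offset) * half).astype(np.int8)
    raise ValueError(f"unknown encoder mode {mode!r}")


def spike_run_stats(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(spike_count, mean_spike_duration) per channel via run-length analysis.

    spike_count = number of maximal runs of 1s in each column;
    mean duration = mean run length in samples (0.0 where no spikes).
    """
    e = np.asarray(encoded)
    if e.ndim != 2:
        raise ValueError("encoded must be 2-D")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("encoded matrix must be binary")
    padded = np.vstack([np.zeros((1, e.shape[1]), dtype=e.dtype), e])
    starts = (np.diff(padded, axis=0) == 1).sum(axis=0).astype(float)
    ones = e.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dur = np.where(starts > 0, ones / np.maximum(starts, 1), 0.0)
    return starts, dur


def seizure_indicator(
    spike_count: np.ndarray, spike_duration: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-channel High/Low indicator and segment seizure probability.

    Channel q is High iff its spike count exceeds the cross-channel mean AND
    its mean spike duration is below the cross-channel average duration (many
    short spikes). Probability = fraction of High channels.
    """
    sp = np.asarray(spike_count, dtype=float)
    dsp = np.asarray(spike_duration, dtype=float)
    if sp.ndim != 1 or sp.shape != dsp.shape or sp.size < 1:
        raise ValueError("spike_count and spike_duration must be equal-length 1-D")
    high = (sp.mean() < sp) & (dsp.mean() > dsp)
    return high.astype(np.int8), float(high.mean())


def fine_tune(encoded: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Logical AND of the spike matrix with the per-channel indicator."""
    e = np.asarray(encoded)
    r = np.asarray(indicator)
    if not np.isin(e, (0, 1)).all() or not np.isin(r, (0, 1)).all():
        raise ValueError("fine_tune requires binary inputs")
    return (e & r[np.newaxis, :]).astype(np.int8)


def surrogate_spike_gradient(x: np.ndarray, beta_slope: float = 10.0) -> np.ndarray:
    """Fast-sigmoid surrogate derivative ``beta / (1 + beta*|x|)**2``.

    Stands in for the derivative of the spike threshold step during
    backpropagation; even in ``x``, peaking at ``x = 0`` with value
    ``beta_slope``.
    """
    x = np.asarray(x, dtype=float)
    return beta_slope / (1.0 + beta_slope * np.abs(x)) ** 2


@dataclass
class SpikeRepresentation:
    """Spike view of one segment: encoding, statistics, indicator, fine-tuned
    matrix, and the per-node gate used by the graph model."""

    encoded: np.ndarray
    spike_count: np.ndarray
    spike_duration: np.ndarray
    indicator: np.ndarray
    probability: float
    fine_tuned: np.ndarray

    @property
    def node_gate(self) -> np.ndarray:
        """Fraction of 1s per channel of the fine-tuned matrix, in [0, 1]."""
        return self.fine_tuned.mean(axis=0)


def encode_segment(
    segment: np.ndarray,
    kappa: float = 1.0,
    mode: str = "mean",
    offset: float = 0.0,
) -> SpikeRepresentation:
    """Full spiking-encoder pass over one segment matrix."""
    thr = compute_thresholds(segment, kappa)
    encoded = encode_spikes(segment, thr, mode=mode, offset=offset)
    count, dur = spike_run_stats(encoded)
    indicator, prob = seizure_indicator(count, dur)
    tuned = fine_tune(encoded, indicator)
    return SpikeRepresentation(
        encoded=encoded,
        spike_count=count,
        spike_duration=dur,
        indicator=indicator,
        probability=prob,
        fine_tuned=tuned,
    )
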