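"""Core domain types shared across the pipeline.

All time conventions are half-open ``[start_s, end_s)`` in seconds, 0-based:
the sample with index ``i`` covers the interval ``[i/fs, (i+1)/fs)``, so a
sample falling exactly on an annotation's ``end_s`` belongs to the next
interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STATES = ("preictal", "interictal", "ictal")

#: Positive class for every binary decision in the pipeline.
POSITIVE_STATE = "preictal"

RISK_CLASSES = ("Pk1", "Pk2", "Pk3")
HRV_FEATURES = ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")


@dataclass
class Annotation:
    state: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"annotation interval must satisfy 0 <= start < end, got "
                f"[{self.start_s}, {self.end_s})"
            )


@dataclass
class EEGRecording:
    """One subject's multichannel signal plus sampling rate and state labels."""

    subject_id: str
    signal: np.ndarray  # (n_samples, n_channels), microvolts
    fs: float
    channel_names: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (n_samples, n_channels) matrix")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[1]:
            raise ValueError(
                f"channel count mismatch: {self.signal.shape[1]} signal columns "
                f"but {len(self.channel_names)} channel names"
            )
        if self.signal.shape[1] < 1:
            raise ValueError("at least one channel required")
        dur = self.duration_s
        ann = sorted(self.annotations, key=lambda a: a.start_s)
        for a in ann:
            if a.end_s > dur + 1e-9:
                raise ValueError(
                    f"annotation [{a.start_s}, {a.end_s}) exceeds recording "
                    f"duration {dur:.6g} s"
                )
        for prev, nxt in zip(ann, ann[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"overlapping annotations: [{prev.start_s}, {prev.end_s}) "
                    f"and [{nxt.start_s}, {nxt.end_s})"
                )
        self.annotations = ann

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def state_at(self, start_s: float, end_s: float) -> Optional[str]:
        """Label of the annotation covering >= 50% of ``[start_s, end_s)``."""
        need = 0.5 * (end_s - start_s)
        for a in self.annotations:
            overlap = min(a.end_s, end_s) - max(a.start_s, start_s)
            if overlap >= need - 1e-12 and overlap > 0:
                return a.state
        return None


@dataclass
class HRVSeries:
    """Per-subject HRV feature time series (times strictly increasing)."""

    subject_id: str
    times: np.ndarray  # seconds
    features: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        missing = [k for k in HRV_FEATURES if k not in self.features]
        if missing:
            raise ValueError(f"missing HRV features: {missing}")
        for k in HRV_FEATURES:
            v = np.asarray(self.features[k], dtype=float)
            if v.shape != self.times.shape:
                raise ValueError(f"feature {k} length differs from times")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"feature {k} contains non-finite values")
            self.features[k] = v

    @property
    def n_points(self) -> int:
        return self.times.size


@dataclass
class ClinicalRecord:
    subject_id: str
    age: float
    gender: str
    genetic: bool
    metabolic: bool
    seizure_event_count: int

    def __post_init__(self) -> None:
        if self.seizure_event_count < 0:
            raise ValueError("seizure_event_count must be >= 0")


@dataclass
class RunConfig:
    """Every tunable in the pipeline, with documented defaults.

    Serializes losslessly to/from JSON via :meth:`to_json` / :meth:`from_json`.
    """

    # preprocessing
    band_low_hz: float = 0.5
    band_high_hz: float = 40.0
    filter_order: int = 2
    norm_window_s: float = 1.0
    channel_drop_tolerance: float = 0.0  # wrapper-elimination accuracy tolerance

    # segmentation
    timescales_s: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    validation_split: float = 0.2

    # spiking encoder
    kappa: float = 2.0  # threshold half-width in channel SDs
    encoder_mode: str = "crossing"  # "mean" (literal rule) or "crossing"
    surrogate_slope: float = 10.0

    # graph / GCNN (hidden units [16, 16], Adam lr 0.01, dropout 0.2,
    # batch 128, <= 10 epochs)
    corr_threshold: float = 0.3
    hidden_units: tuple[int, ...] = (16, 16)
    dropout: float = 0.2
    learning_rate: float = 0.01
    batch_size: int = 128
    epochs: int = 10

    # federation
    w1: float = 1.0
    w2: float = 0.1
    rounds_max: int = 30
    patience: int = 3

    # risk staging
    delta_small: float = 0.05
    delta_large: float = 0.25

    # PSO
    pso_swarm: int = 30
    pso_iterations: int = 50
    pso_inertia: float = 0.7
    pso_cognitive: float = 1.5
    pso_social: float = 1.5

    seed: int = 42

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


@dataclass
class RiskAssessment:
    """Outcome of fine-grained personalization for one subject."""

    subject_id: str
    risk_class: str  # Pk1 (High) / Pk2 (Medium) / Pk3 (Low)
    pattern: str  # alpha / beta / gamma / none
    preictal_start_s: Optional[float] = None
    alarm_onset_s: Optional[float] = None
    sph_s: Optional[float] = None
    anfis_output: Optional[float] = None

    def __post_init__(self) -> None:
        if self.risk_class not in RISK_CLASSES:
            raise ValueError(f"risk_class must be one of {RISK_CLASSES}")
        if self.sph_s is not None and self.sph_s < 0:
            raise ValueError("sph_s must be >= 0 when defined")
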