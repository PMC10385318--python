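"""Seeded multi-hospital synthetic EEG / HRV / clinical fixtures.

EEG: band-limited colored background noise with brief damped-sinusoid
transients overlaid. Preictal intervals carry frequent short high-frequency
bursts; interictal intervals carry rare long low-frequency ones — the
many-short-spikes structure the seizure-indicator rule assumes. Each
transient lands on a random subset of channels so the indicator's
cross-channel comparison has contrast.

HRV: one alpha/beta/gamma transition pattern planted per series, preceded by
a small guard dip (a drop slightly larger than delta_small) so the planted
pattern is the earliest match under the pattern matcher's scan order;
elsewhere relative fluctuations stay below delta_small.

Clinical: drawn from the per-class value ranges (low: no genetic/metabolic
flags, 0 < events < 3; medium: flags set, 3 <= events <= 5; high: flags set,
events > 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .types import Annotation, ClinicalRecord, EEGRecording, HRVSeries, HRV_FEATURES

__all__ = [
    "SyntheticSpec",
    "generate_eeg_dataset",
    "generate_hrv_series",
    "generate_clinical_record",
    "HRV_BASELINES",
]

#: Feature baselines for HRV synthesis (medium-class midpoints).
HRV_BASELINES = {
    "Lmax": 242.0,
    "SDNN": 125.2,
    "LF_HF": 1.6,
    "MeanHR": 76.5,
    "pNN50": 5.3,
}

_PATTERN_LEN = {"Pk1": 2, "Pk2": 3, "Pk3": 4}  # symbols consumed by the plant


@dataclass
class SyntheticSpec:
    """Defaults: 3 hospitals differing in channel count and sampling rate,
    2 subjects each, 2 minutes per state, strong planted spike-rate
    separation (2.0 /s short preictal bursts vs 0.2 /s long interictal
    ones)."""

    n_hospitals: int = 3
    n_subjects: tuple[int, ...] = (2, 2, 2)
    n_channels: tuple[int, ...] = (8, 10, 12)
    fs: tuple[float, ...] = (128.0, 128.0, 256.0)
    minutes_per_state: float = 2.0
    preictal_spike_rate: float = 2.0
    interictal_spike_rate: float = 0.2
    spike_amplitude_factor: float = 6.0
    noise_sd: float = 1.0
    preictal_burst_ms: tuple[float, float] = (40.0, 80.0)
    interictal_burst_ms: tuple[float, float] = (150.0, 300.0)
    preictal_burst_hz: tuple[float, float] = (20.0, 30.0)
    interictal_burst_hz: tuple[float, float] = (4.0, 8.0)
    background_cutoff_hz: float = 6.0
    hrv_risk_classes: tuple[str, ...] = ("Pk1", "Pk2", "Pk3")
    seed: int = 42

    def __post_init__(self) -> None:
        if self.preictal_spike_rate <= self.interictal_spike_rate:
            raise ValueError(
                "preictal_spike_rate must exceed interictal_spike_rate "
                "(planted separability)"
            )
        for n in (self.n_subjects, self.n_channels, self.fs):
            if len(n) != self.n_hospitals:
                raise ValueError("per-hospital tuples must have n_hospitals entries")
        highest = max(self.preictal_burst_hz[1], self.interictal_burst_hz[1],
                      self.background_cutoff_hz)
        for f in self.fs:
            if f < 2 * highest:
                raise ValueError(f"fs={f} below Nyquist for {highest} Hz content")


def _background(rng: np.random.Generator, n: int, m: int, fs: float,
                cutoff_hz: float, sd: float) -> np.ndarray:
    white = rng.standard_normal((n, m))
    sos = sp_signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sp_signal.sosfilt(sos, white, axis=0)
    x_sd = x.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def _add_bursts(
    clean: np.ndarray,
    rng: np.random.Generator,
    fs: float,
    start_s: float,
    end_s: float,
    rate_hz: float,
    dur_ms: tuple[float, float],
    freq_hz: tuple[float, float],
    amplitude: float,
) -> None:
    """Overlay damped-sinusoid transients in-place on ``clean``."""
    if amplitude <= 0 or rate_hz <= 0:
        return
    m = clean.shape[1]
    span = end_s - start_s
    n_events = rng.poisson(rate_hz * span)
    for _ in range(n_events):
        t0 = start_s + rng.uniform(0, span)
        d = rng.uniform(*dur_ms) / 1000.0
        f = rng.uniform(*freq_hz)
        i0 = int(round(t0 * fs))
        n_burst = max(int(round(d * fs)), 2)
        if i0 + n_burst > clean.shape[0]:
            continue
        tau = np.arange(n_burst) / fs
        wave = amplitude * np.sin(2 * np.pi * f * tau) * np.exp(-2.0 * tau / d)
        chans = np.flatnonzero(rng.random(m) < 0.7)
        if chans.size == 0:
            chans = np.array([rng.integers(m)])
        clean[i0 : i0 + n_burst, chans] += wave[:, None]


def generate_eeg_dataset(
    spec: SyntheticSpec, return_clean: bool = False
) -> list[list[EEGRecording]] | tuple[list[list[EEGRecording]], dict]:
    """Per-hospital lists of EEGRecordings with planted state structure.

    Each recording is one subject: an interictal interval followed by a
    preictal interval, annotated exactly. With ``return_clean=True`` also
    returns ``{(hospital, subject): transients-only matrix}`` for oracle
    tests that count transients on the noise-free component.
    """
    rng = np.random.default_rng(spec.seed)
    state_s = spec.minutes_per_state * 60.0
    hospitals: list[list[EEGRecording]] = []
    clean_out: dict[tuple[int, int], np.ndarray] = {}
    for h in range(spec.n_hospitals):
        fs = spec.fs[h]
        m = spec.n_channels[h]
        recs: list[EEGRecording] = []
        for s in range(spec.n_subjects[h]):
            n = int(round(2 * state_s * fs))
            bg = _background(rng, n, m, fs, spec.background_cutoff_hz, spec.noise_sd)
            clean = np.zeros_like(bg)
            amp = spec.spike_amplitude_factor * spec.noise_sd
            _add_bursts(clean, rng, fs, 0.0, state_s, spec.interictal_spike_rate,
                        spec.interictal_burst_ms, spec.interictal_burst_hz, amp)
            _add_bursts(clean, rng, fs, state_s, 2 * state_s, spec.preictal_spike_rate,
                        spec.preictal_burst_ms, spec.preictal_burst_hz, amp)
            rec = EEGRecording(
                subject_id=f"h{h}s{s}",
                signal=bg + clean,
                fs=fs,
                channel_names=[f"ch{q}" for q in range(m)],
                annotations=[
                    Annotation("interictal", 0.0, state_s),
                    Annotation("preictal", state_s, 2 * state_s),
                ],
            )
            recs.append(rec)
            if return_clean:
                clean_out[(h, s)] = clean
        hospitals.append(recs)
    return (hospitals, clean_out) if return_clean else hospitals


def generate_hrv_series(
    risk_class: str,
    n_points: int,
    delta_small: float = 0.05,
    delta_large: float = 0.25,
    seed: int = 42,
    subject_id: str = "synthetic",
    dt_s: float = 60.0,
) -> HRVSeries:
    """HRV series with exactly one planted transition pattern per feature.

    Pk1 plants alpha (moderate then much-greater jump), Pk2 beta (flat,
    moderate, much-greater), Pk3 gamma (flat, flat, moderate, much-greater).
    Background steps fluctuate within +/- 0.4*delta_small; the step right
    before the pattern is a guard dip (drop in (delta_small, 2*delta_small])
    so no earlier spurious match exists.
    """
    if risk_class not in _PATTERN_LEN:
        raise ValueError(f"risk_class must be one of {sorted(_PATTERN_LEN)}")
    if n_points < 5:
        raise ValueError("need n_points >= 5")
    rng = np.random.default_rng(seed)
    n_rel = n_points - 1
    pat_len = _PATTERN_LEN[risk_class]
    if n_rel < pat_len:
        raise ValueError("series too short for the requested pattern")

    features: dict[str, np.ndarray] = {}
    # same plant position for all features (pattern is a subject-level event);
    # p = 0 (no guard needed) only when the pattern fills the whole series
    p = 0 if n_rel == pat_len else int(rng.integers(1, n_rel - pat_len + 1))
    for name in HRV_FEATURES:
        rels = rng.uniform(-0.4 * delta_small, 0.4 * delta_small, size=n_rel)
        if p >= 1:
            rels[p - 1] = -rng.uniform(1.2, 1.9) * delta_small  # guard dip
        if risk_class == "Pk1":
            pattern = [
                rng.uniform(1.3 * delta_small, 0.95 * delta_large),
                rng.uniform(1.3, 1.8) * delta_large,
            ]
        elif risk_class == "Pk2":
            pattern = [
                rng.uniform(-0.4, 0.4) * delta_small,
                rng.uniform(1.3 * delta_small, 0.95 * delta_large),
                rng.uniform(1.3, 1.8) * delta_large,
            ]
        else:
            pattern = [
                rng.uniform(-0.4, 0.4) * delta_small,
                rng.uniform(-0.4, 0.4) * delta_small,
                rng.uniform(1.3 * delta_small, 0.95 * delta_large),
                rng.uniform(1.3, 1.8) * delta_large,
            ]
        rels[p : p + pat_len] = pattern
        # post-pattern: non-negative drift only (alpha's sustained clause)
        rels[p + pat_len :] = rng.uniform(0.0, 0.4 * delta_small,
                                          size=n_rel - p - pat_len)
        base = HRV_BASELINES[name]
        values = base * np.cumprod(np.concatenate([[1.0], 1.0 + rels]))
        features[name] = values
    return HRVSeries(
        subject_id=subject_id,
        times=np.arange(n_points, dtype=float) * dt_s,
        features=features,
    )


def generate_clinical_record(
    subject_id: str, risk_class: str, seed: int = 42
) -> ClinicalRecord:
    """Clinical record drawn from the per-class ranges."""
    rng = np.random.default_rng(seed)
    age = float(rng.uniform(5, 65))
    gender = str(rng.choice(["F", "M"]))
    if risk_class == "Pk3":
        genetic = metabolic = False
        events = int(rng.integers(1, 3))  # 0 < events < 3
    elif risk_class == "Pk2":
        genetic = metabolic = True
        events = int(rng.integers(3, 6))  # 3 <= events <= 5
    elif risk_class == "Pk1":
        genetic = metabolic = True
        events = int(rng.integers(6, 13))  # > 5
    else:
        raise ValueError(f"unknown risk class {risk_class!r}")
    return ClinicalRecord(
        subject_id=subject_id,
        age=age,
        gender=gender,
        genetic=genetic,
        metabolic=metabolic,
        seizure_event_count=events,
    )
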