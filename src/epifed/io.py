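"""Readers/writers for the plain-text interchange formats.

Formats
-------
* EEG: numeric CSV (rows = samples, columns = channels, optional header of
  channel names) plus a JSON sidecar ``{"fs": float, "channels": [...]}`` and
  an optional annotations CSV ``state,start_s,end_s``.
* HRV: CSV with columns ``time_s,Lmax,SDNN,LF_HF,MeanHR,pNN50``.
* Clinical: JSON object per subject.
* Predictions: CSV with one row per scored window.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import HRV_FEATURES, Annotation, ClinicalRecord, EEGRecording, HRVSeries

PREDICTION_COLUMNS = (
    "subject_id",
    "window_start_s",
    "window_end_s",
    "preictal_probability",
    "predicted_state",
)


def read_eeg(
    csv_path: str,
    sidecar_json_path: str,
    annotations_csv_path: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> EEGRecording:
    """Load one EEG recording from CSV + JSON sidecar (+ optional annotations)."""
    with open(sidecar_json_path) as fh:
        sidecar = json.load(fh)
    fs = float(sidecar["fs"])
    channels = list(sidecar["channels"])

    # Detect an optional header row: if the first line is non-numeric treat it
    # as channel names and require it to match the sidecar.
    with open(csv_path) as fh:
        first = fh.readline().strip()
    has_header = False
    for tok in first.split(","):
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(
        csv_path, header=0 if has_header else None, float_precision="round_trip"
    )
    try:
        signal = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {csv_path}: {exc}") from exc
    if signal.shape[1] != len(channels):
        raise ValueError(
            f"channel count mismatch: CSV has {signal.shape[1]} columns but "
            f"sidecar declares {len(channels)} channels"
        )

    annotations: list[Annotation] = []
    if annotations_csv_path is not None:
        ann = pd.read_csv(annotations_csv_path)
        for row in ann.itertuples(index=False):
            annotations.append(
                Annotation(str(row.state), float(row.start_s), float(row.end_s))
            )

    sid = subject_id or sidecar.get("subject_id") or os.path.splitext(
        os.path.basename(csv_path)
    )[0]
    return EEGRecording(
        subject_id=sid,
        signal=signal,
        fs=fs,
        channel_names=channels,
        annotations=annotations,
    )


def write_eeg(recording: EEGRecording, csv_path: str, sidecar_json_path: str,
              annotations_csv_path: Optional[str] = None) -> None:
    """Write a recording in the format :func:`read_eeg` consumes (lossless)."""
    # default float repr is the shortest round-trip representation
    pd.DataFrame(recording.signal, columns=recording.channel_names).to_csv(
        csv_path, index=False
    )
    with open(sidecar_json_path, "w") as fh:
        json.dump(
            {
                "fs": recording.fs,
                "channels": recording.channel_names,
                "subject_id": recording.subject_id,
            },
            fh,
            indent=2,
        )
    if annotations_csv_path is not None:
        pd.DataFrame(
            [(a.state, a.start_s, a.end_s) for a in recording.annotations],
            columns=["state", "start_s", "end_s"],
        ).to_csv(annotations_csv_path, index=False, float_format="%.17g")


def read_hrv(csv_path: str, subject_id: Optional[str] = None) -> HRVSeries:
    df = pd.read_csv(csv_path)
    missing = [c for c in ("time_s", *HRV_FEATURES) if c not in df.columns]
    if missing:
        raise ValueError(f"HRV CSV missing columns: {missing}")
    sid = subject_id or os.path.splitext(os.path.basename(csv_path))[0]
    return HRVSeries(
        subject_id=sid,
        times=df["time_s"].to_numpy(float),
        features={k: df[k].to_numpy(float) for k in HRV_FEATURES},
    )


def write_hrv(series: HRVSeries, csv_path: str) -> None:
    df = pd.DataFrame({"time_s": series.times})
    for k in HRV_FEATURES:
        df[k] = series.features[k]
    df.to_csv(csv_path, index=False, float_format="%.17g")


def read_clinical(json_path: str) -> ClinicalRecord:
    with open(json_path) as fh:
        d = json.load(fh)
    return ClinicalRecord(
        subject_id=str(d["subject_id"]),
        age=float(d["age"]),
        gender=str(d["gender"]),
        genetic=bool(d["genetic"]),
        metabolic=bool(d["metabolic"]),
        seizure_event_count=int(d["seizure_event_count"]),
    )


def write_clinical(record: ClinicalRecord, json_path: str) -> None:
    with open(json_path, "w") as fh:
        json.dump(
            {
                "subject_id": record.subject_id,
                "age": record.age,
                "gender": record.gender,
                "genetic": record.genetic,
                "metabolic": record.metabolic,
                "seizure_event_count": record.seizure_event_count,
            },
            fh,
            indent=2,
        )


def write_predictions(records: Iterable[Sequence], path: str) -> None:
    """Write per-window predictions as CSV.

    ``records`` rows are ``(subject_id, window_start_s, window_end_s,
    preictal_probability, predicted_state)``. Probabilities are validated to
    lie in [0, 1] and printed with >= 6 significant digits.
    """
    rows = list(records)
    for r in rows:
        p = float(r[3])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"preictal_probability {p} outside [0, 1]")
    pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS)).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_predictions(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction CSV missing columns: {missing}")
    return df
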