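"""End-to-end orchestration: preprocess -> bi-timescale segmentation ->
spiking-GCNN federation -> coarse prediction -> risk staging."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import ConfusionCounts, MetricReport, confusion_metrics, roc_auc
from .federated import FederationState, LocalClient, run_federation
from .graph import ChannelGraph, build_graph, predict_proba
from .preprocess import preprocess_recording
from .segmentation import SegmentSet, generate_training_samples, select_bi_timescale
from .types import EEGRecording, RunConfig


@dataclass
class ClientData:
    """Everything derived from one hospital's recordings before federation."""

    client_id: str
    fs: float
    graph: ChannelGraph
    scales: tuple[float, float]
    auc_by_scale: dict[float, float]
    windows_a: np.ndarray
    windows_b: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    start_s: list[float]


def make_bitimescale_pairs(
    set_a: SegmentSet,
    set_b: SegmentSet,
    positive_label: str = "preictal",
    negative_labels: Sequence[str] = ("interictal", "ictal"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[float]]:
    """Pair windows of the two chosen timescales by class-aligned order.

    Segments of each class are sorted by (subject, start time) within each
    scale and zipped; the shorter list wraps around so no window of the
    longer scale is discarded (the two views need not cover identical spans —
    they are two timescale views of the same class regime).
    """

    def grouped(sset: SegmentSet, label_pos: bool):
        segs = [
            s
            for s in sset.segments
            if s.label is not None
            and ((s.label == positive_label) == label_pos)
            and (label_pos or s.label in negative_labels)
        ]
        segs.sort(key=lambda s: (s.subject_id, s.start_s))
        return segs

    wa, wb, y, sids, starts = [], [], [], [], []
    for label_pos in (False, True):
        ga, gb = grouped(set_a, label_pos), grouped(set_b, label_pos)
        n = max(len(ga), len(gb))
        for i in range(n):
            sa, sb = ga[i % len(ga)], gb[i % len(gb)]
            wa.append(sa.window)
            wb.append(sb.window)
            y.append(1 if label_pos else 0)
            sids.append(sa.subject_id)
            starts.append(sa.start_s)
    return (
        np.stack(wa),
        np.stack(wb),
        np.array(y, dtype=int),
        sids,
        starts,
    )


def build_client(
    recordings: Sequence[EEGRecording],
    config: RunConfig,
    seed: int,
    client_id: str,
    scales: Optional[tuple[float, float]] = None,
) -> ClientData:
    """Preprocess one hospital's recordings and assemble paired training
    windows at its two best timescales."""
    pre = [
        preprocess_recording(
            r, config.band_low_hz, config.band_high_hz, config.filter_order,
            config.norm_window_s,
        )
        for r in recordings
    ]
    fs = pre[0].fs
    graph = build_graph(np.vstack([r.signal for r in pre]), config.corr_threshold)

    sets = {
        sc: generate_training_samples(pre, sc) for sc in config.timescales_s
    }
    if scales is None:
        choice = select_bi_timescale(
            sets, validation_split=config.validation_split, seed=seed
        )
        scales = choice.scales
        aucs = choice.auc_by_scale
    else:
        aucs = {}
    wa, wb, y, sids, starts = make_bitimescale_pairs(sets[scales[0]], sets[scales[1]])
    return ClientData(
        client_id=client_id,
        fs=fs,
        graph=graph,
        scales=scales,
        auc_by_scale=aucs,
        windows_a=wa,
        windows_b=wb,
        labels=y,
        subject_ids=sids,
        start_s=starts,
    )


@dataclass
class PipelineResult:
    federation: FederationState
    pooled: MetricReport
    per_client: dict[str, MetricReport] = field(default_factory=dict)
    pooled_counts: ConfusionCounts = field(default_factory=ConfusionCounts)
    scales: dict[str, tuple[float, float]] = field(default_factory=dict)
    test_outputs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _stratified_split(y: np.ndarray, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    tr, te = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(test_fraction * len(idx))))
        te.extend(idx[:k])
        tr.extend(idx[k:])
    return np.sort(np.array(tr)), np.sort(np.array(te))


def run_pipeline(
    hospital_recordings: Sequence[Sequence[EEGRecording]],
    config: RunConfig,
    seed: int = 42,
    test_fraction: float = 0.25,
) -> PipelineResult:
    """Full coarse-grained pipeline over simulated hospitals.

    Per hospital: preprocessing, balanced segmentation at the four
    timescales, bi-timescale selection, then federated training of the
    spiking-GCNN with divergence-regularized personalization. Each client's
    personalized model is scored on its own held-out windows; counts are
    pooled across clients.
    """
    clients_data = [
        build_client(recs, config, seed + 31 * h, client_id=f"hospital{h}")
        for h, recs in enumerate(hospital_recordings)
    ]

    fed_clients: list[LocalClient] = []
    splits = {}
    for h, cd in enumerate(clients_data):
        tr, te = _stratified_split(cd.labels, test_fraction, seed + 53 * h)
        splits[cd.client_id] = (tr, te)
        fed_clients.append(
            LocalClient(
                client_id=cd.client_id,
                windows_a=cd.windows_a[tr],
                windows_b=cd.windows_b[tr],
                labels=cd.labels[tr],
                fs=cd.fs,
                graph=cd.graph,
            )
        )

    state = run_federation(fed_clients, config, seed=seed)

    pooled = ConfusionCounts()
    per_client: dict[str, MetricReport] = {}
    test_outputs = {}
    for cd in clients_data:
        _, te = splits[cd.client_id]
        params = state.client_params.get(cd.client_id, state.global_params)
        probs = predict_proba(
            params, cd.graph, cd.windows_a[te], cd.windows_b[te], cd.fs
        )
        y = cd.labels[te]
        counts = ConfusionCounts.from_predictions(y, (probs >= 0.5).astype(int))
        pooled = pooled + counts
        report = confusion_metrics(counts)
        report.auc = roc_auc(probs, y)[0]
        per_client[cd.client_id] = report
        test_outputs[cd.client_id] = (probs, y)

    return PipelineResult(
        federation=state,
        pooled=confusion_metrics(pooled),
        per_client=per_client,
        pooled_counts=pooled,
        scales={cd.client_id: cd.scales for cd in clients_data},
        test_outputs=test_outputs,
    )
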