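"""Simulated cross-hospital federation.

FedAvg aggregation of GCNN parameters, the global prediction loss, the
Bernoulli-KL (Bregman/logistic) divergence used for coarse-grained
personalization, and the round loop with early stopping.

Privacy boundary: the only thing a client emits is a :class:`RoundPayload` —
parameter tensors and scalar counts/losses. Raw windows never leave the
client object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .graph import ChannelGraph, GCNNParams, batch_node_features, gcnn_forward, \
    init_params, predict_proba, train_local

__all__ = [
    "RoundPayload",
    "LocalClient",
    "FederationState",
    "fedavg_aggregate",
    "global_loss",
    "normalize_global_probability",
    "bregman_divergence",
    "personalized_loss",
    "early_stopping_trace",
    "run_federation",
]


# ---------------------------------------------------------------------------
# losses and probability algebra
# ---------------------------------------------------------------------------

def global_loss(
    subject_outputs: Sequence[tuple[np.ndarray, np.ndarray]],
    eps: Optional[float] = None,
) -> float:
    """Summed negative log-likelihood of the true class across subjects.

    ``subject_outputs`` is a sequence of (probabilities (n, C), labels (n,))
    pairs, one per subject. A zero probability for a true class raises unless
    ``eps`` is given, in which case probabilities are clamped to [eps, 1].
    """
    total = 0.0
    for probs, labels in subject_outputs:
        probs = np.asarray(probs, dtype=float)
        labels = np.asarray(labels).astype(int)
        p_true = probs[np.arange(len(labels)), labels]
        if eps is not None:
            p_true = np.clip(p_true, eps, 1.0)
        if np.any(p_true <= 0):
            raise ValueError("zero probability assigned to a true class")
        total -= float(np.log(p_true).sum())
    return total


def normalize_global_probability(
    p_g: np.ndarray | float, n_high: int, n_low: int, eps: float = 1e-6
):
    """Damp the global preictal probability on low-seizure clients.

    If the client saw more High than Low seizure-indicator segments the
    global probability passes through; otherwise it becomes
    ``clamp(-ln(P_G), eps, 1)`` — high global confidence is shrunk where the
    local spiking indicator disagrees. (The raw "log P_G" branch would be
    non-positive and could not re-enter the divergence as a probability.)
    """
    arr = np.asarray(p_g, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("P_G must lie strictly inside (0, 1)")
    if n_high > n_low:
        out = arr
    else:
        out = np.clip(-np.log(arr), eps, 1.0)
    return float(out) if np.isscalar(p_g) else out


def bregman_divergence(p_bar_g, p_p):
    """Bregman divergence of the logistic loss = KL(Bern(P_bar_G)||Bern(P_P)).

    Boundary convention ``0 * log 0 := 0``; an interior target against a
    degenerate ``P_P`` in {0, 1} is an error (infinite divergence).
    """
    scalar_in = np.isscalar(p_bar_g) and np.isscalar(p_p)
    a, q = np.broadcast_arrays(
        np.atleast_1d(np.asarray(p_bar_g, dtype=float)),
        np.atleast_1d(np.asarray(p_p, dtype=float)),
    )
    if np.any(a < 0) or np.any(a > 1) or np.any(q < 0) or np.any(q > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    interior = (a > 0) & (a < 1)
    if np.any(interior & ((q == 0) | (q == 1))):
        raise ValueError("P_P in {0, 1} with interior P_bar_G gives infinite divergence")

    def xlogxy(x, y):
        out = np.zeros(np.broadcast(x, y).shape)
        nz = x > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out[nz] = (x * np.log(x / np.where(nz, y, 1.0)))[nz]
        return out

    val = xlogxy(a, q) + xlogxy(1.0 - a, 1.0 - q)
    return float(val.reshape(-1)[0]) if scalar_in else val


def personalized_loss(l_pred: float, l_div: float, w1: float, w2: float) -> float:
    """Client loss: w1 * prediction loss + w2 * divergence loss."""
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    return w1 * l_pred + w2 * l_div


def early_stopping_trace(losses: Sequence[float], patience: int) -> tuple[int, int]:
    """(rounds_run, best_round_index) under patience-based early stopping.

    Walks the loss sequence; stops once the loss has failed to improve for
    ``patience`` consecutive rounds. Returns how many rounds were consumed and
    the index of the best (retained) round.
    """
    best = np.inf
    best_idx = -1
    since = 0
    for r, loss in enumerate(losses):
        if loss < best:
            best, best_idx, since = loss, r, 0
        else:
            since += 1
            if since >= patience:
                return r + 1, best_idx
    return len(losses), best_idx


# ---------------------------------------------------------------------------
# federation
# ---------------------------------------------------------------------------

@dataclass
class RoundPayload:
    """Everything a client is allowed to send to the server."""

    client_id: str
    params: GCNNParams
    t_s: int  # training sample count (FedAvg weight)
    n_high: int
    n_low: int
    val_loss: float
    val_count: int


@dataclass
class LocalClient:
    """One hospital: private paired windows + labels and a channel graph."""

    client_id: str
    windows_a: np.ndarray  # (N, Ta, m)
    windows_b: np.ndarray  # (N, Tb, m)
    labels: np.ndarray  # (N,) 0/1, 1 = preictal
    fs: float
    graph: ChannelGraph
    train_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    val_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_high: int = 0
    n_low: int = 0

    def prepare(self, validation_split: float, seed: int, kappa: float,
                mode: str, slope: float) -> None:
        y = np.asarray(self.labels).astype(int)
        n = len(y)
        if validation_split <= 0:
            self.train_idx = np.arange(n)
            self.val_idx = np.arange(n)
        else:
            rng = np.random.default_rng(seed)
            tr, va = [], []
            for cls in np.unique(y):
                idx = np.flatnonzero(y == cls)
                idx = idx[rng.permutation(len(idx))]
                k = max(1, int(round(validation_split * len(idx))))
                va.extend(idx[:k])
                tr.extend(idx[k:])
            self.train_idx = np.sort(np.array(tr))
            self.val_idx = np.sort(np.array(va))
        # seizure-indicator High/Low counts over local data (segment scored
        # High when at least half its channels carry the High indicator)
        _, gate_a, _ = batch_node_features(self.windows_a, self.fs, kappa, 0.0, mode, slope)
        probs = (gate_a > 0).mean(axis=1)
        self.n_high = int((probs >= 0.5).sum())
        self.n_low = int(len(probs) - self.n_high)

    def validation_loss(self, params: GCNNParams) -> tuple[float, int]:
        idx = self.val_idx
        p = predict_proba(params, self.graph, self.windows_a[idx], self.windows_b[idx], self.fs)
        y = np.asarray(self.labels).astype(int)[idx]
        p_true = np.where(y == 1, p, 1.0 - p)
        return float(-np.log(np.clip(p_true, 1e-12, None)).mean()), len(idx)


@dataclass
class FederationState:
    global_params: GCNNParams
    val_losses: list[float]
    rounds_run: int
    best_round: int
    converged: bool
    w1: float
    w2: float
    client_params: dict[str, GCNNParams]


def fedavg_aggregate(payloads: Sequence[RoundPayload]) -> GCNNParams:
    """Sample-count-weighted elementwise mean of client parameters."""
    if not payloads:
        raise ValueError("no clients to aggregate")
    ref = payloads[0].params
    keys = set(ref.weights)
    for pl in payloads[1:]:
        if set(pl.params.weights) != keys:
            raise ValueError("architecture mismatch between clients")
        for k in keys:
            if pl.params.weights[k].shape != ref.weights[k].shape:
                raise ValueError(f"architecture mismatch on tensor {k!r}")
    total = float(sum(pl.t_s for pl in payloads))
    if total <= 0:
        raise ValueError("total sample count must be positive")
    out = ref.copy()
    for k in keys:
        out.weights[k] = sum(
            (pl.t_s / total) * pl.params.weights[k] for pl in payloads
        )
    if all(pl.params.scaler_mean is not None for pl in payloads):
        out.scaler_mean = {
            b: sum((pl.t_s / total) * pl.params.scaler_mean[b] for pl in payloads)
            for b in ref.scaler_mean
        }
        out.scaler_scale = {
            b: sum((pl.t_s / total) * pl.params.scaler_scale[b] for pl in payloads)
            for b in ref.scaler_scale
        }
    return out


def run_federation(
    clients: Sequence[LocalClient],
    config,
    seed: int = 42,
    rounds_max: Optional[int] = None,
    patience: Optional[int] = None,
) -> FederationState:
    """FedAvg round loop with divergence-regularized local personalization.

    Per round each client trains locally from the current global parameters,
    minimizing ``w1 * CE + w2 * KL(P_bar_G || P_P)``; the server aggregates.
    Early stopping retains the global parameters of the best pooled-validation
    round. The personalized client parameters from that round are kept too.
    """
    if not clients:
        raise ValueError("need at least one client")
    rounds_max = config.rounds_max if rounds_max is None else rounds_max
    patience = config.patience if patience is None else patience

    global_params = init_params(
        hidden_units=tuple(config.hidden_units),
        dropout=config.dropout,
        seed=seed,
        kappa=config.kappa,
        encoder_mode=config.encoder_mode,
        surrogate_slope=config.surrogate_slope,
    )
    for c, client in enumerate(clients):
        client.prepare(config.validation_split, seed + 17 + c, config.kappa,
                       config.encoder_mode, config.surrogate_slope)

    val_losses: list[float] = []
    best = np.inf
    best_round = -1
    best_global = global_params
    best_locals: dict[str, GCNNParams] = {}
    since = 0
    rounds_run = 0
    converged = False

    for r in range(rounds_max):
        payloads: list[RoundPayload] = []
        for c, client in enumerate(clients):
            tr = client.train_idx
            use_div = config.w2 > 0.0

            def p_bar_transform(p, _c=client):
                return normalize_global_probability(
                    np.clip(p, 1e-6, 1 - 1e-6), _c.n_high, _c.n_low
                )

            local, _log = train_local(
                client.windows_a[tr],
                client.windows_b[tr],
                np.asarray(client.labels)[tr],
                client.fs,
                client.graph,
                config,
                seed=seed + 9973 * r + 131 * c,
                init=global_params,
                w1=config.w1,
                w2=config.w2 if use_div else 0.0,
                global_params=global_params if use_div else None,
                p_bar_transform=p_bar_transform if use_div else None,
            )
            vloss, vcount = client.validation_loss(local)
            payloads.append(
                RoundPayload(
                    client_id=client.client_id,
                    params=local,
                    t_s=len(tr),
                    n_high=client.n_high,
                    n_low=client.n_low,
                    val_loss=vloss,
                    val_count=vcount,
                )
            )
        new_global = fedavg_aggregate(payloads)
        pooled = sum(pl.val_loss * pl.val_count for pl in payloads) / sum(
            pl.val_count for pl in payloads
        )
        val_losses.append(pooled)
        rounds_run = r + 1
        if pooled < best:
            best, best_round, since = pooled, r, 0
            best_global = new_global
            best_locals = {pl.client_id: pl.params for pl in payloads}
        else:
            since += 1
            if since >= patience:
                converged = True
                break
        global_params = new_global

    return FederationState(
        global_params=best_global,
        val_losses=val_losses,
        rounds_run=rounds_run,
        best_round=best_round,
        converged=converged,
        w1=config.w1,
        w2=config.w2,
        client_params=best_locals,
    )
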