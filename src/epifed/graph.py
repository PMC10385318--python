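"""Channel graph construction and the spiking-GCNN.

The classifier is small enough (two graph-conv layers of 16 units plus a dense
head) that the forward/backward passes are written directly in NumPy. Per
timescale branch:

    Z1 = A_hat @ diag(gate) @ X  @ W1      H1 = act1(Z1)   (dropout)
    Z2 = A_hat @ diag(gate) @ H1 @ W2      H2 = act2(Z2)   (dropout)
    pooled = mean over nodes of H2

The two pooled vectors are concatenated, passed through a sigmoid dense head,
and softmaxed over {interictal/ictal, preictal}; class index 1 is preictal.

Node input features per channel are computed from the fine-tuned spike
representation: (spike rate /s, mean spike duration, spike density, log window
variance). The spike-density feature carries a surrogate gradient with respect
to a trainable threshold offset, which is the backpropagation path through the
discrete spiking encoder.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf

from .spikes import surrogate_spike_gradient

N_NODE_FEATURES = 4
CLASS_NAMES = ("interictal", "preictal")  # softmax order; index 1 = positive


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def renormalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric renormalization with self-loops: D~^(-1/2) (A+I) D~^(-1/2)."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]


@dataclass
class ChannelGraph:
    adjacency: np.ndarray
    a_hat: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def build_graph(training_signal: np.ndarray, corr_threshold: float = 0.3) -> ChannelGraph:
    """Thresholded |Pearson correlation| graph over channels.

    Edges with |r| >= threshold keep their correlation magnitude as weight;
    the diagonal is zero before renormalization. Constant channels correlate 0
    with everything.
    """
    x = np.asarray(training_signal, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 time samples and >= 2 channels")
    sd = x.std(axis=0)
    # relative tolerance so a numerically-constant channel counts as constant
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    xc = x - x.mean(axis=0)
    denom = np.outer(sd, sd)
    denom[denom == 0] = 1.0
    corr = (xc.T @ xc) / x.shape[0] / denom
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    a = np.abs(corr)
    a[a < corr_threshold] = 0.0
    np.fill_diagonal(a, 0.0)
    a = 0.5 * (a + a.T)  # guard symmetry against float asymmetry
    return ChannelGraph(adjacency=a, a_hat=renormalize_adjacency(a))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x):
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


_ACTIVATIONS = {
    "gelu": (_gelu, _gelu_grad),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "sigmoid": (
        lambda x: 1.0 / (1.0 + np.exp(-x)),
        lambda x: (s := 1.0 / (1.0 + np.exp(-x))) * (1.0 - s),
    ),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


def _softmax(u: np.ndarray) -> np.ndarray:
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class GCNNParams:
    """All trainable tensors plus architecture metadata.

    ``weights`` holds, per timescale branch b in {0, 1}: ``W1_b``, ``W2_b``,
    and the shared dense head ``Wd``/``bd`` and spike-threshold ``offset``.
    ``scaler_mean``/``scaler_scale`` standardize node features per branch.
    """

    weights: dict[str, np.ndarray]
    activations: tuple[str, str, str] = ("gelu", "tanh", "sigmoid")
    dropout: float = 0.2
    kappa: float = 1.0
    encoder_mode: str = "mean"
    surrogate_slope: float = 10.0
    scaler_mean: Optional[dict[str, np.ndarray]] = None
    scaler_scale: Optional[dict[str, np.ndarray]] = None

    def copy(self) -> "GCNNParams":
        return GCNNParams(
            weights={k: v.copy() for k, v in self.weights.items()},
            activations=self.activations,
            dropout=self.dropout,
            kappa=self.kappa,
            encoder_mode=self.encoder_mode,
            surrogate_slope=self.surrogate_slope,
            scaler_mean=None if self.scaler_mean is None
            else {k: v.copy() for k, v in self.scaler_mean.items()},
            scaler_scale=None if self.scaler_scale is None
            else {k: v.copy() for k, v in self.scaler_scale.items()},
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([self.weights[k].ravel() for k in sorted(self.weights)])


def init_params(
    hidden_units: tuple[int, int] = (16, 16),
    dropout: float = 0.2,
    seed: int = 42,
    activations: tuple[str, str, str] = ("gelu", "tanh", "sigmoid"),
    kappa: float = 1.0,
    encoder_mode: str = "mean",
    surrogate_slope: float = 10.0,
) -> GCNNParams:
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    h1, h2 = hidden_units
    rng = np.random.default_rng(seed)
    w = {}
    for b in (0, 1):
        w[f"W1_{b}"] = rng.normal(0.0, np.sqrt(2.0 / N_NODE_FEATURES), (N_NODE_FEATURES, h1))
        w[f"W2_{b}"] = rng.normal(0.0, np.sqrt(2.0 / h1), (h1, h2))
    w["Wd"] = rng.normal(0.0, np.sqrt(2.0 / (2 * h2)), (2 * h2, 2))
    w["bd"] = np.zeros(2)
    w["offset"] = np.zeros(1)
    return GCNNParams(
        weights=w,
        activations=activations,
        dropout=dropout,
        kappa=kappa,
        encoder_mode=encoder_mode,
        surrogate_slope=surrogate_slope,
    )


def save_params(params: GCNNParams, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    meta = {
        "activations": list(params.activations),
        "dropout": params.dropout,
        "kappa": params.kappa,
        "encoder_mode": params.encoder_mode,
        "surrogate_slope": params.surrogate_slope,
        "tensors": {k: list(v.shape) for k, v in params.weights.items()},
        "has_scaler": params.scaler_mean is not None,
    }
    with open(os.path.join(directory, "architecture.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    for k, v in params.weights.items():
        np.savetxt(os.path.join(directory, f"{k}.csv"), np.atleast_2d(v), delimiter=",")
    if params.scaler_mean is not None:
        for b in params.scaler_mean:
            np.savetxt(os.path.join(directory, f"scaler_mean_{b}.csv"),
                       np.atleast_2d(params.scaler_mean[b]), delimiter=",")
            np.savetxt(os.path.join(directory, f"scaler_scale_{b}.csv"),
                       np.atleast_2d(params.scaler_scale[b]), delimiter=",")


def load_params(directory: str) -> GCNNParams:
    with open(os.path.join(directory, "architecture.json")) as fh:
        meta = json.load(fh)
    weights = {}
    for k, shape in meta["tensors"].items():
        arr = np.loadtxt(os.path.join(directory, f"{k}.csv"), delimiter=",", ndmin=2)
        weights[k] = arr.reshape(shape)
    scaler_mean = scaler_scale = None
    if meta["has_scaler"]:
        scaler_mean, scaler_scale = {}, {}
        for b in ("0", "1"):
            scaler_mean[b] = np.loadtxt(
                os.path.join(directory, f"scaler_mean_{b}.csv"), delimiter=",", ndmin=2
            ).ravel()
            scaler_scale[b] = np.loadtxt(
                os.path.join(directory, f"scaler_scale_{b}.csv"), delimiter=",", ndmin=2
            ).ravel()
    return GCNNParams(
        weights=weights,
        activations=tuple(meta["activations"]),
        dropout=meta["dropout"],
        kappa=meta["kappa"],
        encoder_mode=meta["encoder_mode"],
        surrogate_slope=meta["surrogate_slope"],
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
    )


# ---------------------------------------------------------------------------
# batched spike featurization (with surrogate gradient wrt threshold offset)
# ---------------------------------------------------------------------------

def batch_node_features(
    windows: np.ndarray,
    fs: float,
    kappa: float,
    offset: float,
    mode: str = "mean",
    surrogate_slope: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node features, per-node gates, and d(features)/d(offset).

    ``windows`` has shape (B, T, m). Returns ``X`` (B, m, 4), ``gate`` (B, m)
    and ``dX_doffset`` (B, m, 4). Only the spike-density feature is
    differentiated through the threshold (fast-sigmoid surrogate); the
    run-count/duration features and the High/Low indicator use a
    straight-through treatment (zero gradient).
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3:
        raise ValueError("windows must have shape (B, T, m)")
    B, T, m = w.shape
    mu = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    half = kappa * sd
    if mode == "mean":
        thr = mu + offset * half
        e = (w >= thr).astype(np.int8)
    elif mode == "crossing":
        thr = None
        e = (np.abs(w - mu) >= (1.0 + offset) * half).astype(np.int8)
    else:
        raise ValueError(f"unknown encoder mode {mode!r}")

    starts = e[:, 0, :].astype(float) + (np.diff(e, axis=1) == 1).sum(axis=1)
    ones = e.sum(axis=1).astype(float)
    density = ones / T
    dur = np.where(starts > 0, ones / np.maximum(starts, 1.0), 0.0)
    high = (starts.mean(axis=1, keepdims=True) < starts) & (
        dur.mean(axis=1, keepdims=True) > dur
    )
    ind = high.astype(float)
    gate = density * ind

    dur_s = T / fs
    logvar = np.log(w.var(axis=1) + 1e-12)
    # spike duration in seconds so features are comparable across clients
    # recorded at different sampling rates
    X = np.stack(
        [starts * ind / dur_s, dur * ind / fs, density * ind, logvar], axis=-1
    )

    dX = np.zeros_like(X)
    if mode == "mean":
        g = surrogate_spike_gradient(w - thr, surrogate_slope)
        ddensity = -(g * half).mean(axis=1)  # d thr/d offset = half
        dX[:, :, 2] = ddensity * ind
    return X, gate, dX


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _branch_forward(a_hat, X, gate, W1, W2, acts, dropout, rng, cache):
    f1, _ = _ACTIVATIONS[acts[0]]
    f2, _ = _ACTIVATIONS[acts[1]]
    G0 = gate[:, :, None] * X  # (B, m, d0)
    Z1 = np.einsum("ij,bjk,kl->bil", a_hat, G0, W1)
    H1 = f1(Z1)
    if rng is not None and dropout > 0:
        mask1 = (rng.random(H1.shape) >= dropout) / (1.0 - dropout)
        H1 = H1 * mask1
    else:
        mask1 = None
    G1 = gate[:, :, None] * H1
    Z2 = np.einsum("ij,bjk,kl->bil", a_hat, G1, W2)
    H2 = f2(Z2)
    if rng is not None and dropout > 0:
        mask2 = (rng.random(H2.shape) >= dropout) / (1.0 - dropout)
        H2 = H2 * mask2
    else:
        mask2 = None
    pooled = H2.mean(axis=1)  # (B, h2)
    cache.update(dict(X=X, gate=gate, G0=G0, Z1=Z1, H1=H1, G1=G1, Z2=Z2,
                      mask1=mask1, mask2=mask2, n_nodes=X.shape[1]))
    return pooled


def gcnn_forward(
    params: GCNNParams,
    graph: ChannelGraph,
    Xa: np.ndarray,
    gate_a: np.ndarray,
    Xb: np.ndarray,
    gate_b: np.ndarray,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns class probabilities (B, 2) and a cache."""
    acts = params.activations
    if params.scaler_mean is not None:
        Xa = (Xa - params.scaler_mean["0"]) / params.scaler_scale["0"]
        Xb = (Xb - params.scaler_mean["1"]) / params.scaler_scale["1"]
    drop_rng = rng if training else None
    cache: dict = {"a_hat": graph.a_hat, "branches": [{}, {}]}
    pooled_a = _branch_forward(
        graph.a_hat, Xa, gate_a, params.weights["W1_0"], params.weights["W2_0"],
        acts, params.dropout, drop_rng, cache["branches"][0]
    )
    pooled_b = _branch_forward(
        graph.a_hat, Xb, gate_b, params.weights["W1_1"], params.weights["W2_1"],
        acts, params.dropout, drop_rng, cache["branches"][1]
    )
    z = np.concatenate([pooled_a, pooled_b], axis=1)
    u_pre = z @ params.weights["Wd"] + params.weights["bd"]
    fd, _ = _ACTIVATIONS[acts[2]]
    u = fd(u_pre)
    p = _softmax(u)
    cache.update(dict(z=z, u_pre=u_pre, u=u, p=p))
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise AssertionError("softmax output does not sum to 1")
    return p, cache


def _branch_backward(a_hat, dpooled, W1, W2, acts, cache):
    _, g1 = _ACTIVATIONS[acts[0]]
    _, g2 = _ACTIVATIONS[acts[1]]
    B, m = dpooled.shape[0], cache["n_nodes"]
    dH2 = np.repeat(dpooled[:, None, :], m, axis=1) / m
    if cache["mask2"] is not None:
        dH2 = dH2 * cache["mask2"]
    dZ2 = dH2 * g2(cache["Z2"])
    AG1 = np.einsum("ij,bjk->bik", a_hat, cache["G1"])
    dW2 = np.einsum("bik,bil->kl", AG1, dZ2)
    dG1 = np.einsum("ji,bjl,kl->bik", a_hat, dZ2, W2)
    dH1 = cache["gate"][:, :, None] * dG1
    if cache["mask1"] is not None:
        dH1 = dH1 * cache["mask1"]
    dZ1 = dH1 * g1(cache["Z1"])
    AG0 = np.einsum("ij,bjk->bik", a_hat, cache["G0"])
    dW1 = np.einsum("bik,bil->kl", AG0, dZ1)
    dG0 = np.einsum("ji,bjl,kl->bik", a_hat, dZ1, W1)
    dX = cache["gate"][:, :, None] * dG0
    return dW1, dW2, dX


def gcnn_backward(
    params: GCNNParams,
    cache: dict,
    y: np.ndarray,
    div_grad: Optional[np.ndarray] = None,
    ce_weight: float = 1.0,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Gradients of the mean loss over the batch.

    ``y`` is 0/1 (1 = preictal). The base loss is ``ce_weight`` times the
    cross-entropy; ``div_grad`` optionally adds a per-sample
    dL/d(p_preictal) term (used by the divergence-regularized
    personalization).
    """
    p = cache["p"]
    B = p.shape[0]
    onehot = np.zeros_like(p)
    onehot[np.arange(B), y.astype(int)] = 1.0
    du = ce_weight * (p - onehot) / B  # softmax + CE
    if div_grad is not None:
        # dL/du via softmax jacobian row for the preictal output
        dp_pos = div_grad / B
        jac = p[:, 1:2] * (np.eye(2)[1][None, :] - p)
        du = du + dp_pos[:, None] * jac
    _, gd = _ACTIVATIONS[params.activations[2]]
    du_pre = du * gd(cache["u_pre"])
    dWd = cache["z"].T @ du_pre
    dbd = du_pre.sum(axis=0)
    dz = du_pre @ params.weights["Wd"].T
    h2 = dz.shape[1] // 2
    grads = {"Wd": dWd, "bd": dbd}
    dXs = []
    for b, dpooled in ((0, dz[:, :h2]), (1, dz[:, h2:])):
        dW1, dW2, dX = _branch_backward(
            cache["a_hat"], dpooled, params.weights[f"W1_{b}"],
            params.weights[f"W2_{b}"], params.activations, cache["branches"][b]
        )
        grads[f"W1_{b}"] = dW1
        grads[f"W2_{b}"] = dW2
        dXs.append(dX)
    return grads, dXs[0], dXs[1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, keys, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            weights[k] = weights[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainLog:
    epoch_loss: list[float] = field(default_factory=list)


def _divergence_grad(p_bar_g: np.ndarray, p_p: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """d/dP_P of the Bernoulli-KL divergence KL(P_bar_G || P_P)."""
    q = np.clip(p_p, eps, 1 - eps)
    return -p_bar_g / q + (1.0 - p_bar_g) / (1.0 - q)


def train_local(
    windows_a: np.ndarray,
    windows_b: np.ndarray,
    labels: np.ndarray,
    fs: float,
    graph: ChannelGraph,
    config,
    seed: int = 42,
    init: Optional[GCNNParams] = None,
    w1: float = 1.0,
    w2: float = 0.0,
    global_params: Optional[GCNNParams] = None,
    p_bar_transform=None,
) -> tuple[GCNNParams, TrainLog]:
    """Adam/cross-entropy training of the bi-timescale spiking-GCNN.

    ``windows_a``/``windows_b`` are paired raw windows (B, T, m) at the two
    chosen timescales with shared 0/1 ``labels`` (1 = preictal). When
    ``w2 > 0`` and ``global_params`` is given, a Bernoulli-KL divergence
    toward the (optionally transformed) global preictal probability is added
    with weight ``w2`` — the personalized loss. Deterministic for a fixed
    seed.
    """
    if len(labels) == 0:
        raise ValueError("empty training set")
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    params = init.copy() if init is not None else init_params(
        hidden_units=tuple(config.hidden_units),
        dropout=config.dropout,
        seed=seed,
        kappa=config.kappa,
        encoder_mode=config.encoder_mode,
        surrogate_slope=config.surrogate_slope,
    )

    # fit node-feature scaler at the initial offset (held fixed thereafter)
    if params.scaler_mean is None:
        off0 = float(params.weights["offset"][0])
        sm, ss = {}, {}
        for key, wins in (("0", windows_a), ("1", windows_b)):
            X, _, _ = batch_node_features(
                wins, fs, params.kappa, off0, params.encoder_mode, params.surrogate_slope
            )
            flat = X.reshape(-1, X.shape[-1])
            sm[key] = flat.mean(axis=0)
            sd = flat.std(axis=0)
            ss[key] = np.where(sd > 1e-9, sd, 1.0)
        params.scaler_mean, params.scaler_scale = sm, ss

    opt = _Adam(params.weights.keys(), lr=config.learning_rate)
    log = TrainLog()
    n = len(y)
    use_div = w2 > 0.0 and global_params is not None

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            wa, wb, yb = windows_a[idx], windows_b[idx], y[idx]
            off = float(params.weights["offset"][0])
            Xa, ga, dXa = batch_node_features(
                wa, fs, params.kappa, off, params.encoder_mode, params.surrogate_slope
            )
            Xb, gb, dXb = batch_node_features(
                wb, fs, params.kappa, off, params.encoder_mode, params.surrogate_slope
            )
            p, cache = gcnn_forward(params, graph, Xa, ga, Xb, gb, training=True, rng=rng)
            p_true = np.clip(p[np.arange(len(yb)), yb], 1e-12, None)
            loss = -np.log(p_true).mean() * w1

            div_grad = None
            if use_div:
                pg, _ = gcnn_forward(global_params, graph, Xa, ga, Xb, gb, training=False)
                p_bar = pg[:, 1]
                if p_bar_transform is not None:
                    p_bar = p_bar_transform(p_bar)
                div_grad = w2 * _divergence_grad(p_bar, p[:, 1])
                q = np.clip(p[:, 1], 1e-7, 1 - 1e-7)
                pb = np.clip(p_bar, 1e-7, 1 - 1e-7)
                loss += w2 * float(
                    np.mean(pb * np.log(pb / q) + (1 - pb) * np.log((1 - pb) / (1 - q)))
                )

            grads, dX_a, dX_b = gcnn_backward(params, cache, yb, div_grad, ce_weight=w1)
            d_off = float(
                (dX_a * dXa / params.scaler_scale["0"]).sum()
                + (dX_b * dXb / params.scaler_scale["1"]).sum()
            )
            grads["offset"] = np.array([d_off])
            opt.step(params.weights, grads)
            epoch_loss += loss * len(yb)
        log.epoch_loss.append(epoch_loss / n)
    return params, log


def predict_proba(
    params: GCNNParams,
    graph: ChannelGraph,
    windows_a: np.ndarray,
    windows_b: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Preictal probability per paired window (evaluation mode, no dropout)."""
    off = float(params.weights["offset"][0])
    Xa, ga, _ = batch_node_features(
        windows_a, fs, params.kappa, off, params.encoder_mode, params.surrogate_slope
    )
    Xb, gb, _ = batch_node_features(
        windows_b, fs, params.kappa, off, params.encoder_mode, params.surrogate_slope
    )
    p, _ = gcnn_forward(params, graph, Xa, ga, Xb, gb, training=False)
    return p[:, 1]
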