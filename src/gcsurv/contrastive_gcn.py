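"""Self-supervised graph-convolutional encoder with momentum contrastive learning.

Each sample's fused feature vector is treated as a one-channel signal over the
pathway-derived feature graph. A graph convolution sigma(S h w) produces
per-node channels that a small multilayer perceptron maps to a d-dimensional
embedding; by default the node-channel outputs are kept (flattened) so that
per-feature identity survives into the embedding, with mean-pooling over
nodes available as a cheaper alternative. Training pulls
together the two corrupted views of a sample (positive pair) and pushes apart
views of different samples, using a temperature-scaled softmax over cosine
similarities, an L2 activity penalty, a fast query encoder updated by
backpropagation (Adam) and a slow key encoder updated as an exponential moving
average of the query parameters.

Implemented in NumPy with hand-written gradients; fully deterministic given
the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from gcsurv.fusion_augment import AugmentConfig, FusionBundle, make_paired_views
from gcsurv.pathway_graph import NormalizedAdjacency


@dataclass
class EncoderConfig:
    """Architecture and optimization settings for the contrastive encoder."""

    gcn_units: int = 16
    hidden_sizes: tuple[int, ...] = (128,)
    embed_dim: int = 32
    temperature: float = 0.5
    l2_gamma: float = 1e-4
    momentum: float = 0.99
    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-3
    activation: str = "relu"
    pooling: str = "flatten"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.l2_gamma < 0:
            raise ValueError("l2_gamma must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")
        if self.pooling not in ("flatten", "mean"):
            raise ValueError("pooling must be 'flatten' or 'mean'")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)


@dataclass
class EncoderParams:
    """Parameter arrays for one encoder (query or key).

    ``wg``/``bg`` are the single-input-channel GCN weights and biases
    (one scalar weight and bias per GCN channel); ``weights``/``biases`` are
    the MLP layers mapping the pooled GCN channels to the embedding.
    """

    wg: np.ndarray
    bg: np.ndarray
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            self.wg.copy(),
            self.bg.copy(),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    def flat(self) -> list[np.ndarray]:
        return [self.wg, self.bg, *self.weights, *self.biases]

    def congruent(self, other: "EncoderParams") -> bool:
        a, b = self.flat(), other.flat()
        return len(a) == len(b) and all(x.shape == y.shape for x, y in zip(a, b))


@dataclass
class Embedding:
    """Per-sample d-dimensional representations, columns aligned with sample_ids."""

    Z: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[1] != len(self.sample_ids):
            raise ValueError("Z columns must match sample_ids")
        if not np.isfinite(self.Z).all():
            raise ValueError("embedding contains non-finite values")

    @property
    def dim(self) -> int:
        return self.Z.shape[0]


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(x, 0.0) if kind == "relu" else x


def gcn_forward(
    H: np.ndarray,
    S: NormalizedAdjacency | np.ndarray,
    W: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph-convolution layer: sigma(S H W).

    ``H`` is the node-feature matrix (nodes x channels), ``W`` maps input to
    output channels.
    """
    Smat = S.matrix if isinstance(S, NormalizedAdjacency) else np.asarray(S)
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if Smat.shape[1] != H.shape[0]:
        raise ValueError(f"S has {Smat.shape[1]} nodes but H has {H.shape[0]} rows")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"H has {H.shape[1]} channels but W expects {W.shape[0]}")
    return _act(Smat @ H @ W, activation)


def contrastive_loss(view_embeddings: np.ndarray, pair_index: np.ndarray, tau: float) -> float:
    """Temperature-scaled contrastive loss over a batch of paired views.

    Embeddings (columns) are L2-normalized; for each anchor i the loss is
    -log softmax of its positive partner among all other views, and the batch
    loss is the mean over anchors.
    """
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    Z = np.asarray(view_embeddings, dtype=float)
    if Z.shape[1] < 4:
        raise ValueError("need at least 4 views (2 pairs)")
    loss, _ = _nt_xent(Z, np.asarray(pair_index, dtype=int), tau)
    return float(loss)


def _nt_xent(Z: np.ndarray, pair: np.ndarray, tau: float) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the *unnormalized* embedding columns Z (d x 2N)."""
    n = Z.shape[1]
    norms = np.linalg.norm(Z, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    V = Z / norms
    logits = (V.T @ V) / tau
    np.fill_diagonal(logits, -np.inf)
    mx = logits.max(axis=1, keepdims=True)
    ex = np.exp(logits - mx)
    ssum = ex.sum(axis=1, keepdims=True)
    P = ex / ssum  # row i: softmax over k != i
    pos = logits[np.arange(n), pair]
    loss = float(np.mean(-(pos - mx.ravel()) + np.log(ssum.ravel())))
    # dLoss/dlogits
    G = P.copy()
    G[np.arange(n), pair] -= 1.0
    G /= n * tau
    np.fill_diagonal(G, 0.0)
    dV = V @ (G + G.T)
    # back through the normalization v = z/|z|
    dZ = (dV - V * np.sum(dV * V, axis=0, keepdims=True)) / norms
    return loss, dZ


def l2_activity_penalty(layer_outputs: list[np.ndarray], gamma: float) -> float:
    """Activity regularizer: gamma * sum of squared Frobenius norms of layer
    activations, averaged over batch columns."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    total = 0.0
    for L in layer_outputs:
        L = np.asarray(L, dtype=float)
        b = L.shape[1] if L.ndim == 2 else 1
        total += float(np.sum(L * L)) / b
    return gamma * total


def momentum_update(theta_k: EncoderParams, theta_q: EncoderParams, lam: float) -> EncoderParams:
    """Exponential-moving-average update of the key encoder toward the query."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("momentum must lie in [0, 1]")
    if not theta_k.congruent(theta_q):
        raise ValueError("parameter sets are not shape-congruent")
    out = theta_k.copy()
    for pk, pq in zip(out.flat(), theta_q.flat()):
        pk *= lam
        pk += (1.0 - lam) * pq
    return out


def init_params(n_features: int, cfg: EncoderConfig, rng: np.random.Generator) -> EncoderParams:
    """Glorot-scaled random initialization."""
    wg = rng.normal(0.0, 1.0, size=cfg.gcn_units)
    bg = np.zeros(cfg.gcn_units)
    mlp_in = cfg.gcn_units * (n_features if cfg.pooling == "flatten" else 1)
    sizes = [mlp_in, *cfg.hidden_sizes, cfg.embed_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        sd = math.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, sd, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return EncoderParams(wg, bg, weights, biases)


def _forward(X: np.ndarray, S: NormalizedAdjacency, params: EncoderParams, cfg: EncoderConfig):
    """Forward pass for a batch of columns; returns embedding and a cache."""
    SX = S.dot(X)  # (m, B)
    # GCN with one input channel: T[m, c, b] = SX[m, b] * wg[c] + bg[c]
    T = SX[:, None, :] * params.wg[None, :, None] + params.bg[None, :, None]
    G = _act(T, cfg.activation)
    if cfg.pooling == "mean":
        P = G.mean(axis=0)  # (C, B) pooled node activity per channel
    else:
        m, C, B = G.shape
        P = G.reshape(m * C, B)  # keep per-node channels
    acts = [P]
    pre = []
    h = P
    n_layers = len(params.weights)
    for li, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = W @ h + b[:, None]
        pre.append(z)
        h = _act(z, cfg.activation) if li < n_layers - 1 else z  # linear head
        acts.append(h)
    cache = {"SX": SX, "T": T, "G": G, "acts": acts, "pre": pre}
    return h, cache


def _backward(
    dZ: np.ndarray,
    cache: dict,
    params: EncoderParams,
    cfg: EncoderConfig,
) -> EncoderParams:
    """Backward pass; dZ is the gradient at the embedding output.

    The activity penalty's gradient (2*gamma*activation/B) is injected at each
    cached layer on the way down.
    """
    B = dZ.shape[1]
    acts, pre = cache["acts"], cache["pre"]
    gamma = cfg.l2_gamma
    gw = [np.zeros_like(w) for w in params.weights]
    gb = [np.zeros_like(b) for b in params.biases]
    n_layers = len(params.weights)
    dh = dZ + 2.0 * gamma * acts[-1] / B
    for li in range(n_layers - 1, -1, -1):
        dz = dh if li == n_layers - 1 else dh * (pre[li] > 0 if cfg.activation == "relu" else 1.0)
        gw[li] = dz @ acts[li].T
        gb[li] = dz.sum(axis=1)
        dh = params.weights[li].T @ dz
        if li > 0:
            dh = dh + 2.0 * gamma * acts[li] / B
    # pooled GCN output
    dP = dh + 2.0 * gamma * acts[0] / B
    m = cache["T"].shape[0]
    if cfg.pooling == "mean":
        dG = np.broadcast_to(dP[None, :, :] / m, cache["T"].shape)
    else:
        dG = dP.reshape(cache["T"].shape)
    if cfg.activation == "relu":
        dT = dG * (cache["T"] > 0)
    else:
        dT = dG
    dwg = np.einsum("mcb,mb->c", dT, cache["SX"])
    dbg = dT.sum(axis=(0, 2))
    return EncoderParams(dwg, dbg, gw, gb)


class _Adam:
    def __init__(self, params: EncoderParams, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params.flat()]
        self.v = [np.zeros_like(p) for p in params.flat()]

    def step(self, params: EncoderParams, grads: EncoderParams) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params.flat(), grads.flat())):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def batch_loss(
    X_batch: np.ndarray,
    S: NormalizedAdjacency,
    theta_q: EncoderParams,
    theta_k: EncoderParams,
    cfg: EncoderConfig,
    aug: AugmentConfig,
    view_seed: int,
    sample_ids: list[str] | None = None,
) -> tuple[float, EncoderParams]:
    """Total loss (contrastive + activity penalty) and gradient w.r.t. theta_q
    for one batch: query views through theta_q, key views through theta_k."""
    n = X_batch.shape[1]
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    import pandas as pd  # local: avoids cycle at import time

    meta = pd.DataFrame(
        {"modality": ["mrna"] * X_batch.shape[0],
         "gene_symbol": [str(i) for i in range(X_batch.shape[0])],
         "source_feature_id": [str(i) for i in range(X_batch.shape[0])]}
    )
    bundle = FusionBundle(X_batch, meta, ids)
    views = make_paired_views(bundle, replace(aug, seed=view_seed), ids)
    Vq = views.view_matrix[:, :n]
    Vk = views.view_matrix[:, n:]
    Zq, cache_q = _forward(Vq, S, theta_q, cfg)
    Zk, _ = _forward(Vk, S, theta_k, cfg)
    Z = np.hstack([Zq, Zk])
    pair = np.concatenate([np.arange(n) + n, np.arange(n)])
    closs, dZ = _nt_xent(Z, pair, cfg.temperature)
    penalty = l2_activity_penalty(cache_q["acts"], cfg.l2_gamma)
    grads = _backward(dZ[:, :n], cache_q, cfg=cfg, params=theta_q)
    return closs + penalty, grads


def train_encoder(
    bundle: FusionBundle,
    S: NormalizedAdjacency,
    cfg: EncoderConfig,
    aug: AugmentConfig,
) -> tuple[EncoderParams, EncoderParams, list[float]]:
    """Train query/key encoders by momentum contrastive learning.

    Returns (theta_q, theta_k, per-epoch mean losses). The key encoder starts
    as a copy of the query encoder and never receives gradients; after every
    query update it moves by an exponential moving average toward the query.
    """
    n = bundle.n_samples
    if n < 2 * cfg.batch_size and n < 4:
        raise ValueError("need at least 4 samples to form contrastive batches")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
    theta_q = init_params(bundle.n_features, cfg, rng)
    theta_k = theta_q.copy()
    opt = _Adam(theta_q, cfg.learning_rate)
    log: list[float] = []
    X = bundle.X
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for bstart in range(0, n, cfg.batch_size):
            idx = order[bstart : bstart + cfg.batch_size]
            if len(idx) < 2:
                continue
            view_seed = int(
                np.random.SeedSequence([int(cfg.seed), 11, epoch, bstart]).generate_state(1)[0]
                % (2**31)
            )
            loss, grads = batch_loss(
                X[:, idx], S, theta_q, theta_k, cfg, aug, view_seed,
                sample_ids=[bundle.sample_ids[i] for i in idx],
            )
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {bstart}"
                )
            opt.step(theta_q, grads)
            theta_k = momentum_update(theta_k, theta_q, cfg.momentum)
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return theta_q, theta_k, log


def extract_embedding(
    params: EncoderParams,
    bundle: FusionBundle,
    S: NormalizedAdjacency,
    cfg: EncoderConfig,
) -> Embedding:
    """Encode un-augmented samples through the query encoder's embedding layer."""
    Z, _ = _forward(bundle.X, S, params, cfg)
    return Embedding(Z, list(bundle.sample_ids))


def save_params(params: EncoderParams, cfg: EncoderConfig, path: str) -> None:
    """Persist parameters plus a config echo as a self-describing npz archive."""
    arrays = {"wg": params.wg, "bg": params.bg}
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    arrays["n_layers"] = np.array([len(params.weights)])
    import json

    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg.__dict__, default=list).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_params(path: str) -> EncoderParams:
    with np.load(path) as data:
        n_layers = int(data["n_layers"][0])
        return EncoderParams(
            data["wg"],
            data["bg"],
            [data[f"w{i}"] for i in range(n_layers)],
            [data[f"b{i}"] for i in range(n_layers)],
        )
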