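"""Federated simulation: local SGD training and FedAvg aggregation.

One communication round broadcasts the global parameters, trains each
client locally (SGD + momentum, cross-entropy with mixup, cosine-annealing
warm-restart learning-rate schedule), and aggregates the updates as the
sample-count-weighted mean (FedAvg).  The reference recipe is 5 rounds of
20 local epochs, batch 16, learning rate annealed 0.05 -> 1e-5 within each
round and restarting at round boundaries, mixup alpha = 0.5.  Desk-scale
runs shrink rounds/epochs, not the recipe.

The final model is taken at the round with the minimum mean validation
loss (each client holds out a stratified 20% of its training samples for
validation).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import (
    SGD,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ModelParameters,
    ReLU,
    Sequential,
    cross_entropy_loss,
    one_hot,
    softmax,
)


@dataclass
class FederationConfig:
    rounds: int = 5
    local_epochs: int = 20
    batch_size: int = 16
    lr_init: float = 0.05
    lr_min: float = 1e-5
    momentum: float = 0.9
    mixup_alpha: float = 0.5  # 0 disables mixup
    embedding_dim: int = 64
    n_classes: int = 4
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.local_epochs < 0:
            raise ValueError("rounds must be >= 1 and local_epochs >= 0")
        if not self.lr_init > self.lr_min > 0:
            raise ValueError("need lr_init > lr_min > 0")


@dataclass
class ClientState:
    """One client's local training set (clean, noisy or pseudo labels,
    depending on the experiment mode)."""

    client_id: str
    pixels: np.ndarray  # (n, H, W)
    labels: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.n_k < 1:
            raise ValueError("client must hold at least one sample")
        if len(self.pixels) != self.n_k:
            raise ValueError("pixels/labels length mismatch")

    @property
    def n_k(self) -> int:
        return len(self.labels)


def build_classifier(embedding_dim: int = 64, n_classes: int = 4, seed: int = 0) -> Sequential:
    """Encoder backbone + linear classification head, as one named chain.

    Backbone layer names match :class:`planefed.contrastive.Encoder`, so a
    contrastively pretrained backbone drops straight in.
    """
    rng = np.random.default_rng(seed)
    return Sequential(
        [
            ("conv1", Conv2d(1, 8, stride=2, rng=rng)),
            ("relu1", ReLU()),
            ("conv2", Conv2d(8, 16, stride=2, rng=rng)),
            ("relu2", ReLU()),
            ("conv3", Conv2d(16, 32, stride=2, rng=rng)),
            ("relu3", ReLU()),
            ("pool", GlobalAvgPool()),
            ("embed", Linear(32, embedding_dim, rng=rng)),
            ("headrelu", ReLU()),
            ("head", Linear(embedding_dim, n_classes, rng=rng)),
        ]
    )


def init_from_backbone(model: Sequential, backbone_params: ModelParameters) -> None:
    """Overwrite the model's backbone parameters with pretrained ones,
    leaving the classification head at its fresh initialization."""
    params = model.get_params()
    for key, arr in backbone_params.items():
        if key not in params:
            raise ValueError(f"backbone parameter {key!r} not in model")
        params[key] = arr.copy()
    model.set_params(params)


def fedavg(updates: list[tuple[ModelParameters, int]]) -> ModelParameters:
    """Sample-count-weighted elementwise mean of client parameters."""
    if not updates:
        raise ValueError("no updates to aggregate")
    total = sum(n for _, n in updates)
    if total <= 0:
        raise ValueError("total sample count must be positive")
    names = list(updates[0][0].keys())
    for params, _ in updates:
        if list(params.keys()) != names:
            raise ValueError("clients disagree on parameter names")
    out: ModelParameters = {}
    for name in names:
        shapes = {params[name].shape for params, _ in updates}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for parameter {name!r}")
        out[name] = sum((n / total) * params[name] for params, n in updates)
    return out


def cosine_warm_restart_lr(
    global_epoch: int, cycle_len: int, lr_init: float = 0.05, lr_min: float = 1e-5
) -> float:
    """Cosine annealing from lr_init to lr_min over one cycle, restarting
    at every multiple of cycle_len (one communication round)."""
    if cycle_len < 1:
        raise ValueError("cycle_len must be >= 1")
    phase = (global_epoch % cycle_len) / cycle_len
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + np.cos(np.pi * phase))


def _client_rng(cfg: FederationConfig, client_id: str, round_idx: int):
    # crc32 keeps the stream independent of PYTHONHASHSEED
    uid = zlib.crc32(client_id.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, round_idx, uid]))


def local_train(
    client: ClientState,
    global_params: ModelParameters,
    cfg: FederationConfig,
    round_idx: int = 0,
) -> ModelParameters:
    """One client's local epochs of mixup cross-entropy SGD, starting from
    the broadcast global parameters.  Deterministic under the federation
    seed, the round index and the client id."""
    model = build_classifier(cfg.embedding_dim, cfg.n_classes, seed=0)
    model.set_params(global_params)
    if cfg.local_epochs == 0:
        return model.get_params()
    rng = _client_rng(cfg, client.client_id, round_idx)
    opt = SGD(model, momentum=cfg.momentum)
    x_all = client.pixels[:, None, :, :]
    y_all = one_hot(client.labels, cfg.n_classes)

    for epoch in range(cfg.local_epochs):
        lr = cosine_warm_restart_lr(
            round_idx * cfg.local_epochs + epoch, cfg.local_epochs, cfg.lr_init, cfg.lr_min
        )
        order = rng.permutation(client.n_k)
        for start in range(0, client.n_k, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, y = x_all[idx], y_all[idx]
            if cfg.mixup_alpha > 0 and len(idx) > 1:
                lam = rng.beta(cfg.mixup_alpha, cfg.mixup_alpha)
                perm = rng.permutation(len(idx))
                x = lam * x + (1.0 - lam) * x[perm]
                y = lam * y + (1.0 - lam) * y[perm]
            logits = model.forward(x)
            _, dlogits = cross_entropy_loss(logits, y)
            _, grads = model.backward(dlogits)
            opt.step(grads, lr)
    return model.get_params()


def predict_proba(
    params: ModelParameters, pixels: np.ndarray, cfg: FederationConfig, batch_size: int = 64
) -> np.ndarray:
    model = build_classifier(cfg.embedding_dim, cfg.n_classes, seed=0)
    model.set_params(params)
    x = np.asarray(pixels, dtype=np.float64)[:, None, :, :]
    out = [softmax(model.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
    return np.concatenate(out) if out else np.empty((0, cfg.n_classes))


def predict(params: ModelParameters, pixels: np.ndarray, cfg: FederationConfig) -> np.ndarray:
    return predict_proba(params, pixels, cfg).argmax(axis=1)


def _stratified_val_split(labels: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Boolean mask marking the validation part, stratified per class."""
    mask = np.zeros(len(labels), dtype=bool)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_val = int(round(fraction * len(idx)))
        if len(idx) > 1:
            n_val = min(max(n_val, 0), len(idx) - 1)
        mask[rng.permutation(idx)[:n_val]] = True
    return mask


def validation_split(client: ClientState, cfg: FederationConfig):
    """Carve the client's stratified validation hold-out, deterministic in
    the federation seed and the client id.  Returns (train ClientState,
    val pixels, val labels)."""
    uid = zlib.crc32(client.client_id.encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20, uid]))
    val_mask = _stratified_val_split(client.labels, cfg.val_fraction, rng)
    train = ClientState(client.client_id, client.pixels[~val_mask], client.labels[~val_mask])
    return train, client.pixels[val_mask], client.labels[val_mask]


def run_federation(
    clients: list[ClientState],
    model_init: ModelParameters | None,
    cfg: FederationConfig,
    select_best: bool = True,
):
    """Broadcast -> local train -> FedAvg for ``cfg.rounds`` rounds.

    Returns (global parameters at the round with minimum mean validation
    loss -- or at the last round if ``select_best`` is False -- and a
    per-round history DataFrame with columns round, client, val_loss,
    val_macro_f1).
    """
    from .evaluation import f1_scores  # local import: evaluation also uses this module

    if not clients:
        raise ValueError("need at least one client")
    if model_init is None:
        model_init = build_classifier(cfg.embedding_dim, cfg.n_classes, seed=cfg.seed).get_params()

    train_clients, val_sets = [], []
    for client in clients:
        train, vx, vy = validation_split(client, cfg)
        train_clients.append(train)
        val_sets.append((vx, vy))

    global_params = {k: v.copy() for k, v in model_init.items()}
    rows = []
    best_loss, best_params = np.inf, global_params
    for rnd in range(cfg.rounds):
        updates = [
            (local_train(tc, global_params, cfg, round_idx=rnd), tc.n_k)
            for tc in train_clients
        ]
        global_params = fedavg(updates)

        losses = []
        for client, (vx, vy) in zip(clients, val_sets):
            if len(vy) == 0:
                continue
            proba = predict_proba(global_params, vx, cfg)
            logp = np.log(np.clip(proba, 1e-12, None))
            val_loss = float(-logp[np.arange(len(vy)), vy].mean())
            _, macro = f1_scores(proba.argmax(axis=1), vy, cfg.n_classes)
            losses.append(val_loss)
            rows.append(
                {
                    "round": rnd,
                    "client": client.client_id,
                    "val_loss": val_loss,
                    "val_macro_f1": macro,
                }
            )
        mean_loss = float(np.mean(losses)) if losses else np.inf
        if mean_loss < best_loss:
            best_loss = mean_loss
            best_params = {k: v.copy() for k, v in global_params.items()}
    history = pd.DataFrame(rows)
    if not select_best:
        return global_params, history
    return best_params, history
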