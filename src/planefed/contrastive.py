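"""Contrastive (SimCLR-style) pretraining of the image encoder.

The large, representative client trains an encoder f(.) self-supervisedly:
each image yields two augmented views, both are embedded and projected, and
the NT-Xent loss with temperature tau pulls the paired projections together
against the in-batch negatives.  Downstream stages (k-NN denoising,
prototypes) consume the *backbone* embeddings, never the projection-head
output -- the head exists only for the loss.

The reference-scale configuration is a ResNet-50 backbone with 2048-length
embeddings, batch 256 and tau = 0.5; the desk-scale default here is a small
three-block CNN with 64-length embeddings so that the full pipeline runs on
one CPU in seconds.  No deep-learning framework is used: the encoder and
its gradients are the NumPy layers in :mod:`planefed.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import SGD, Conv2d, GlobalAvgPool, Linear, ReLU, Sequential


@dataclass
class AugmentationSpec:
    """Random view transforms: horizontal flip, rotation, shift,
    brightness and contrast jitter.  Defaults follow the ultrasound
    setting: rotations up to 15 degrees, shifts up to 12 pixels, and
    brightness/contrast in [0.7, 1.3]."""

    hflip_prob: float = 0.5
    max_rotation_deg: float = 15.0
    max_shift_px: float = 12.0
    brightness_range: tuple[float, float] = (0.7, 1.3)
    contrast_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        for lo, hi in (self.brightness_range, self.contrast_range):
            if not lo <= 1.0 <= hi:
                raise ValueError("brightness/contrast ranges must contain 1.0")

    def is_identity(self) -> bool:
        return (
            self.hflip_prob == 0.0
            and self.max_rotation_deg == 0.0
            and self.max_shift_px == 0.0
            and self.brightness_range == (1.0, 1.0)
            and self.contrast_range == (1.0, 1.0)
        )


IDENTITY_AUG = AugmentationSpec(
    hflip_prob=0.0,
    max_rotation_deg=0.0,
    max_shift_px=0.0,
    brightness_range=(1.0, 1.0),
    contrast_range=(1.0, 1.0),
)


@dataclass
class ContrastiveConfig:
    tau: float = 0.5
    batch_pairs: int = 32
    embedding_dim: int = 64
    projection_dim: int = 32
    epochs: int = 5
    lr: float = 0.1
    momentum: float = 0.9
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    arch: str = "tinycnn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.batch_pairs < 2:
            raise ValueError("batch_pairs must be >= 2")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


class Encoder:
    """The encoder contract: a parameterized map from an image to a
    fixed-length embedding, deterministic in inference mode."""

    def __init__(self, arch: str, embedding_dim: int, seed: int = 0):
        if arch != "tinycnn":
            raise ValueError(
                f"architecture {arch!r} is not available in this build; "
                "only 'tinycnn' is implemented"
            )
        self.arch = arch
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng(seed)
        self.net = Sequential(
            [
                ("conv1", Conv2d(1, 8, stride=2, rng=rng)),
                ("relu1", ReLU()),
                ("conv2", Conv2d(8, 16, stride=2, rng=rng)),
                ("relu2", ReLU()),
                ("conv3", Conv2d(16, 32, stride=2, rng=rng)),
                ("relu3", ReLU()),
                ("pool", GlobalAvgPool()),
                ("embed", Linear(32, embedding_dim, rng=rng)),
            ]
        )

    def get_params(self):
        return self.net.get_params()

    def set_params(self, params) -> None:
        self.net.set_params(params)


def _as_batch(images) -> np.ndarray:
    """Stack images (LabeledImage or raw arrays) into (B, 1, H, W)."""
    arrs = [im.pixels if hasattr(im, "pixels") else np.asarray(im) for im in images]
    return np.stack(arrs)[:, None, :, :]


def embed(encoder: Encoder, images, batch_size: int = 64) -> np.ndarray:
    """Backbone embeddings, one row per image, order-preserving."""
    x = _as_batch(images)
    out = [
        encoder.net.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(out) if out else np.empty((0, encoder.embedding_dim))


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def _pair_index(n: int, pairing=None) -> np.ndarray:
    if pairing is None:
        pairing = np.arange(n) ^ 1  # (0,1), (2,3), ...
    pairing = np.asarray(pairing, dtype=np.int64)
    if len(pairing) != n or np.any(pairing[pairing] != np.arange(n)) or np.any(
        pairing == np.arange(n)
    ):
        raise ValueError("pairing must be a perfect matching without fixed points")
    return pairing


def nt_xent_loss(projections: np.ndarray, tau: float = 0.5, pairing=None) -> float:
    """Normalized-temperature cross-entropy over a batch of 2N paired
    projections, averaged over all 2N anchors.

    For anchor i with positive j: -log[ exp(sim(z_i,z_j)/tau) /
    sum_{r != i} exp(sim(z_i,z_r)/tau) ], with cosine similarity.
    """
    loss, _ = nt_xent_loss_and_grad(projections, tau, pairing)
    return loss


def nt_xent_loss_and_grad(projections: np.ndarray, tau: float = 0.5, pairing=None):
    z = np.asarray(projections, dtype=np.float64)
    n = z.shape[0]
    if n < 2 or n % 2 != 0:
        raise ValueError("need an even number (>= 2) of projections")
    if tau <= 0:
        raise ValueError("tau must be positive")
    pair = _pair_index(n, pairing)

    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm projection")
    u = z / norms
    s = (u @ u.T) / tau
    np.fill_diagonal(s, -np.inf)  # anchor never its own negative

    m = s.max(axis=1, keepdims=True)
    exps = np.exp(s - m)
    lse = m[:, 0] + np.log(exps.sum(axis=1))
    loss = float(np.mean(lse - s[np.arange(n), pair]))

    # dL/dS: softmax over negatives minus the positive indicator, per anchor
    g = exps / exps.sum(axis=1, keepdims=True)
    g[np.arange(n), pair] -= 1.0
    g /= n
    du = (g + g.T) @ u / tau
    # through the row normalization u = z / ||z||
    dz = (du - u * (u * du).sum(axis=1, keepdims=True)) / norms
    return loss, dz


def _rotate(img, deg):
    return ndimage.rotate(
        img, deg, reshape=False, order=1, mode="nearest", prefilter=False
    )


def augment_image(
    pixels: np.ndarray, aug: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    """One random view; output has the same shape and stays in [0, 1]."""
    if aug.is_identity():
        return np.array(pixels, copy=True)
    out = pixels
    if rng.random() < aug.hflip_prob:
        out = out[:, ::-1]
    deg = rng.uniform(-aug.max_rotation_deg, aug.max_rotation_deg)
    if deg != 0.0:
        out = _rotate(out, deg)
    if aug.max_shift_px > 0:
        dy, dx = rng.uniform(-aug.max_shift_px, aug.max_shift_px, size=2)
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest", prefilter=False)
    b = rng.uniform(*aug.brightness_range)
    c = rng.uniform(*aug.contrast_range)
    if b != 1.0 or c != 1.0:
        out = (out * b - 0.5) * c + 0.5
    return np.clip(out, 0.0, 1.0)


def make_simclr_views(image, aug: AugmentationSpec, rng: np.random.Generator):
    """Two independent random views of one image (neither forced to be the
    identity)."""
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    return augment_image(pixels, aug, rng), augment_image(pixels, aug, rng)


def pretrain_encoder(images, cfg: ContrastiveConfig):
    """Self-supervised pretraining on one client; labels are never read.

    Returns (encoder, projection-head parameters, per-epoch mean loss).
    """
    if len(images) < cfg.batch_pairs:
        raise ValueError("dataset smaller than one batch")
    rng = np.random.default_rng(cfg.seed)
    encoder = Encoder(cfg.arch, cfg.embedding_dim, seed=cfg.seed)
    head = Sequential(
        [
            ("proj1", Linear(cfg.embedding_dim, cfg.projection_dim, rng=rng)),
            ("projrelu", ReLU()),
            ("proj2", Linear(cfg.projection_dim, cfg.projection_dim, rng=rng)),
        ]
    )
    opt_enc = SGD(encoder.net, momentum=cfg.momentum)
    opt_head = SGD(head, momentum=cfg.momentum)
    pixels = [im.pixels if hasattr(im, "pixels") else np.asarray(im) for im in images]

    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(pixels))
        losses = []
        for start in range(0, len(order) - cfg.batch_pairs + 1, cfg.batch_pairs):
            batch = order[start : start + cfg.batch_pairs]
            views = []
            for i in batch:
                vi, vj = make_simclr_views(pixels[i], cfg.augmentation, rng)
                views.extend([vi, vj])  # consecutive pairing (2i, 2i+1)
            x = np.stack(views)[:, None, :, :]
            z = encoder.net.forward(x)
            p = head.forward(z)
            loss, dp = nt_xent_loss_and_grad(p, cfg.tau)
            dz, hgrads = head.backward(dp)
            _, egrads = encoder.net.backward(dz)
            opt_head.step(hgrads, cfg.lr)
            opt_enc.step(egrads, cfg.lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return encoder, head.get_params(), history
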