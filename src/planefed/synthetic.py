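"""Synthetic standard-plane images and Gaussian-mixture embeddings.

The generator emulates the geometry that distinguishes the four fetal
ultrasound standard planes -- abdomen (filled cross-section with a bright
stomach-bubble dot), brain (bright skull ring), femur (elongated bright
bone), thorax (cross-section containing dark cardiac chambers) -- plus the
acquisition-side nuisances a multi-centre federation exhibits: per-client
brightness/contrast offsets, multiplicative speckle noise, and symmetric
label noise at a controllable rate.

Everything is deterministic under a seed so that every downstream stage
(contrastive pretraining, k-NN denoising, prototype voting, federated
training) is testable without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("abdomen", "brain", "femur", "thorax")
N_CLASSES = 4


@dataclass
class LabeledImage:
    """A grayscale image with its class label and federation tags."""

    pixels: np.ndarray  # (H, W) float in [0, 1]
    label: int  # 0 abdomen, 1 brain, 2 femur, 3 thorax
    client: str = ""
    country: str = ""
    split: str = "train"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        h, w = self.pixels.shape
        if h != w or h < 32:
            raise ValueError("images must be square with side >= 32")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.label not in range(N_CLASSES):
            raise ValueError(f"label must be in 0..{N_CLASSES - 1}")
        if self.split not in ("train", "val", "test"):
            raise ValueError("split must be train, val or test")


@dataclass
class NoiseSpec:
    """Symmetric (uniform) label-noise model.

    ``symmetric_exclusive`` replaces each selected label by a uniformly
    chosen *different* class, so the realized noise rate equals the nominal
    rate exactly.  ``symmetric_inclusive`` draws uniformly over all classes
    (possibly re-drawing the original label).
    """

    rate: float
    model: str = "symmetric_exclusive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.model not in ("symmetric_exclusive", "symmetric_inclusive"):
            raise ValueError(f"unknown noise model {self.model!r}")


@dataclass
class ClientShift:
    """Per-client acquisition shift: brightness, contrast, speckle."""

    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    speckle_sigma: float = 0.0


IDENTITY_SHIFT = ClientShift()


@dataclass
class EmbeddingClusterSpec:
    """Gaussian class clusters in a latent space (a stand-in, synthetic
    fixture for the structure a contrastively trained encoder produces)."""

    n_classes: int = 4
    dim: int = 32
    n_per_class: int = 400
    separation: float = 6.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.separation <= 0 or self.sigma <= 0:
            raise ValueError("separation and sigma must be positive")


def apply_client_shift(
    pixels: np.ndarray, shift: ClientShift, rng: np.random.Generator
) -> np.ndarray:
    """Contrast about mid-gray, then brightness, then multiplicative
    speckle; re-clipped to [0, 1]."""
    out = (pixels - 0.5) * shift.contrast_gain + 0.5 + shift.brightness_offset
    if shift.speckle_sigma > 0:
        out = out * (1.0 + shift.speckle_sigma * rng.standard_normal(out.shape))
    return np.clip(out, 0.0, 1.0)


def _ellipse_mask(size, cy, cx, ry, rx, angle):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2


def gen_plane_image(
    label: int,
    shift: ClientShift = IDENTITY_SHIFT,
    rng: np.random.Generator | None = None,
    size: int = 64,
) -> LabeledImage:
    """Draw one class-determined geometric primitive with random
    position/scale jitter on a dim speckled background.

    abdomen: filled bright ellipse with a brighter internal dot;
    brain: bright elliptical ring, dark interior;
    femur: elongated bright bar at a random angle;
    thorax: filled ellipse containing 2-4 dark chamber blobs.
    """
    if label not in range(N_CLASSES):
        raise ValueError(f"unknown label {label!r}")
    if rng is None:
        rng = np.random.default_rng()

    img = 0.08 + 0.04 * rng.random((size, size))
    c0 = size / 2.0
    cy = c0 + rng.uniform(-0.08, 0.08) * size
    cx = c0 + rng.uniform(-0.08, 0.08) * size
    scale = size * rng.uniform(0.26, 0.34)
    angle = rng.uniform(0.0, np.pi)

    if label == 0:  # abdomen: filled ellipse + bright stomach dot
        d = _ellipse_mask(size, cy, cx, scale, 0.85 * scale, angle)
        img[d <= 1.0] = 0.55
        dot = _ellipse_mask(
            size,
            cy + rng.uniform(-0.25, 0.25) * scale,
            cx + rng.uniform(-0.25, 0.25) * scale,
            0.18 * scale,
            0.18 * scale,
            0.0,
        )
        img[dot <= 1.0] = 0.95
    elif label == 1:  # brain: bright skull ring
        d = _ellipse_mask(size, cy, cx, scale, 0.8 * scale, angle)
        img[d <= 1.0] = 0.9
        img[d <= 0.72**2] = 0.2
    elif label == 2:  # femur: thin elongated bright bar
        d = _ellipse_mask(size, cy, cx, 0.12 * scale, 1.35 * scale, angle)
        img[d <= 1.0] = 0.9
    else:  # thorax: filled ellipse with dark chambers
        d = _ellipse_mask(size, cy, cx, scale, 0.9 * scale, angle)
        img[d <= 1.0] = 0.6
        for _ in range(rng.integers(2, 5)):
            ang = rng.uniform(0.0, 2 * np.pi)
            r = rng.uniform(0.15, 0.5) * scale
            ch = _ellipse_mask(
                size,
                cy + r * np.sin(ang),
                cx + r * np.cos(ang),
                0.22 * scale,
                0.22 * scale,
                0.0,
            )
            img[ch <= 1.0] = 0.15

    img = apply_client_shift(img, shift, rng)
    return LabeledImage(pixels=img, label=int(label))


def gen_client_dataset(
    n_per_class: int,
    shift: ClientShift = IDENTITY_SHIFT,
    client: str = "client",
    country: str = "",
    seed: int = 0,
    size: int = 64,
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> list[LabeledImage]:
    """Balanced dataset of ``4 * n_per_class`` images for one client,
    with a deterministic stratified train/val/test split."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    for label in range(N_CLASSES):
        splits = _stratum_splits(n_per_class, split_fractions, rng)
        for i in range(n_per_class):
            im = gen_plane_image(label, shift, rng, size=size)
            im.client = client
            im.country = country
            im.split = splits[i]
            images.append(im)
    return images


def _stratum_splits(n, fractions, rng):
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    rng.shuffle(tags)
    return tags


def inject_label_noise(labels, spec: NoiseSpec) -> np.ndarray:
    """Flip exactly ``round(rate * n)`` labels, chosen without replacement.

    A fixed-size sample (rather than i.i.d. Bernoulli selection) makes the
    realized rate exact, so tests can assert it directly.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    classes = np.unique(labels)
    n_flip = int(round(spec.rate * labels.size))
    if n_flip == 0:
        return labels.copy()
    if spec.model == "symmetric_exclusive" and classes.size < 2:
        raise ValueError("exclusive noise needs at least 2 classes present")
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    noisy = labels.copy()
    if spec.model == "symmetric_exclusive":
        for i in idx:
            others = classes[classes != labels[i]]
            noisy[i] = rng.choice(others)
    else:
        noisy[idx] = rng.choice(classes, size=n_flip)
    return noisy


def gen_embedding_clusters(spec: EmbeddingClusterSpec):
    """Isotropic Gaussian clusters with pairwise-equidistant means.

    Means are placed on mutually orthogonal scaled basis vectors
    (``separation / sqrt(2)`` each), which makes every pairwise mean
    distance exactly ``separation`` when ``dim >= n_classes``.  If the
    dimension is too small for that, basis vectors are reused with growing
    multipliers and the distances are no longer all equal (warned).
    """
    rng = np.random.default_rng(spec.seed)
    means = np.zeros((spec.n_classes, spec.dim))
    r = spec.separation / np.sqrt(2.0)
    if spec.dim >= spec.n_classes:
        for c in range(spec.n_classes):
            means[c, c] = r
    else:
        warnings.warn(
            "dim < n_classes: falling back to reused basis directions; "
            "pairwise mean distances are no longer all equal",
            stacklevel=2,
        )
        for c in range(spec.n_classes):
            means[c, c % spec.dim] = r * (1 + c // spec.dim)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    X = means[labels] + spec.sigma * rng.standard_normal((labels.size, spec.dim))
    return X, labels
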