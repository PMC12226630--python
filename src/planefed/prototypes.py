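"""Class prototypes and augmented-view majority-vote pseudo-labeling.

A prototype p_c is the arithmetic mean of the clean class-c embeddings of
the representative client.  Sharing only the prototypes (n_classes x
embedding_dim numbers) plus the encoder keeps the federation
privacy-compliant: no per-sample data crosses clients.

The small client discards its own labels entirely.  Each of its images x
is expanded into T views {R_1(x)=x, R_2(x), ..., R_T(x)} (R_1 is the
identity), every view is embedded and votes for its nearest prototype's
class, and the majority class becomes the pseudo-label.  Voting is
unthresholded -- every sample receives a label, nothing is discarded --
because a small client cannot afford to lose images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contrastive import AugmentationSpec, Encoder, augment_image, embed


@dataclass
class Prototype:
    class_id: int
    vector: np.ndarray


@dataclass
class ViewEnsembleConfig:
    T: int = 8
    aug: AugmentationSpec = field(default_factory=AugmentationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class VoteRecord:
    view_classes: np.ndarray  # per-view assigned class
    final_label: int
    vote_counts: np.ndarray  # per class id present in the prototype set
    class_ids: np.ndarray  # class ids the counts refer to
    mean_winner_distance: float


def compute_prototypes(embeddings, labels) -> list[Prototype]:
    """Per-class mean embedding; classes absent from the input are absent
    from the output (warned)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if embeddings.size == 0:
        raise ValueError("empty input")
    present = np.unique(labels)
    expected = np.arange(labels.max() + 1)
    missing = np.setdiff1d(expected, present)
    if missing.size:
        warnings.warn(f"classes {missing.tolist()} have no members; omitted", stacklevel=2)
    return [
        Prototype(int(c), embeddings[labels == c].mean(axis=0)) for c in present
    ]


def prototype_matrix(protos: list[Prototype]):
    """(class_ids, matrix) sorted by class id."""
    protos = sorted(protos, key=lambda p: p.class_id)
    ids = np.array([p.class_id for p in protos])
    return ids, np.stack([p.vector for p in protos])


def nearest_prototype(z, protos: list[Prototype]):
    """(class id, Euclidean distance) of the closest prototype; ties go to
    the lowest class id."""
    if not protos:
        raise ValueError("empty prototype list")
    ids, mat = prototype_matrix(protos)
    d = np.linalg.norm(mat - np.asarray(z, dtype=np.float64), axis=1)
    i = int(np.argmin(d))  # argmin returns first minimum -> lowest class id
    return int(ids[i]), float(d[i])


def label_by_view_ensemble(
    image,
    encoder: Encoder,
    protos: list[Prototype],
    cfg: ViewEnsembleConfig,
    rng: np.random.Generator | None = None,
) -> VoteRecord:
    """Majority vote of per-view nearest-prototype assignments.

    Vote ties are broken by the smallest summed distance from the tied
    class's supporting views to that class's prototype, then by lowest
    class id.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    views = [pixels] + [
        augment_image(pixels, cfg.aug, rng) for _ in range(cfg.T - 1)
    ]
    z = embed(encoder, views)
    ids, mat = prototype_matrix(protos)
    # (T, n_protos) distances
    d = np.linalg.norm(z[:, None, :] - mat[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)
    view_classes = ids[assign]

    counts = np.array([(assign == j).sum() for j in range(len(ids))])
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        sums = [d[assign == j, j].sum() for j in tied]
        winner = int(tied[int(np.argmin(sums))])  # argmin -> lowest id on tie
    else:
        winner = int(tied[0])
    mean_dist = float(d[assign == winner, winner].mean()) if best else float("nan")
    return VoteRecord(
        view_classes=view_classes,
        final_label=int(ids[winner]),
        vote_counts=counts,
        class_ids=ids,
        mean_winner_distance=mean_dist,
    )


def label_client(
    dataset,
    encoder: Encoder,
    protos: list[Prototype],
    cfg: ViewEnsembleConfig,
):
    """Pseudo-label every sample of a client (no discards); the dataset's
    own label field is never read."""
    rng = np.random.default_rng(cfg.seed)
    records = [
        label_by_view_ensemble(im, encoder, protos, cfg, rng) for im in dataset
    ]
    labels = np.array([r.final_label for r in records], dtype=np.int64)
    return labels, records
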