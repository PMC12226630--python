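"""Per-country macro-F1 metrics and the ablation experiment harness.

The experiment grid compares training strategies for a two-client
federation in which the large client (``repr``) has noisy labels it can
denoise contrastively, and the small client (``norepr``) has labels so
unreliable they are discarded outright:

- ``local_train``    each client trains alone on its own (noisy) labels;
- ``simple_fl``      FedAvg on raw noisy labels, no denoising;
- ``baseline``       repr denoised; norepr keeps its noisy labels;
- ``proto_baseline`` baseline + norepr relabeled by single-view
                     nearest-prototype assignment;
- ``proto_views``    no federation: train on the denoised repr only,
                     classify norepr by view-ensemble prototype voting;
- ``proposed``       repr denoised + norepr pseudo-labeled by the view
                     ensemble + FedAvg (the full framework);
- ``pretrained_weights`` train on the denoised repr only, evaluate the
                     model directly on every country.

Scores are one-vs-rest F1 per class and unweighted macro-F1, reported per
country on that country's test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import federated
from .contrastive import ContrastiveConfig, Encoder, embed, pretrain_encoder
from .denoising import DenoiseConfig, knn_consensus_filter
from .federated import ClientState, FederationConfig, build_classifier, init_from_backbone
from .prototypes import ViewEnsembleConfig, compute_prototypes, label_client
from .synthetic import N_CLASSES, CLASS_NAMES, LabeledImage, NoiseSpec, inject_label_noise

EXPERIMENT_MODES = (
    "local_train",
    "simple_fl",
    "baseline",
    "proto_baseline",
    "proto_views",
    "proposed",
    "pretrained_weights",
)

_PRETRAIN_MODES = frozenset(
    {"baseline", "proto_baseline", "proto_views", "proposed", "pretrained_weights"}
)


def f1_scores(predictions, truth, n_classes: int = N_CLASSES):
    """One-vs-rest F1 per class and unweighted macro-F1.

    A class absent from both predictions and truth is excluded from the
    macro mean; a class present but never predicted correctly scores 0.
    """
    predictions = np.asarray(predictions, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if len(predictions) != len(truth) or len(truth) == 0:
        raise ValueError("predictions and truth must have equal positive length")
    per_class = np.zeros(n_classes)
    included = []
    for c in range(n_classes):
        tp = int(np.sum((predictions == c) & (truth == c)))
        fp = int(np.sum((predictions == c) & (truth != c)))
        fn = int(np.sum((predictions != c) & (truth == c)))
        if tp + fp + fn == 0:
            continue  # absent from both sides
        per_class[c] = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        included.append(c)
    macro = float(per_class[included].mean()) if included else 0.0
    return per_class, macro


@dataclass
class ExperimentConfig:
    """Bundle of stage configurations shared by all modes of one grid."""

    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    views: ViewEnsembleConfig = field(default_factory=ViewEnsembleConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)


def _split(images: list[LabeledImage], split: str):
    sel = [im for im in images if im.split == split]
    pixels = np.stack([im.pixels for im in sel]) if sel else np.empty((0, 0, 0))
    labels = np.array([im.label for im in sel], dtype=np.int64)
    countries = np.array([im.country for im in sel])
    return pixels, labels, countries


def _noisy(labels: np.ndarray, rate: float, seed: int) -> np.ndarray:
    if rate == 0.0 or labels.size == 0:
        return labels.copy()
    return inject_label_noise(labels, NoiseSpec(rate=rate, seed=seed))


def run_experiment(
    mode: str,
    datasets: dict[str, list[LabeledImage]],
    noise_repr: float = 0.2,
    noise_norepr: float = 0.2,
    cfg: ExperimentConfig | None = None,
    seed: int = 0,
    encoder: Encoder | None = None,
) -> pd.DataFrame:
    """Run one experiment mode end to end and score every country's test
    split.  ``datasets`` maps {"repr": images, "norepr": images}.

    A pretrained ``encoder`` may be passed in to share the contrastive
    stage across modes of the same grid; otherwise modes that need one
    pretrain it here on the repr client's training images.
    """
    if mode not in EXPERIMENT_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {EXPERIMENT_MODES}")
    if set(datasets) != {"repr", "norepr"}:
        raise ValueError("datasets must have exactly the keys 'repr' and 'norepr'")
    cfg = cfg or ExperimentConfig()
    ss = np.random.SeedSequence([seed, 7])
    noise_seed_repr, noise_seed_norepr = [int(s) for s in ss.generate_state(2) % (2**31)]

    rx, ry, _ = _split(datasets["repr"], "train")
    nx, ny, _ = _split(datasets["norepr"], "train")
    if rx.size == 0 or nx.size == 0:
        raise ValueError("both clients need non-empty training splits")
    ry_noisy = _noisy(ry, noise_repr, noise_seed_repr)
    ny_noisy = _noisy(ny, noise_norepr, noise_seed_norepr)

    fed_cfg = cfg.federation
    if fed_cfg.seed != seed:
        fed_cfg = FederationConfig(**{**fed_cfg.__dict__, "seed": seed})

    # --- contrastive stage (self-supervised, repr client only) ---
    protos = None
    backbone = None
    if mode in _PRETRAIN_MODES:
        if encoder is None:
            ccfg = cfg.contrastive
            if ccfg.seed != seed:
                ccfg = ContrastiveConfig(**{**ccfg.__dict__, "seed": seed})
            encoder, _, _ = pretrain_encoder(list(rx), ccfg)
        if encoder.embedding_dim != fed_cfg.embedding_dim:
            raise ValueError(
                "encoder embedding_dim must match federation.embedding_dim "
                f"({encoder.embedding_dim} != {fed_cfg.embedding_dim})"
            )
        backbone = encoder.get_params()
        z = embed(encoder, list(rx))
        den = knn_consensus_filter(z, ry_noisy, cfg.denoise)
        rx_clean, ry_clean = rx[den.kept_mask], den.labels_out
        protos = compute_prototypes(z[den.kept_mask], ry_clean)

    def fresh_model(use_backbone: bool):
        model = build_classifier(fed_cfg.embedding_dim, fed_cfg.n_classes, seed=seed)
        if use_backbone:
            init_from_backbone(model, backbone)
        return model.get_params()

    # --- assemble clients and train, per mode ---
    if mode == "local_train":
        params_repr, _ = federated.run_federation(
            [ClientState("repr", rx, ry_noisy)], fresh_model(False), fed_cfg
        )
        params_norepr, _ = federated.run_federation(
            [ClientState("norepr", nx, ny_noisy)], fresh_model(False), fed_cfg
        )
        models = {"repr": params_repr, "norepr": params_norepr}
    elif mode == "simple_fl":
        params, _ = federated.run_federation(
            [ClientState("repr", rx, ry_noisy), ClientState("norepr", nx, ny_noisy)],
            fresh_model(False),
            fed_cfg,
        )
        models = {"repr": params, "norepr": params}
    elif mode in ("baseline", "proto_baseline", "proposed"):
        if mode == "baseline":
            norepr_labels = ny_noisy
        else:
            vcfg = cfg.views
            if mode == "proto_baseline":
                vcfg = ViewEnsembleConfig(T=1, aug=vcfg.aug, seed=seed)
            elif vcfg.seed != seed:
                vcfg = ViewEnsembleConfig(T=vcfg.T, aug=vcfg.aug, seed=seed)
            norepr_labels, _ = label_client(list(nx), encoder, protos, vcfg)
        params, _ = federated.run_federation(
            [
                ClientState("repr", rx_clean, ry_clean),
                ClientState("norepr", nx, norepr_labels),
            ],
            fresh_model(True),
            fed_cfg,
        )
        models = {"repr": params, "norepr": params}
    elif mode in ("proto_views", "pretrained_weights"):
        params, _ = federated.run_federation(
            [ClientState("repr", rx_clean, ry_clean)], fresh_model(True), fed_cfg
        )
        models = {"repr": params, "norepr": params}
    else:  # pragma: no cover
        raise AssertionError(mode)

    # --- evaluate every country's test split ---
    rows = []
    for side in ("repr", "norepr"):
        tx, ty, tc = _split(datasets[side], "test")
        if ty.size == 0:
            continue
        if mode == "proto_views" and side == "norepr":
            vcfg = cfg.views
            if vcfg.seed != seed:
                vcfg = ViewEnsembleConfig(T=vcfg.T, aug=vcfg.aug, seed=seed)
            preds, _ = label_client(list(tx), encoder, protos, vcfg)
        else:
            preds = federated.predict(models[side], tx, fed_cfg)
        for country in pd.unique(tc):
            m = tc == country
            per_class, macro = f1_scores(preds[m], ty[m], fed_cfg.n_classes)
            row = {
                "mode": mode,
                "noise_repr": noise_repr,
                "noise_norepr": noise_norepr,
                "country": country,
            }
            row.update({f"f1_{name}": per_class[i] for i, name in enumerate(CLASS_NAMES)})
            row["macro_f1"] = macro
            rows.append(row)
    return pd.DataFrame(rows)


def federation_mean(table: pd.DataFrame) -> float:
    """Unweighted mean of macro-F1 over the countries of one table."""
    return float(table["macro_f1"].mean())


def report(tables: list[pd.DataFrame], baseline_mode: str = "baseline"):
    """Side-by-side per-country comparison with a delta-vs-baseline column.

    Returns (summary DataFrame, formatted text table).
    """
    if not tables:
        raise ValueError("no tables to report")
    keys = [tuple(sorted(t["country"])) for t in tables]
    if len(set(keys)) != 1:
        raise ValueError("tables do not share country keys")
    rows = []
    for t in tables:
        entry = {"mode": t["mode"].iloc[0]}
        for _, r in t.iterrows():
            entry[r["country"]] = r["macro_f1"]
        entry["mean"] = federation_mean(t)
        rows.append(entry)
    summary = pd.DataFrame(rows)
    base = summary.loc[summary["mode"] == baseline_mode, "mean"]
    if base.empty:
        raise ValueError(f"baseline mode {baseline_mode!r} not among tables")
    summary["delta_vs_baseline"] = summary["mean"] - float(base.iloc[0])
    text = summary.to_string(index=False, float_format=lambda v: f"{v:.4f}")
    return summary, text
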