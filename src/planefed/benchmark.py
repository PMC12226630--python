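"""Desk-scale benchmark conditions shared by the test suite and the
reproduction script.

The end-to-end benchmark emulates the target setting at desk scale: a
representative client roughly ten times larger than the small one
(2000 vs 200 images, the size imbalance typical of multi-centre
federations), 64x64 images, four classes, per-client acquisition shift,
20% symmetric label noise on both clients, contrastive pretraining on
the large client, and a 3-round x 5-epoch federation.
"""

from __future__ import annotations

import numpy as np

from .contrastive import ContrastiveConfig, pretrain_encoder
from .denoising import DenoiseConfig
from .evaluation import ExperimentConfig, federation_mean, run_experiment
from .federated import FederationConfig
from .prototypes import ViewEnsembleConfig
from .synthetic import ClientShift, gen_client_dataset

REPR_N_PER_CLASS = 500  # 2000 images
NOREPR_N_PER_CLASS = 50  # 200 images
NOREPR_SHIFT = ClientShift(brightness_offset=0.08, contrast_gain=1.2, speckle_sigma=0.15)
NOISE_RATE = 0.2


def benchmark_datasets(seed: int):
    return {
        "repr": gen_client_dataset(
            REPR_N_PER_CLASS, client="repr", country="countryA", seed=seed
        ),
        "norepr": gen_client_dataset(
            NOREPR_N_PER_CLASS,
            NOREPR_SHIFT,
            client="norepr",
            country="countryB",
            seed=seed + 1,
        ),
    }


def benchmark_config(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        contrastive=ContrastiveConfig(epochs=15, batch_pairs=64, lr=0.1, seed=seed),
        denoise=DenoiseConfig(k=50, th=40),
        views=ViewEnsembleConfig(T=8, seed=seed),
        federation=FederationConfig(rounds=3, local_epochs=5, seed=seed),
    )


def run_mode_comparison(seed: int, modes=("simple_fl", "baseline", "proposed")):
    """Federation-mean macro-F1 per mode under shared data and seed; the
    contrastive stage is pretrained once and shared by the modes that use
    it."""
    datasets = benchmark_datasets(seed)
    cfg = benchmark_config(seed)
    encoder = None
    needs_encoder = {"baseline", "proto_baseline", "proto_views", "proposed", "pretrained_weights"}
    if needs_encoder & set(modes):
        rx = [im.pixels for im in datasets["repr"] if im.split == "train"]
        encoder, _, _ = pretrain_encoder(rx, cfg.contrastive)
    scores = {}
    for mode in modes:
        table = run_experiment(
            mode,
            datasets,
            noise_repr=NOISE_RATE,
            noise_norepr=NOISE_RATE,
            cfg=cfg,
            seed=seed,
            encoder=encoder if mode in needs_encoder else None,
        )
        scores[mode] = federation_mean(table)
    return scores
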