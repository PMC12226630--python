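# planefed

Federated learning for fetal-ultrasound standard-plane classification with
noisy labels: contrastive label denoising on the large client, prototype
pseudo-labeling on the small one, FedAvg in between.

## The problem

Multi-centre fetal ultrasound studies want one model that classifies the
four biometric standard planes (abdomen, brain, femur, thorax), but the
participating sites cannot pool images, their datasets differ in size by an
order of magnitude, and their labels are unreliable. Plain federated
averaging (FedAvg) treats every label as trustworthy, so a small client
with noisy labels both learns badly and pollutes the global model.

`planefed` implements a two-step remedy for a federation with one large,
representative client `S_repr` and one small client `S_norepr`:

1. **Denoise the large client in embedding space.** A SimCLR-style
   encoder f(·) is pretrained self-supervisedly on `S_repr` with the
   NT-Xent loss

   L_i = −log [ exp(sim(z_i, z_j)/τ) / Σ_{r≠i} exp(sim(z_i, z_r)/τ) ],

   with τ = 0.5 and cosine similarity on projection-head outputs. In the
   resulting latent space each sample's k = 50 nearest neighbours
   (Euclidean distance) vote on its label: a sample is kept only if at
   least th = 40% of its neighbours share its current label, otherwise it
   is discarded.

2. **Pseudo-label the small client with shared prototypes.** The class
   prototypes p_c — the mean of the clean class-c embeddings — and the
   encoder parameters (never any image or per-sample datum) are shared
   with `S_norepr`, whose own labels are discarded outright. Each of its
   images is expanded into T = 8 augmented views (identity + random
   flips/rotations/shifts/brightness/contrast), every view votes for the
   class of its nearest prototype, and the majority class becomes the
   training label. Voting is unthresholded: no image is wasted.

Both clients then train jointly — SGD with momentum, cross-entropy with
mixup (α = 0.5), a cosine-annealing warm-restart schedule (0.05 → 1e-5
within each round) — and the server aggregates with sample-count-weighted
FedAvg. The final model is the round with the lowest mean validation loss.

No deep-learning framework is required: the encoder (a small strided
convolutional network), its gradients, and the optimizer are implemented
directly in NumPy, which keeps every run bit-reproducible under a seed.
Everything runs on synthetic data from the built-in generator — toy
"standard planes" whose geometry mimics what separates the real ones
(ring vs filled ellipse vs elongated bar vs chambered ellipse) with
per-client brightness/contrast/speckle shift and injectable symmetric
label noise — so the whole pipeline is testable on a laptop CPU.

## Worked example

```bash
planefed pipeline --config configs/desk.yaml --out demo_run
```

runs the full chain (simulate two shifted clients at a 10:1 size ratio
with 20% symmetric label noise on both → contrastive pretraining →
k-NN consensus denoising → prototypes → view-ensemble pseudo-labeling →
3 federated rounds) in under a minute and prints per-country test scores:

```
    mode  noise_repr  noise_norepr  country  f1_abdomen  f1_brain  f1_femur  f1_thorax  macro_f1
proposed         0.2           0.2 countryA    0.857143       1.0       1.0   0.888889  0.936508
proposed         0.2           0.2 countryB    0.800000       1.0       1.0   0.857143  0.914286
```

Each row is one country's held-out test split; `macro_f1` is the
unweighted mean of the per-class F1 scores. countryA is the large client;
countryB is the small client whose labels were never used — its 0.91
macro-F1 comes entirely from prototype pseudo-labels.

The individual stages are also available as subcommands
(`simulate-data`, `pretrain`, `denoise`, `sweep-th`, `make-prototypes`,
`pseudo-label`, `run-fl`, `evaluate`, `ablation`) and as plain library
functions (`planefed.knn_consensus_filter`, `planefed.fedavg`, ...).

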