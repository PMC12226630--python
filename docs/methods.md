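# Methods

## Setting and notation

A federation holds two clients with very different sizes: a
representative client `S_repr` and a small client `S_norepr` at roughly a
10:1 ratio. Images are single-channel grayscale in [0, 1]; the label
vocabulary is the four fetal standard planes {abdomen, brain, femur,
thorax}. Labels on `S_repr` are noisy at an unknown rate; labels on
`S_norepr` are considered unusable and discarded. The pipeline is:
contrastive pretraining on `S_repr` → k-NN consensus label cleaning on
`S_repr` → prototype + encoder sharing → view-ensemble pseudo-labeling of
`S_norepr` → federated supervised training with FedAvg.

## Contrastive pretraining

The encoder f(·) maps an image to an embedding z. Two random views of
each image in a batch of N images are embedded and passed through a
projection head (linear → ReLU → linear); the NT-Xent loss over the 2N
projections, averaged over all 2N anchors, is

    L_i = −log [ exp(sim(z_i, z_j)/τ) / Σ_{r≠i} exp(sim(z_i, z_r)/τ) ]

with cosine similarity and temperature τ = 0.5. The implementation is
evaluated with a log-sum-exp-stable form and an analytic gradient through
the cosine normalization; tests check it against a plain double-loop
enumeration oracle at 1e-6.

Downstream stages (denoising, prototypes) consume the **backbone**
embeddings, not the projection-head outputs; the head exists only for the
loss.

The reference-scale configuration is a ResNet-50 backbone with
2048-dimensional embeddings and batch 256 on GPUs. This package targets
desk scale on one CPU: the default `tinycnn` backbone is three strided
3×3 convolution blocks (8, 16, 32 channels, stride 2) with ReLU, global
average pooling and a linear map to a 64-dimensional embedding. All
layers, gradients and the SGD-with-momentum optimizer are NumPy
(float64), which makes every run bit-reproducible under a seed. A
`resnet50` architecture id is accepted in configs but reports itself as
unavailable in this build.

Free parameters of the pretraining recipe (the reference recipe fixes
only τ and the augmentation family): learning rate 0.1, momentum 0.9,
batch 32–64 pairs, 5–15 epochs at desk scale. These were calibrated once
on the synthetic generator so that the encoder separates the four classes
(nearest-centroid accuracy in embedding space ≳ 0.95); higher learning
rates collapse the representation (the loss pins at log(2N−1)).

## k-NN consensus denoising

For each sample of `S_repr`, its k = 50 nearest *other* samples by
Euclidean distance in embedding space are found (self excluded — including
self would inflate consensus by 1/k uniformly). With consensus threshold
th = 40 (percent), `consensus_keep` mode keeps a sample iff at least
th% of its neighbours share its current label; labels are never altered,
only dropped. `relabel_majority` mode instead keeps a sample when the
neighbourhood's plurality class reaches th% of k and replaces the label
with that plurality class; it exists as a config option, but
`consensus_keep` is the default used in all experiments.

Numerical choices: exact neighbour search (cdist + stable argsort);
distance ties break toward the lower original index, which makes the
filter deterministic and permutation-equivariant. Embeddings are used
raw, without L2 normalization, matching the Euclidean-distance
specification of the consensus rule.

`threshold_sweep` reproduces the threshold-selection procedure: for each
(th, noise rate) it injects symmetric noise, filters, and reports the
percentage of preserved samples and the residual noise among them. The
keep-rule tightens monotonically in th, so preserved% is non-increasing —
a property the tests assert across th ∈ {40, 50, 60, 70} and noise
∈ {0%, 20%, 50%}.

## Prototypes and view-ensemble pseudo-labeling

The prototype of class c is the arithmetic mean p_c of the clean class-c
embeddings. Sharing {p_c} plus the encoder parameters transmits exactly
n_classes × embedding_dim numbers and no per-sample data, which is the
privacy contract of the federation (asserted in tests).

Each `S_norepr` image x is expanded into T = 8 views {R_1(x) = x,
R_2(x), …, R_T(x)} — the first view is always the identity — using the
same augmentation family as training: horizontal flips, rotations up to
15°, shifts up to 12 px, brightness and contrast in [0.7, 1.3]. Every
view is embedded and votes for its nearest prototype's class; the
majority class is the pseudo-label. Voting is unthresholded: every image
receives a label. T is a free parameter (the ensemble size is not pinned
by the reference recipe); 8 balances vote stability against embedding
cost.

Tie-breaks are deterministic: a vote tie goes to the class whose
supporting views have the smallest summed distance to that class's
prototype, then to the lowest class id. Nearest-prototype ties go to the
lowest class id.

## Federated training

Local training is SGD with momentum 0.9 on cross-entropy, batch 16, with
mixup regularization (α = 0.5: each batch is convexly combined with a
shuffled copy of itself, labels as one-hot mixtures). The learning rate
follows cosine annealing with warm restarts: lr(e) = lr_min + ½(lr_init −
lr_min)(1 + cos(π (e mod E)/E)) with lr_init = 0.05, lr_min = 1e-5 and
cycle length E = the local epochs per round, so the rate anneals within
each communication round and restarts at the next. Weight decay is not
used. Gradients are clipped to a global L2 norm of 1 before each update;
without clipping, the first supervised steps on top of a pretrained
backbone are large enough to push every ReLU into the dead regime, after
which training cannot recover.

FedAvg aggregates client updates as the sample-count-weighted elementwise
mean (weights n_k/Σn, client sizes counted after denoising or
pseudo-labeling). Each client holds out a stratified 20% of its training
samples for validation; the returned model is the round with the lowest
mean validation loss. The reference recipe is 5 rounds × 20 local
epochs; desk-scale runs use 3 × 5 with the same schedule shape.

Determinism: every local-training stream is seeded by (federation seed,
round index, CRC-32 of the client id), so runs are bit-for-bit
reproducible, a single-client federation is bitwise identical to
centralized training of that client, and identical clients aggregate to
their own parameters.

## Experiment modes

- `local_train` — each client trains alone on its own (noisy) labels.
- `simple_fl` — FedAvg over both clients with raw noisy labels.
- `baseline` — `S_repr` denoised; `S_norepr` keeps its noisy labels.
- `proto_baseline` — baseline + `S_norepr` relabeled by single-view
  nearest-prototype assignment (T = 1).
- `proto_views` — no federation: train on the denoised `S_repr` only and
  classify the `S_norepr` test split directly by view-ensemble voting.
- `proposed` — denoising + view-ensemble pseudo-labels + FedAvg.
- `pretrained_weights` — train on the denoised `S_repr` only; evaluate
  the model on every country.

Scores are one-vs-rest F1 per class and unweighted macro-F1, computed per
country on that country's test split; a class absent from both
predictions and truth is excluded from the macro mean, and a class
present but with zero precision+recall scores 0.

## The synthetic generator

Real multi-centre ultrasound data cannot ship with a desk-scale package,
so the generator emulates the features the method actually exploits:

- **Class geometry.** Abdomen: filled ellipse with a bright internal dot;
  brain: bright elliptical ring; femur: thin elongated bar at random
  angle; thorax: filled ellipse with 2–4 dark chamber blobs. Position,
  scale and orientation jitter per image. These mirror the geometric cues
  that distinguish the real planes (roundness of the skull, the straight
  femur line, cardiac chambers).
- **Client shift.** Additive brightness, multiplicative contrast about
  mid-gray, multiplicative speckle noise, re-clipped to [0, 1]. The
  small client's default shift (+0.08 brightness, ×1.2 contrast, 0.15
  speckle) was chosen once so that the cross-client distribution shift is
  visible to the pipeline (pseudo-labeling is measurably harder on the
  shifted client) without being insurmountable.
- **Label noise.** Symmetric noise selects exactly round(rate·n)
  positions without replacement and replaces each selected label with a
  uniformly chosen *different* class (`symmetric_exclusive`), so the
  realized rate equals the nominal rate exactly and tests can assert it;
  the `symmetric_inclusive` convention (uniform over all classes) is
  retained as an option.
- **Latent-space fixture.** `gen_embedding_clusters` draws isotropic
  Gaussian clusters with pairwise-equidistant means (orthogonal scaled
  basis construction, exact when dim ≥ n_classes) as a controlled
  stand-in for a trained encoder's latent space; the denoising and
  prototype stages are additionally tested on it independently of any
  encoder. At the default separation of 6σ the nearest-true-mean error
  rate is 3·Φ(−3) ≈ 0.4% (the decision margin between two means 6σ apart
  is 3σ).

What passing tests on this generator do **not** show: robustness to real
speckle physics, probe-specific artifacts, anatomical variability,
class-dependent (asymmetric) noise, or any claim about the absolute F1
attainable on clinical data. The synthetic benchmark supports the
*qualitative* claims — the filter removes injected noise, prototypes
transfer across a moderate acquisition shift, and the full framework is
at least as good as plain FedAvg under label noise — not any absolute
performance level on clinical data, which requires real multi-centre
cohorts and GPU-scale training.

## Benchmark conditions

The end-to-end benchmark (`planefed.benchmark`) fixes: 2000 vs 200
images (500/50 per class, the ~10:1 imbalance typical of multi-centre
federations), 64×64 pixels, 20% symmetric-exclusive noise on both clients,
contrastive pretraining for 15 epochs at 64 pairs/batch, k = 50, th = 40,
T = 8, and a 3-round × 5-epoch federation — sizes chosen so a full
three-mode comparison runs in ~2 minutes on one CPU. Under these
conditions the expected ordering (proposed ≥ simple_fl and proposed ≥
baseline, by federation-mean macro-F1) holds in at least 4 of 5 paired
seeds; near the performance ceiling individual seeds can tie or differ by
a single test image.

## Known limitations

- Only the `tinycnn` backbone is runnable; ResNet-50-scale training is
  out of reach without a GPU framework.
- Exact O(n²) neighbour search; fine at desk scale, not for 10⁵ samples.
- The federation is simulated in-process: no transport, client dropout,
  secure aggregation, or differential privacy.
- Aggregation is FedAvg only (no FedProx/SCAFFOLD/FedRoD).
- Asymmetric/class-dependent label noise is not modeled.
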