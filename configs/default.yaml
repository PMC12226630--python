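# Reference-scale training recipe; data sizes are the desk-scale synthetic
# two-client layout (repr : norepr ~ 10 : 1).
mode: proposed
seed: 0
noise_repr: 0.2
noise_norepr: 0.2
data:
  repr_n_per_class: 500
  norepr_n_per_class: 50
  image_size: 64
contrastive:
  tau: 0.5
  batch_pairs: 32
  embedding_dim: 64
  epochs: 5
denoise:
  k: 50
  th: 40
views:
  T: 8
federation:
  rounds: 5
  local_epochs: 20
  batch_size: 16
  lr_init: 0.05
  lr_min: 1.0e-5
  mixup_alpha: 0.5
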