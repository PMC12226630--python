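# Quick desk-scale demo: small clients, short federation (~2 min on CPU).
mode: proposed
seed: 0
noise_repr: 0.2
noise_norepr: 0.2
data:
  repr_n_per_class: 100
  norepr_n_per_class: 15
  image_size: 64
contrastive:
  tau: 0.5
  batch_pairs: 32
  embedding_dim: 64
  epochs: 10
denoise:
  k: 25
  th: 40
views:
  T: 8
federation:
  rounds: 3
  local_epochs: 5
  batch_size: 16
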