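# Default pipeline configuration. Model and optimizer values are the
# published defaults; the simulate block is the desk-scale benchmark.
#
# Hyperparameter sweeps (e.g. L in {1,2,4,8,16,32,64} or K in 1..5) are run
# by editing `model.L` / `model.K` here and re-invoking `circnet evaluate`.

simulate:
  n_genes: 2000
  pos_fraction: 0.5
  exon_count_range: [2, 6]
  exon_len_range: [20, 40]
  intron_len_range: [20, 60]
  acceptor_motif: TTTCAG
  donor_motif: GTAAGT
  motif_mutation_prob: 0.1
  gc: 0.5
  duplication_fraction: 0.0

model:
  K: 3          # k-mer size
  l: 128        # k-mer embedding dimension
  L: 4          # flanking-window length
  h: 128        # GRU hidden size per direction
  a_dim: 16     # attention-vector size
  f_dim: 128    # pre-output hidden units
  lambda_l2: 1.0e-3

train:
  learning_rate: 1.0e-3
  beta1: 0.9
  beta2: 0.999
  amsgrad: true
  batch_size: 64
  lambda_l2: 1.0e-3
  max_epochs: 100
  patience: 5
  val_fraction: 0.1
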