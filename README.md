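# circnet

Attention-based circular-RNA prediction from splice-junction flanking
sequence, with zero-shot backsplice-pair discovery.

Given a gene (or isoform) sequence and its exon boundaries, the model encodes
a short flanking window around every acceptor and donor junction with k-mer
embeddings and bidirectional GRUs, lets the two junction families attend to
each other with single-head dot-product cross-attention, pools each side with
a second attention layer, and predicts a circRNA probability. Because every
aggregation step is an explicit attention distribution, a trained classifier
yields a joint distribution over (donor, acceptor) pairs —
`P(d_j, a_i) = gamma_d[j] * beta_d[j, i]` — that ranks candidate backsplice
junction pairs without ever training on pair annotations.

The network, its gradients and the AMSGrad optimizer are implemented in pure
NumPy on a small reverse-mode autodiff core (`circnet.autograd`), so the
package has no deep-learning-framework dependency and runs deterministically
on a single CPU.

## Command-line usage

All subcommands accept `--seed` and write a `*.manifest.json` (command,
config, seed, versions, wall time) beside every output.

```bash
# 1. generate a synthetic benchmark: sim.jsonl + sim.fa
circnet simulate --config configs/default.yaml --seed 7 --out-prefix out/sim

# 2. train a classifier (checkpoint + per-epoch JSONL log)
circnet train --dataset out/sim.jsonl --fasta out/sim.fa \
    --config configs/default.yaml --seed 7 --checkpoint out/model.ckpt

# 3. score records
circnet predict --dataset out/sim.jsonl --fasta out/sim.fa \
    --checkpoint out/model.ckpt --out out/predictions.tsv

# 4. rank (donor, acceptor) backsplice candidates from attention weights
circnet discover --dataset out/sim.jsonl --fasta out/sim.fa \
    --checkpoint out/model.ckpt --bedpe-top-k 1 --out out/pairs.tsv

# 5. grouped 5-fold cross-validation with per-fold and mean +/- sd metrics
circnet evaluate --dataset out/sim.jsonl --fasta out/sim.fa \
    --config configs/default.yaml --folds 5 --seed 7 --out out/metrics.tsv
```

Inputs can also be BED12 transcript structures against a chromosome FASTA
(`--bed --fasta chroms.fa`); minus-strand entries are reverse-complemented at
load time so the model always sees the transcribed strand.

## Data formats

- **JSONL dataset** — one object per line: `id`, `exons` (0-based half-open
  `[start, end)` intervals on the record sequence), optional `sequence`
  (else looked up by `id` in the companion FASTA), optional `label` (1 =
  circRNA), `group` (paralog cluster for grouped CV) and `true_pair`
  (`[donor_ordinal, acceptor_ordinal]`, 0-based; simulation ground truth).
- Internally exons are 1-based inclusive `(a, d)` with `a` the first and `d`
  the last exonic base. Flanking windows span
  `center - floor((L-1)/2) .. center + floor(L/2)`; k-mers that cross a
  sequence boundary or an `N` map to one reserved padding embedding.
- Prediction output is TSV `id / score / call` with `call = 1` iff
  `score > threshold` (strict).
- Discovery output is TSV
  `record_id / donor_ordinal / acceptor_ordinal / donor_pos / acceptor_pos /
  score / rank` (+ optional BEDPE of top-k pairs).

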