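"""Seeded synthetic genes with known labels and known backsplice pairs.

Positive genes carry an acceptor motif and a donor motif overwritten at the
junctions of one upstream-directed (acceptor exon i, donor exon j) pair with
i <= j; negatives are pure background. Everything is determined by the seed,
so the generator doubles as a reproducible end-to-end test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Dataset, GeneRecord

__all__ = ["SimConfig", "simulate_dataset", "null_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    pos_fraction: float = 0.5
    exon_count_range: tuple[int, int] = (2, 6)
    exon_len_range: tuple[int, int] = (20, 40)
    intron_len_range: tuple[int, int] = (20, 60)
    acceptor_motif: str = "TTTCAG"
    donor_motif: str = "GTAAGT"
    motif_mutation_prob: float = 0.0
    gc: float = 0.5
    duplication_fraction: float = 0.0   # fraction of genes copied into their group
    duplication_mutation_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.pos_fraction <= 1.0):
            raise ValueError("pos_fraction must be in [0,1]")
        for name in ("exon_count_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive (min,max) range")
        for motif in (self.acceptor_motif, self.donor_motif):
            if not motif or set(motif) - set("ACGT"):
                raise ValueError("motifs must be non-empty strings over ACGT")
            if len(motif) > self.exon_len_range[0]:
                raise ValueError("motifs must be shorter than the minimum exon length")
        if not (0.0 <= self.motif_mutation_prob <= 1.0):
            raise ValueError("motif_mutation_prob must be in [0,1]")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0,1)")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    return rng.choice(4, size=length, p=probs)


def _mutate_motif(rng: np.random.Generator, motif_codes: np.ndarray, prob: float) -> np.ndarray:
    out = motif_codes.copy()
    if prob <= 0:
        return out
    hits = rng.random(len(out)) < prob
    for idx in np.nonzero(hits)[0]:
        choices = [b for b in range(4) if b != out[idx]]
        out[idx] = choices[rng.integers(0, 3)]
    return out


def _plant(seq: np.ndarray, center_1based: int, motif_codes: np.ndarray) -> None:
    m = len(motif_codes)
    start = center_1based - (m - 1) // 2 - 1  # 0-based
    seq[start : start + m] = motif_codes


def _make_gene(rng: np.random.Generator, cfg: SimConfig, gene_id: str,
               positive: bool, group_id: str) -> GeneRecord:
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_exons)
    intron_lens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1,
                               size=n_exons + 1)
    total = int(exon_lens.sum() + intron_lens.sum())
    seq = _random_sequence(rng, total, cfg.gc)
    exons, pos = [], 0
    for e in range(n_exons):
        pos += int(intron_lens[e])
        a = pos + 1                       # 1-based first exonic base
        d = pos + int(exon_lens[e])       # 1-based last exonic base
        exons.append((a, d))
        pos = d
    true_pair = None
    if positive:
        pairs = [(i, j) for i in range(n_exons) for j in range(i, n_exons)]
        i, j = pairs[int(rng.integers(0, len(pairs)))]
        acc_codes = np.array([_BASES.tolist().index(c) for c in cfg.acceptor_motif])
        don_codes = np.array([_BASES.tolist().index(c) for c in cfg.donor_motif])
        _plant(seq, exons[i][0], _mutate_motif(rng, acc_codes, cfg.motif_mutation_prob))
        _plant(seq, exons[j][1], _mutate_motif(rng, don_codes, cfg.motif_mutation_prob))
        true_pair = (j, i)  # (donor_ordinal, acceptor_ordinal), 0-based
    return GeneRecord(
        id=gene_id,
        sequence="".join(_BASES[seq]),
        exons=tuple(exons),
        label=int(positive),
        group_id=group_id,
        true_pair=true_pair,
    )


def _point_mutate(rng: np.random.Generator, sequence: str, prob: float) -> str:
    codes = np.array(["ACGT".index(c) if c in "ACGT" else 4 for c in sequence])
    hits = (rng.random(len(codes)) < prob) & (codes < 4)
    for idx in np.nonzero(hits)[0]:
        choices = [b for b in range(4) if b != codes[idx]]
        codes[idx] = choices[rng.integers(0, 3)]
    return "".join("ACGTN"[c] for c in codes)


def simulate_dataset(cfg: SimConfig, level: str = "gene") -> Dataset:
    """Generate ``cfg.n_genes`` labeled genes, fully determined by the seed."""
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.pos_fraction * cfg.n_genes))
    flags = np.zeros(cfg.n_genes, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)
    records = []
    for g in range(cfg.n_genes):
        gene_id = f"gene{g:05d}"
        records.append(_make_gene(rng, cfg, gene_id, bool(flags[g]), group_id=gene_id))
    if cfg.duplication_fraction > 0:
        n_dup = int(round(cfg.duplication_fraction * cfg.n_genes))
        dup_idx = rng.choice(cfg.n_genes, size=n_dup, replace=False)
        for g in sorted(int(x) for x in dup_idx):
            src = records[g]
            records.append(
                replace(
                    src,
                    id=f"{src.id}_dup",
                    sequence=_point_mutate(rng, src.sequence, cfg.duplication_mutation_prob),
                )
            )
    return Dataset(records=records, level=level)


def null_dataset(dataset: Dataset, seed: int = 0) -> Dataset:
    """Identical sequences with labels randomly permuted (negative control)."""
    rng = np.random.default_rng(seed)
    labels = [r.label for r in dataset.records]
    perm = rng.permutation(len(labels))
    records = [
        replace(rec, label=labels[int(perm[k])])
        for k, rec in enumerate(dataset.records)
    ]
    return Dataset(records=records, level=dataset.level)
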