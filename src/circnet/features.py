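"""Turn junction positions into padded, masked k-mer index tensors.

Each splice site contributes a window of ``L`` consecutive positions centred
on the junction; each position is encoded as the base-4 index of the k-mer
centred on it. Windows that run off the sequence, or that cover an ambiguous
base, map to a single reserved padding index ``4**K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneRecord

__all__ = ["FeatConfig", "JunctionBatch", "flanking_positions", "kmer_index", "build_batch"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FeatConfig:
    """Flanking-window length ``L`` and k-mer size ``K``."""

    L: int = 4
    K: int = 3

    def __post_init__(self) -> None:
        if self.L < 1 or self.K < 1:
            raise ValueError("L and K must be >= 1")

    @property
    def pad_index(self) -> int:
        return 4 ** self.K

    @property
    def vocab_size(self) -> int:
        return 4 ** self.K + 1


@dataclass
class JunctionBatch:
    """Padded per-record site windows for the two junction families.

    ``acceptor_ids`` and ``donor_ids`` have shape ``[B, M_max, L]``;
    ``site_mask`` is ``[B, M_max]`` with 1 marking a real exon. Rows of
    masked-out sites are filled entirely with the padding index.
    """

    acceptor_ids: np.ndarray
    donor_ids: np.ndarray
    site_mask: np.ndarray
    labels: np.ndarray | None = None
    record_ids: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.acceptor_ids.shape[0]

    @property
    def max_sites(self) -> int:
        return self.acceptor_ids.shape[1]


def flanking_positions(center: int, L: int) -> list[int]:
    """The ``L`` consecutive 1-based positions centred on ``center``.

    Spans ``center - floor((L-1)/2)`` through ``center + floor(L/2)``.
    Out-of-range positions (including <= 0) are returned as-is; they resolve
    to the padding index downstream.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    start = center - (L - 1) // 2
    return list(range(start, start + L))


def kmer_index(sequence: str, center: int, K: int) -> int:
    """Base-4 code of the K-mer centred on 1-based position ``center``.

    A=0, C=1, G=2, T=3, most-significant digit first. Returns ``4**K``
    (the padding index) when the window leaves the sequence or covers a
    non-ACGT character.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    start = center - (K - 1) // 2  # 1-based inclusive
    end = center + K // 2
    if start < 1 or end > len(sequence):
        return 4 ** K
    code = 0
    for ch in sequence[start - 1 : end]:
        digit = _BASE_CODE.get(ch)
        if digit is None:
            return 4 ** K
        code = code * 4 + digit
    return code


def _site_window(sequence: str, center: int, cfg: FeatConfig) -> list[int]:
    return [kmer_index(sequence, p, cfg.K) for p in flanking_positions(center, cfg.L)]


def build_batch(records: list[GeneRecord], cfg: FeatConfig) -> JunctionBatch:
    """Featurize ``records`` into one padded, masked batch.

    Pure and deterministic: identical inputs give bit-identical tensors.
    """
    if not records:
        raise ValueError("cannot build a batch from zero records")
    for rec in records:
        if not rec.exons:
            raise ValueError(f"record {rec.id!r} has no exons")
    n = len(records)
    m_max = max(len(rec.exons) for rec in records)
    pad = cfg.pad_index
    acc = np.full((n, m_max, cfg.L), pad, dtype=np.int64)
    don = np.full((n, m_max, cfg.L), pad, dtype=np.int64)
    mask = np.zeros((n, m_max), dtype=np.float64)
    labels = np.full(n, -1, dtype=np.int64)
    have_labels = all(rec.label is not None for rec in records)
    for b, rec in enumerate(records):
        for i, (a, d) in enumerate(rec.exons):
            acc[b, i] = _site_window(rec.sequence, a, cfg)
            don[b, i] = _site_window(rec.sequence, d, cfg)
            mask[b, i] = 1.0
        if have_labels:
            labels[b] = rec.label
    return JunctionBatch(
        acceptor_ids=acc,
        donor_ids=don,
        site_mask=mask,
        labels=labels if have_labels else None,
        record_ids=[rec.id for rec in records],
    )
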