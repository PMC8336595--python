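"""Zero-shot backsplice-pair scoring from a trained classifier's attention.

No pair annotation or retraining is used: the donor site weights ``gamma_d``
are read as P(donor) and the donor-side cross-attention rows ``beta_d`` as
P(acceptor | donor), so every (donor j, acceptor i) pair gets the joint
score ``gamma_d[j] * beta_d[j, i]``. Per record, the scores form a proper
distribution over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneRecord
from .model import AttentionMaps
from .train import rank_auc

__all__ = [
    "BacksplicePairScore",
    "backsplice_scores",
    "rank_pairs",
    "evaluate_discovery",
    "DiscoveryReport",
]


@dataclass(frozen=True)
class BacksplicePairScore:
    """Joint score for one (donor, acceptor) ordinal pair of a record."""

    record_id: str
    donor_ordinal: int      # 0-based exon ordinal j
    acceptor_ordinal: int   # 0-based exon ordinal i
    donor_position: int     # 1-based d_j on the record sequence
    acceptor_position: int  # 1-based a_i
    score: float


def backsplice_scores(maps: AttentionMaps, record: GeneRecord,
                      upstream_only: bool = False) -> list[BacksplicePairScore]:
    """Score every (donor, acceptor) pair of ``record`` from its attention maps.

    With ``upstream_only`` the candidate space is restricted to pairs whose
    acceptor lies at or upstream of the donor (a_i <= d_j), the direction real
    backsplices take; scores are then renormalized over the kept pairs.
    """
    m = record.n_exons
    gamma_d = np.asarray(maps.gamma_d)
    beta_d = np.asarray(maps.beta_d)
    if gamma_d.shape != (m,) or beta_d.shape != (m, m):
        raise ValueError(
            f"attention maps shaped {beta_d.shape}/{gamma_d.shape} do not match "
            f"record {record.id!r} with {m} exons"
        )
    joint = gamma_d[:, None] * beta_d  # [donor j, acceptor i]
    if upstream_only:
        keep = np.zeros((m, m), dtype=bool)
        for j in range(m):
            for i in range(m):
                keep[j, i] = record.exons[i][0] <= record.exons[j][1]
        joint = np.where(keep, joint, 0.0)
        total = joint.sum()
        if total > 0:
            joint = joint / total
    out = []
    for j in range(m):
        for i in range(m):
            if upstream_only and joint[j, i] == 0.0 and record.exons[i][0] > record.exons[j][1]:
                continue
            out.append(
                BacksplicePairScore(
                    record_id=record.id,
                    donor_ordinal=j,
                    acceptor_ordinal=i,
                    donor_position=record.exons[j][1],
                    acceptor_position=record.exons[i][0],
                    score=float(joint[j, i]),
                )
            )
    return out


def rank_pairs(scores: list[BacksplicePairScore]) -> list[BacksplicePairScore]:
    """Descending by score; ties broken by (donor, acceptor) ordinal ascending."""
    if not scores:
        raise ValueError("no pair scores to rank")
    return sorted(scores, key=lambda s: (-s.score, s.donor_ordinal, s.acceptor_ordinal))


@dataclass
class DiscoveryReport:
    auc: float
    top1_hit_rate: float
    n_records: int
    n_pairs: int
    roc_points: list[tuple[float, float]]
    skipped: list[str]


def _roc_points(y: np.ndarray, s: np.ndarray) -> list[tuple[float, float]]:
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    n_pos, n_neg = tps[-1], fps[-1]
    pts = [(0.0, 0.0)]
    pts += [(float(f) / n_neg, float(t) / n_pos) for f, t in zip(fps, tps)]
    return pts


def evaluate_discovery(records: list[GeneRecord],
                       per_record_scores: list[list[BacksplicePairScore]]) -> DiscoveryReport:
    """Pooled ROC/AUC of pair scores against the known true pairs.

    Pairs from all records are pooled; each record's true pair is the positive
    and every other candidate a negative. Records lacking a true pair or with
    fewer than two candidates are skipped with a note. Also reports the
    fraction of records whose top-ranked pair is the true one.
    """
    y, s, skipped = [], [], []
    hits = used = 0
    for rec, pair_scores in zip(records, per_record_scores):
        if rec.true_pair is None:
            skipped.append(rec.id)
            continue
        if len(pair_scores) < 2:
            skipped.append(rec.id)
            continue
        tj, ti = rec.true_pair
        for ps in pair_scores:
            y.append(int(ps.donor_ordinal == tj and ps.acceptor_ordinal == ti))
            s.append(ps.score)
        top = rank_pairs(pair_scores)[0]
        hits += int(top.donor_ordinal == tj and top.acceptor_ordinal == ti)
        used += 1
    if used == 0:
        raise ValueError("no records with a true_pair to evaluate")
    y_arr, s_arr = np.asarray(y), np.asarray(s)
    return DiscoveryReport(
        auc=rank_auc(y_arr, s_arr),
        top1_hit_rate=hits / used,
        n_records=used,
        n_pairs=len(y),
        roc_points=_roc_points(y_arr, s_arr),
        skipped=skipped,
    )


def write_pair_scores(path, ranked: dict[str, list[BacksplicePairScore]]) -> None:
    """TSV of ranked pair scores per record."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tdonor_ordinal\tacceptor_ordinal\tdonor_pos\tacceptor_pos\tscore\trank\n")
        for rec_id in ranked:
            for rank, ps in enumerate(ranked[rec_id], 1):
                fh.write(
                    f"{ps.record_id}\t{ps.donor_ordinal}\t{ps.acceptor_ordinal}\t"
                    f"{ps.donor_position}\t{ps.acceptor_position}\t{ps.score:.6g}\t{rank}\n"
                )


def write_bedpe(path, ranked: dict[str, list[BacksplicePairScore]], top_k: int = 1) -> None:
    """Top-k pairs as BEDPE: junction bases as 0-based half-open single-base intervals."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec_id in ranked:
            for ps in ranked[rec_id][:top_k]:
                d0 = ps.donor_position - 1
                a0 = ps.acceptor_position - 1
                fh.write(
                    f"{rec_id}\t{d0}\t{d0 + 1}\t{rec_id}\t{a0}\t{a0 + 1}\t"
                    f"{rec_id}:d{ps.donor_ordinal}-a{ps.acceptor_ordinal}\t{ps.score:.6g}\n"
                )
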