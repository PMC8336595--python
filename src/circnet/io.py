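"""Dataset model and readers/writers for FASTA, BED12, JSONL and TSV.

Internal coordinates are 1-based inclusive: for every exon, ``a`` is the
first exonic base (the acceptor junction) and ``d`` the last (the donor
junction). External BED and JSONL exon intervals are 0-based half-open and
converted on the way in/out. Sequences are materialized 5'->3' of the
transcribed strand at load time, so downstream code never sees strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "Dataset",
    "read_fasta",
    "read_jsonl_dataset",
    "write_jsonl_dataset",
    "read_bed12",
    "write_predictions",
]

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class GeneRecord:
    """One gene/isoform: sequence, ordered exon junctions and metadata.

    ``exons`` holds 1-based inclusive ``(acceptor, donor)`` positions, sorted,
    non-overlapping. ``true_pair`` is the simulation-only ground-truth
    backsplice pair as 0-based ordinals ``(donor_ordinal, acceptor_ordinal)``.
    """

    id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    label: int | None = None
    group_id: str | None = None
    true_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: sequence contains characters outside "
                f"ACGTN: {sorted(bad)}"
            )
        if not self.exons:
            raise ValueError(f"record {self.id!r} has no exons")
        prev_d = 0
        for a, d in self.exons:
            if not (1 <= a <= d <= len(self.sequence)):
                raise ValueError(
                    f"record {self.id!r}: exon ({a},{d}) out of bounds for "
                    f"sequence of length {len(self.sequence)}"
                )
            if a <= prev_d:
                raise ValueError(f"record {self.id!r}: exons overlap or are unsorted")
            prev_d = d
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")
        if self.true_pair is not None:
            j, i = self.true_pair
            m = len(self.exons)
            if not (0 <= j < m and 0 <= i < m):
                raise ValueError(f"record {self.id!r}: true_pair ordinals out of range")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def acceptor_positions(self) -> list[int]:
        return [a for a, _ in self.exons]

    def donor_positions(self) -> list[int]:
        return [d for _, d in self.exons]


@dataclass
class Dataset:
    """A list of :class:`GeneRecord` at a declared prediction level."""

    records: list[GeneRecord]
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("isoform", "gene"):
            raise ValueError("level must be 'isoform' or 'gene'")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labeled(self) -> list[GeneRecord]:
        return [r for r in self.records if r.label is not None]


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``; uppercases and maps U->T.

    Raises on duplicate ids (naming the id) and on an empty file.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seq = _normalize_seq(str(rec.seq))
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"FASTA record {rec.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def _intervals_to_junctions(rec_id: str, exons, seq_len: int) -> tuple[tuple[int, int], ...]:
    """0-based half-open [start, end) -> 1-based inclusive (a, d)."""
    out = []
    for start, end in exons:
        start, end = int(start), int(end)
        if not (0 <= start < end <= seq_len):
            raise ValueError(
                f"record {rec_id!r}: exon interval [{start},{end}) out of bounds "
                f"for sequence of length {seq_len}"
            )
        out.append((start + 1, end))
    for (_, d_prev), (a_next, _) in zip(out, out[1:]):
        if a_next <= d_prev:
            raise ValueError(f"record {rec_id!r}: overlapping or unsorted exons")
    return tuple(out)


def _junctions_to_intervals(exons) -> list[list[int]]:
    return [[a - 1, d] for a, d in exons]


def read_jsonl_dataset(path, fasta=None, level: str = "gene") -> Dataset:
    """Read the JSONL dataset format (one object per line).

    Required fields: ``id``, ``exons`` (0-based half-open intervals). The
    sequence comes from an inline ``sequence`` field or from the companion
    ``fasta``. Optional: ``label``, ``group``, ``true_pair``.
    """
    fasta_seqs = read_fasta(fasta) if fasta is not None else {}
    records: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{line_no}: invalid JSON: {exc}") from exc
            rec_id = obj["id"]
            if "sequence" in obj:
                seq = _normalize_seq(obj["sequence"])
            elif rec_id in fasta_seqs:
                seq = fasta_seqs[rec_id]
            else:
                raise ValueError(
                    f"record {rec_id!r}: no inline sequence and id not found in FASTA"
                )
            exons = _intervals_to_junctions(rec_id, obj["exons"], len(seq))
            tp = obj.get("true_pair")
            records.append(
                GeneRecord(
                    id=rec_id,
                    sequence=seq,
                    exons=exons,
                    label=obj.get("label"),
                    group_id=obj.get("group"),
                    true_pair=tuple(tp) if tp is not None else None,
                )
            )
    return Dataset(records=records, level=level)


def write_jsonl_dataset(dataset: Dataset, jsonl_path, fasta_path=None) -> None:
    """Write JSONL (+ optional companion FASTA); inverse of the reader.

    With a FASTA path, sequences go to the FASTA and the JSONL carries only
    structure; otherwise sequences are inlined.
    """
    with open(jsonl_path, "w", encoding="utf-8") as fh:
        for rec in dataset.records:
            obj: dict = {"id": rec.id, "exons": _junctions_to_intervals(rec.exons)}
            if fasta_path is None:
                obj["sequence"] = rec.sequence
            if rec.label is not None:
                obj["label"] = rec.label
            if rec.group_id is not None:
                obj["group"] = rec.group_id
            if rec.true_pair is not None:
                obj["true_pair"] = list(rec.true_pair)
            fh.write(json.dumps(obj) + "\n")
    if fasta_path is not None:
        with open(fasta_path, "w", encoding="utf-8") as fh:
            for rec in dataset.records:
                fh.write(f">{rec.id}\n")
                for k in range(0, len(rec.sequence), 70):
                    fh.write(rec.sequence[k : k + 70] + "\n")


def read_bed12(path, fasta, level: str = "isoform") -> Dataset:
    """Read BED12 transcript structures against a FASTA of chromosomes.

    Each line becomes one record whose sequence is the chromStart..chromEnd
    slice, reverse-complemented for strand '-', with exon junctions
    re-indexed so the first exon in transcription order comes first and
    ``a`` stays the 5' junction of each exon.
    """
    chroms = read_fasta(fasta)
    records: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, 1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{line_no}: expected 12 BED fields, got {len(fields)}")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{path}:{line_no}: blockCount={block_count} does not match "
                    f"{len(sizes)} blockSizes / {len(starts)} blockStarts"
                )
            if chrom not in chroms:
                raise ValueError(f"{path}:{line_no}: chrom {chrom!r} not in FASTA")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{line_no}: strand must be '+' or '-'")
            seq = chroms[chrom][start:end]
            span = end - start
            # intervals relative to chromStart, 0-based half-open
            rel = [(s, s + sz) for s, sz in zip(starts, sizes)]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
                rel = [(span - e, span - s) for s, e in reversed(rel)]
            exons = _intervals_to_junctions(name, rel, len(seq))
            records.append(GeneRecord(id=name, sequence=seq, exons=exons))
    if not records:
        raise ValueError(f"no BED records found in {path}")
    return Dataset(records=records, level=level)


def write_predictions(records, scores, path, threshold: float = 0.5) -> None:
    """Write a TSV of ``id, score, call`` with ``call = 1 iff score > threshold``."""
    records = list(records)
    scores = list(scores)
    if len(records) != len(scores):
        raise ValueError(
            f"{len(records)} records but {len(scores)} scores"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tscore\tcall\n")
        for rec, s in zip(records, scores):
            s = float(s)
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for record {rec.id!r} outside [0,1]")
            fh.write(f"{rec.id}\t{s:.6f}\t{int(s > threshold)}\n")


def relabel(record: GeneRecord, label: int) -> GeneRecord:
    return replace(record, label=label)
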