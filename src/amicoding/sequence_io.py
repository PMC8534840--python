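"""FASTA/GTF input and parent-sequence construction.

A genome is reduced to two "parent" sequences per species:

* the **coding parent** — every annotated CDS, extracted 5'→3' (reverse
  complemented when on the minus strand), concatenated per transcript,
  deduplicated across byte-identical transcripts, and joined in annotation
  order;
* the **noncoding parent** — every maximal interval not covered by any CDS
  on either strand, with each interval contributing its forward sequence
  followed by its reverse complement so that noncoding context of genes on
  both strands is represented.

Coordinates follow the GTF convention (1-based, inclusive) throughout this
module; the BED-like audit table is the only place where 0-based half-open
coordinates appear, and the conversion happens at write time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
import gffutils.feature

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "CdsFeature",
    "ParentSequences",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_cds_features",
    "reverse_complement",
    "merge_intervals",
    "complement_intervals",
    "build_parent_sequences",
    "write_parents_fasta",
    "read_parents_fasta",
    "write_interval_audit",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation files or out-of-bounds features."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named contig with a strand."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise AnnotationError(
                f"invalid interval {self.seqid}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CdsFeature:
    transcript_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ParentSequences:
    """Concatenated coding and noncoding parent sequences for one species."""

    species_id: str
    coding: str
    noncoding: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA into ``{seqid: uppercase sequence}``."""
    path = Path(path)
    records: dict[str, str] = {}
    with path.open() as fh:
        first = fh.read(1)
        if first == "":
            raise AnnotationError(f"{path}: empty FASTA file")
        if first != ">":
            raise AnnotationError(f"{path}: line 1: expected '>' header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise AnnotationError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]],
                width: int = 70) -> None:
    if isinstance(records, Mapping):
        records = records.items()
    with Path(path).open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def read_cds_features(path) -> list[CdsFeature]:
    """Return the CDS rows of a GTF file, in file order.

    Only rows whose feature column equals ``CDS`` are kept; the annotation
    is accepted as-is (no ORF re-calling, phase column ignored).  A row
    lacking a ``transcript_id`` attribute gets a synthetic per-row id and a
    warning is logged.
    """
    path = Path(path)
    features: list[CdsFeature] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.count("\t") < 7:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype != "CDS":
                continue
            tids = feat.attributes.get("transcript_id", [])
            if tids:
                tid = tids[0]
            else:
                tid = f"row{lineno}"
                logger.warning(
                    "%s: line %d: CDS row without transcript_id, using %s",
                    path, lineno, tid,
                )
            strand = feat.strand if feat.strand in "+-" else "+"
            features.append(
                CdsFeature(tid, GenomicInterval(feat.seqid, feat.start, feat.end, strand))
            )
    return features


# ---------------------------------------------------------------------------
# sequence arithmetic


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity letters mapped to their complements."""
    return str(Seq(seq).reverse_complement())


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted list of disjoint ones."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def complement_intervals(
    merged: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Maximal intervals of ``[1, length]`` not covered by ``merged``."""
    out: list[tuple[int, int]] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= length:
        out.append((cursor, length))
    return out


# ---------------------------------------------------------------------------
# parent construction


def _transcript_order(features: Sequence[CdsFeature]) -> list[str]:
    seen: dict[str, None] = {}
    for f in features:
        seen.setdefault(f.transcript_id, None)
    return list(seen)


def build_parent_sequences(
    assembly: Mapping[str, str],
    cds_features: Sequence[CdsFeature],
    species_id: str = "",
    max_seqs: int | None = None,
    dedupe: bool = True,
    per_transcript: bool = True,
) -> ParentSequences:
    """Build the coding and noncoding parent sequences of a genome.

    Parameters
    ----------
    assembly
        Mapping seqid -> sequence, in file order (Python dicts preserve it).
    cds_features
        CDS rows in annotation order.
    max_seqs
        If set, restrict to the first ``max_seqs`` assembly records (the
        "first chromosomes only" rule for large genomes).
    dedupe
        Drop byte-identical transcript CDS sequences after the first.
    per_transcript
        Group CDS segments by transcript and concatenate them 5'→3' before
        joining transcripts (preserves reading frame across exon junctions).
        When False, raw CDS rows are extracted independently in file order.
    """
    seqids = list(assembly)
    if max_seqs is not None:
        seqids = seqids[:max_seqs]
    used = {sid: assembly[sid] for sid in seqids}

    features = [f for f in cds_features if f.interval.seqid in used]
    for f in features:
        contig = used[f.interval.seqid]
        if f.interval.end > len(contig):
            raise AnnotationError(
                f"CDS {f.transcript_id} {f.interval.seqid}:"
                f"{f.interval.start}-{f.interval.end} exceeds contig length "
                f"{len(contig)}"
            )

    def extract(iv: GenomicInterval) -> str:
        return used[iv.seqid][iv.start - 1 : iv.end]

    # coding parent
    pieces: list[str] = []
    if per_transcript:
        by_tid: dict[str, list[CdsFeature]] = {}
        for f in features:
            by_tid.setdefault(f.transcript_id, []).append(f)
        for tid in _transcript_order(features):
            segs = sorted(by_tid[tid], key=lambda f: (f.interval.seqid, f.interval.start))
            strands = {f.interval.strand for f in segs}
            if len(strands) > 1:
                raise AnnotationError(f"transcript {tid} has CDS on both strands")
            seq = "".join(extract(f.interval) for f in segs)
            if strands == {"-"}:
                # concatenating in coordinate order then reverse complementing
                # the whole transcript equals per-segment revcomp in reverse
                # coordinate order
                seq = reverse_complement(seq)
            pieces.append(seq)
    else:
        for f in features:
            seq = extract(f.interval)
            if f.interval.strand == "-":
                seq = reverse_complement(seq)
            pieces.append(seq)
    if dedupe:
        seen: set[str] = set()
        uniq = []
        for p in pieces:
            if p not in seen:
                seen.add(p)
                uniq.append(p)
        pieces = uniq
    coding = "".join(pieces)

    # noncoding parent: strand-agnostic complement of the CDS union,
    # each interval forward then reverse-complemented, in coordinate order
    noncoding_parts: list[str] = []
    for sid in seqids:
        covered = merge_intervals(
            (f.interval.start, f.interval.end)
            for f in features
            if f.interval.seqid == sid
        )
        for s, e in complement_intervals(covered, len(used[sid])):
            fwd = used[sid][s - 1 : e]
            noncoding_parts.append(fwd)
            noncoding_parts.append(reverse_complement(fwd))
    noncoding = "".join(noncoding_parts)

    if not coding:
        raise AnnotationError("empty coding parent (no usable CDS features)")
    if not noncoding:
        raise AnnotationError("empty noncoding parent (assembly fully covered by CDS)")
    return ParentSequences(species_id, coding, noncoding)


def write_parents_fasta(path, parents: ParentSequences) -> None:
    write_fasta(path, [("coding", parents.coding), ("noncoding", parents.noncoding)])


def read_parents_fasta(path, species_id: str = "") -> ParentSequences:
    records = read_fasta(path)
    try:
        return ParentSequences(species_id, records["coding"], records["noncoding"])
    except KeyError as exc:
        raise AnnotationError(
            f"{path}: parent FASTA must contain 'coding' and 'noncoding' records"
        ) from exc


def write_interval_audit(
    path,
    assembly: Mapping[str, str],
    cds_features: Sequence[CdsFeature],
    max_seqs: int | None = None,
) -> None:
    """BED-like TSV of the strand-agnostic CDS union and its complement.

    Emitted 0-based half-open (BED convention); internal coordinates are
    1-based inclusive, so ``start - 1, end`` is written.
    """
    seqids = list(assembly)[:max_seqs] if max_seqs is not None else list(assembly)
    with Path(path).open("w") as fh:
        fh.write("seqid\tstart\tend\tclass\n")
        for sid in seqids:
            covered = merge_intervals(
                (f.interval.start, f.interval.end)
                for f in cds_features
                if f.interval.seqid == sid
            )
            for s, e in covered:
                fh.write(f"{sid}\t{s - 1}\t{e}\tcoding\n")
            for s, e in complement_intervals(covered, len(assembly[sid])):
                fh.write(f"{sid}\t{s - 1}\t{e}\tnoncoding\n")
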