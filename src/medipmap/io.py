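"""Readers and writers for FASTA, FASTQ, BED and the GFF-lite gene format.

BED is native (0-based half-open).  GFF-lite is 1-based inclusive on disk,
per GFF convention, and converted on read.  FASTQ Phred offset (33/64) is
auto-detected and recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .genemodel import GeneModel
from .intervals import GenomeIndex, GenomicInterval

log = logging.getLogger(__name__)


class Genome:
    """In-memory genome with a :class:`GenomeIndex` and sequence access.

    Sequences are uppercased on load.  Retrieval by interval returns exactly
    ``end - start`` characters and errors on out-of-bounds requests.
    """

    def __init__(self, records: dict[str, str], order: Optional[list[str]] = None):
        if not records:
            raise ValueError("empty genome")
        for name, seq in records.items():
            if not seq:
                raise ValueError(f"empty record {name!r}")
        self._seqs = {name: seq.upper() for name, seq in records.items()}
        names = order or list(records)
        self.index = GenomeIndex([(n, len(self._seqs[n])) for n in names])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records: dict[str, str] = {}
        order: list[str] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA record {rec.id!r}")
            records[rec.id] = str(rec.seq)
            order.append(rec.id)
        return cls(records, order)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self._seqs.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(seq):
            raise ValueError(f"interval {interval} outside chromosome bounds")
        return seq[interval.start : interval.end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.index.names:
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA genome; returns index plus sequence accessor."""
    return Genome.from_fasta(path)


# ---------------------------------------------------------------------------
# BED


def read_bed(
    path: str | Path,
    genome: Optional[GenomeIndex] = None,
    on_unknown_chrom: str = "error",
) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving input order.

    Column 4 (name) is retained — repeat tracks use it as the class label —
    as are column 5 (score) and column 6 (strand) when present.  With a
    genome index, intervals on unknown chromosomes either raise
    (``on_unknown_chrom='error'``) or are dropped with a log message
    (``'skip'``).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if genome is not None and chrom not in genome:
                if on_unknown_chrom == "skip":
                    log.warning("%s:%d: skipping unknown chromosome %s", path, lineno, chrom)
                    continue
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; emits exactly the columns that carry data."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                cols.append(format(iv.score, "g") if iv.score is not None else ".")
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF-lite gene models
#
# Tab-separated dialect, 1-based inclusive on disk:
#   gene <gene_id> <chrom> <start> <end> <strand>
#   exon <gene_id> <start> <end>
#   cds  <gene_id> <start> <end>
# Child lines reference a previously declared gene_id; one model per gene.


def read_gff(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            kind = cols[0]
            if kind == "gene":
                _, gid, chrom, start, end, strand = cols
                if gid in genes:
                    raise ValueError(f"{path}:{lineno}: duplicate gene {gid!r}")
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                    "cds": None,
                }
                order.append(gid)
            elif kind in ("exon", "cds"):
                _, gid, start, end = cols
                if gid not in genes:
                    raise ValueError(f"{path}:{lineno}: child line before gene {gid!r}")
                span = (int(start) - 1, int(end))
                if kind == "exon":
                    genes[gid]["exons"].append(span)
                else:
                    genes[gid]["cds"] = span
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {kind!r}")
    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),
                exons=sorted(g["exons"]),
                cds_span=g["cds"],
            )
        )
    return out


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"gene\t{g.gene_id}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\n"
            )
            for s, e in g.exons:
                fh.write(f"exon\t{g.gene_id}\t{s + 1}\t{e}\n")
            if g.cds_span is not None:
                s, e = g.cds_span
                fh.write(f"cds\t{g.gene_id}\t{s + 1}\t{e}\n")


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class SeqRead:
    """A sequencing read: bases over {A,C,G,T,N} with per-base Phred scores."""

    read_id: str
    bases: str
    quals: list[int]
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id}: negative quality score")


def detect_phred_offset(path: str | Path, max_reads: int = 1000) -> int:
    """Heuristic Phred-offset detection: any quality char below '@' (ord 64)
    implies offset 33; otherwise chars above 'J' (ord 74) imply 64."""
    lo, hi = 255, 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i // 4 >= max_reads:
                break
            if i % 4 == 3:
                line = line.rstrip("\n")
                if line:
                    lo = min(lo, min(ord(c) for c in line))
                    hi = max(hi, max(ord(c) for c in line))
    if lo < 64:
        return 33
    if hi > 74:
        return 64
    return 33


def read_fastq(path: str | Path, offset: Optional[int] = None) -> Iterator[SeqRead]:
    """Stream a FASTQ file as :class:`SeqRead`; offset auto-detected if None."""
    if offset is None:
        offset = detect_phred_offset(path)
    fmt = "fastq" if offset == 33 else "fastq-illumina"
    for rec in SeqIO.parse(str(path), fmt):
        yield SeqRead(
            read_id=rec.id,
            bases=str(rec.seq).upper(),
            quals=list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[SeqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")
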