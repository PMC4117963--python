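"""Gene models and derivation of the seven genomic feature categories.

A gene model contributes up to six categories — upstream 2 kb, 5'UTR, CDS,
intron, 3'UTR, downstream 2 kb — all strand-aware; whatever is left of the
genome is intergenic.  Overlaps between categories of different genes are
resolved per base pair by a fixed precedence order so the categories form a
disjoint partition of the genome, which is what the density denominators
require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import GenomeIndex, GenomicInterval, IntervalSet

#: Partition categories in precedence order (highest first).  Applied per
#: base pair when overlapping gene-derived categories compete.
CATEGORY_PRECEDENCE = (
    "cds",
    "utr5",
    "utr3",
    "intron",
    "upstream2kb",
    "downstream2kb",
    "intergenic",
)

#: Table-column order for per-category reports.
CATEGORY_ORDER = (
    "upstream2kb",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "downstream2kb",
    "intergenic",
)

REPEAT_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA",
    "satellite",
    "simple",
    "low_complexity",
    "other",
)


@dataclass
class GeneModel:
    """Strand-aware gene with exon structure.

    ``exons`` are sorted, disjoint ``(start, end)`` spans within the gene
    interval; ``cds_span`` is the genomic span of the coding region (absent
    for non-coding genes).  TSS is ``interval.start`` on + and
    ``interval.end`` on −.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            self.exons = [(self.interval.start, self.interval.end)]
        self.exons = sorted(self.exons)
        prev_end = self.interval.start - 1
        for s, e in self.exons:
            if s >= e or s < self.interval.start or e > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValueError(f"gene {self.gene_id}: cds outside exon chain")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site (a point; the coordinate of the first
        transcribed base on + strand, one past it on −)."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass
class FeatureAnnotation:
    """Disjoint genome partition into the seven categories plus a repeat
    overlay.

    ``categories`` maps each of :data:`CATEGORY_ORDER` to an
    :class:`IntervalSet`; after precedence resolution these are pairwise
    disjoint and their union is the whole genome.  ``repeats`` is an
    independent overlay keyed by repeat class — a peak may hit both a genic
    category and a repeat.
    """

    genome: GenomeIndex
    categories: dict[str, IntervalSet]
    repeats: dict[str, IntervalSet] = field(default_factory=dict)

    @property
    def repeat_union(self) -> IntervalSet:
        out = IntervalSet()
        for s in self.repeats.values():
            out = out.union(s)
        return out

    def partition_lengths(self) -> dict[str, int]:
        return {c: self.categories[c].total_length() for c in CATEGORY_ORDER}


def _raw_category_intervals(
    gene: GeneModel, genome: GenomeIndex, flank: int
) -> dict[str, list[GenomicInterval]]:
    """Per-gene category spans before cross-gene precedence resolution."""
    chrom_len = genome.length(gene.chrom)
    iv = gene.interval
    out: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORY_PRECEDENCE}

    def add(cat: str, s: int, e: int) -> None:
        s, e = max(0, s), min(chrom_len, e)
        if s < e:
            out[cat].append(GenomicInterval(gene.chrom, s, e))

    # flanks, transcription-oriented, clipped at chromosome edges
    if gene.strand == "+":
        add("upstream2kb", iv.start - flank, iv.start)
        add("downstream2kb", iv.end, iv.end + flank)
    else:
        add("upstream2kb", iv.end, iv.end + flank)
        add("downstream2kb", iv.start - flank, iv.start)

    exon_set = IntervalSet(GenomicInterval(gene.chrom, s, e) for s, e in gene.exons)
    gene_set = IntervalSet([GenomicInterval(gene.chrom, iv.start, iv.end)])
    for intron in gene_set.subtract(exon_set):
        add("intron", intron.start, intron.end)

    if gene.cds_span is None:
        # non-coding gene: exonic sequence counted under CDS (exon proxy)
        for ex in exon_set:
            add("cds", ex.start, ex.end)
        return out

    cs, ce = gene.cds_span
    for ex in exon_set:
        add("cds", max(ex.start, cs), min(ex.end, ce))
        # exonic sequence 5' of the CDS is 5'UTR, 3' of it 3'UTR
        left_cat = "utr5" if gene.strand == "+" else "utr3"
        right_cat = "utr3" if gene.strand == "+" else "utr5"
        add(left_cat, ex.start, min(ex.end, cs))
        add(right_cat, max(ex.start, ce), ex.end)
    return out


def derive_features(
    genes: Sequence[GeneModel],
    genome: GenomeIndex,
    flank: int = 2000,
    repeats: Sequence[GenomicInterval] = (),
) -> FeatureAnnotation:
    """Build the disjoint seven-category partition from gene models.

    Precedence (CDS > 5'UTR > 3'UTR > intron > upstream > downstream >
    intergenic) is applied by subtracting every higher-precedence category
    from each category's raw union; intergenic is the genome minus all
    gene-derived sequence.  Repeats (labelled intervals, one class each) are
    kept as an overlay, not part of the partition.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.interval.end > genome.length(g.chrom):
            raise ValueError(f"gene {g.gene_id} extends beyond chromosome")

    raw: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORY_PRECEDENCE}
    for g in genes:
        for cat, ivs in _raw_category_intervals(g, genome, flank).items():
            raw[cat].extend(ivs)

    categories: dict[str, IntervalSet] = {}
    claimed = IntervalSet()
    for cat in CATEGORY_PRECEDENCE[:-1]:
        cat_set = IntervalSet(raw[cat]).subtract(claimed)
        categories[cat] = cat_set
        claimed = claimed.union(cat_set)
    categories["intergenic"] = IntervalSet(genome.as_intervals()).subtract(claimed)

    repeat_sets: dict[str, list[GenomicInterval]] = {}
    for iv in repeats:
        cls = iv.name if iv.name in REPEAT_CLASSES else "other"
        repeat_sets.setdefault(cls, []).append(iv)
    return FeatureAnnotation(
        genome=genome,
        categories=categories,
        repeats={c: IntervalSet(ivs) for c, ivs in repeat_sets.items()},
    )
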