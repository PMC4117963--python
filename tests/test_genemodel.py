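"""Feature-category derivation: forced examples and the genome-partition
property against a per-bp label-array oracle."""

import numpy as np
import pytest

from medipmap.genemodel import (
    CATEGORY_ORDER,
    CATEGORY_PRECEDENCE,
    GeneModel,
    derive_features,
)
from medipmap.intervals import GenomeIndex, GenomicInterval


def _spans(intervalset):
    return [(iv.start, iv.end) for iv in intervalset]


def test_plus_strand_single_exon_gene_categories():
    genome = GenomeIndex([("chr1", 20_000)])
    gene = GeneModel(
        "g",
        GenomicInterval("chr1", 5000, 8000, "+"),
        exons=[(5000, 8000)],
        cds_span=(5500, 7500),
    )
    ann = derive_features([gene], genome)
    assert _spans(ann.categories["upstream2kb"]) == [(3000, 5000)]
    assert _spans(ann.categories["utr5"]) == [(5000, 5500)]
    assert _spans(ann.categories["cds"]) == [(5500, 7500)]
    assert _spans(ann.categories["utr3"]) == [(7500, 8000)]
    assert _spans(ann.categories["downstream2kb"]) == [(8000, 10_000)]
    assert _spans(ann.categories["intron"]) == []
    assert _spans(ann.categories["intergenic"]) == [(0, 3000), (10_000, 20_000)]


def test_minus_strand_upstream_lies_past_gene_end():
    genome = GenomeIndex([("chr1", 20_000)])
    gene = GeneModel(
        "g",
        GenomicInterval("chr1", 5000, 8000, "-"),
        exons=[(5000, 8000)],
        cds_span=(5500, 7500),
    )
    ann = derive_features([gene], genome)
    assert _spans(ann.categories["upstream2kb"]) == [(8000, 10_000)]
    assert _spans(ann.categories["downstream2kb"]) == [(3000, 5000)]
    # UTR sides flip with strand: 5'UTR is now the high-coordinate side
    assert _spans(ann.categories["utr5"]) == [(7500, 8000)]
    assert _spans(ann.categories["utr3"]) == [(5000, 5500)]


def test_flank_clipped_at_chromosome_edge():
    genome = GenomeIndex([("chr1", 6000)])
    gene = GeneModel("g", GenomicInterval("chr1", 500, 4500, "+"), cds_span=(700, 4300))
    ann = derive_features([gene], genome)
    assert _spans(ann.categories["upstream2kb"]) == [(0, 500)]
    assert _spans(ann.categories["downstream2kb"]) == [(4500, 6000)]


def test_gene_beyond_chromosome_rejected():
    genome = GenomeIndex([("chr1", 6000)])
    gene = GeneModel("g", GenomicInterval("chr1", 500, 7000, "+"))
    with pytest.raises(ValueError, match="beyond chromosome"):
        derive_features([gene], genome)


def _random_genes(rng, genome, n):
    genes = []
    for i in range(n):
        chrom, clen = genome.chroms[int(rng.integers(len(genome.chroms)))]
        length = int(rng.integers(1000, 8000))
        start = int(rng.integers(0, clen - length))
        n_ex = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(start + 50, start + length - 50), 2 * (n_ex - 1), replace=False))
        bounds = [start, *map(int, cuts), start + length]
        exons = [(bounds[2 * j], bounds[2 * j + 1]) for j in range(n_ex)]
        cds = (exons[0][0] + 10, exons[-1][1] - 10)
        genes.append(
            GeneModel(
                f"g{i}",
                GenomicInterval(chrom, start, start + length, "+" if rng.random() < 0.5 else "-"),
                exons=exons,
                cds_span=cds,
            )
        )
    return genes


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_partition_matches_per_bp_label_oracle(seed):
    """Random overlapping genes: categories partition the genome exactly as
    a brute-force per-bp labeling with the same precedence order."""
    rng = np.random.default_rng(seed)
    genome = GenomeIndex([("chr1", 60_000), ("chr2", 40_000)])
    genes = _random_genes(rng, genome, 20)
    ann = derive_features(genes, genome)

    prec = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    for chrom, clen in genome.chroms:
        label = np.full(clen, prec["intergenic"], dtype=int)

        def paint(cat, s, e):
            s, e = max(0, s), min(clen, e)
            sl = label[s:e]
            sl[sl > prec[cat]] = prec[cat]

        for g in genes:
            if g.chrom != chrom:
                continue
            s, e = g.interval.start, g.interval.end
            if g.strand == "+":
                paint("upstream2kb", s - 2000, s)
                paint("downstream2kb", e, e + 2000)
            else:
                paint("upstream2kb", e, e + 2000)
                paint("downstream2kb", s - 2000, s)
            exon_mask = np.zeros(clen, dtype=bool)
            for xs, xe in g.exons:
                exon_mask[xs:xe] = True
            intron_mask = np.zeros(clen, dtype=bool)
            intron_mask[s:e] = True
            intron_mask &= ~exon_mask
            for pos in np.flatnonzero(intron_mask):
                if label[pos] > prec["intron"]:
                    label[pos] = prec["intron"]
            cs, ce = g.cds_span
            for xs, xe in g.exons:
                paint("cds", max(xs, cs), min(xe, ce))
                left = "utr5" if g.strand == "+" else "utr3"
                right = "utr3" if g.strand == "+" else "utr5"
                paint(left, xs, min(xe, cs))
                paint(right, max(xs, ce), xe)

        total = 0
        for cat in CATEGORY_ORDER:
            got = ann.categories[cat].overlap_length(chrom, 0, clen)
            want = int((label == prec[cat]).sum())
            assert got == want, f"{chrom}:{cat}: {got} != {want}"
            total += got
        assert total == clen  # partition covers the chromosome exactly


def test_partition_categories_pairwise_disjoint(small_study):
    ann = small_study["annotation"]
    cats = list(ann.categories)
    total = sum(ann.categories[c].total_length() for c in cats)
    assert total == ann.genome.total_size
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            assert ann.categories[a].intersection_length(ann.categories[b]) == 0


def test_repeat_track_is_overlay_with_class_labels(small_study):
    ann = small_study["annotation"]
    assert set(ann.repeats) == set(small_study["config"].n_repeats)
    # overlay sits inside intron+intergenic space, outside the exonic classes
    for cls, track in ann.repeats.items():
        for cat in ("cds", "utr5", "utr3", "upstream2kb", "downstream2kb"):
            assert track.intersection_length(ann.categories[cat]) == 0
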