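"""Two-sample differential methylation calling.

Procedure: the two samples' peak sets are merged into disjoint regions,
reads are counted per region in each sample, each region is tested with a
2×2 chi-square (region reads vs rest-of-library, no continuity correction),
p-values are Benjamini–Hochberg adjusted across regions, and regions with
q < alpha and a library-size-normalized fold-change strictly above the
threshold are called DMRs, hyper- or hypomethylated in sample A by
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .density import methylation_density
from .genemodel import FeatureAnnotation
from .intervals import GenomicInterval, IntervalSet


@dataclass
class MergedRegion:
    """A merged-peak region with per-sample read counts and library sizes."""

    interval: GenomicInterval
    count_a: int
    count_b: int
    total_a: int
    total_b: int

    def __post_init__(self) -> None:
        if min(self.count_a, self.count_b) < 0:
            raise ValueError("negative read count")
        if self.count_a > self.total_a or self.count_b > self.total_b:
            raise ValueError("count exceeds library size")


@dataclass
class DMRRecord:
    region: MergedRegion
    chi2: float
    p: float
    q: float
    fold: float  # normalized rate_a / rate_b (pseudocounted for zeros)
    direction: str  # "hyper" (A > B) or "hypo"
    is_dmr: bool

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval


def merge_peak_sets(
    peaks_a: Sequence[GenomicInterval], peaks_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Connected components of the union of both peak sets (book-ended
    intervals joined); sorted and disjoint."""
    return IntervalSet(list(peaks_a) + list(peaks_b)).to_intervals()


def count_reads(
    regions: Sequence[GenomicInterval],
    reads: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.5,
) -> np.ndarray:
    """Reads per region; a read counts when >= ``min_overlap_frac`` of it
    overlaps the region, and is assigned to at most one region (the one of
    maximal overlap; earliest wins ties)."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, idx))
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    idxs: dict[str, np.ndarray] = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts[chrom] = np.array([i[0] for i in items])
        ends[chrom] = np.array([i[1] for i in items])
        idxs[chrom] = np.array([i[2] for i in items])
    counts = np.zeros(len(regions), dtype=np.int64)
    for read in reads:
        s_arr = starts.get(read.chrom)
        if s_arr is None:
            continue
        e_arr = ends[read.chrom]
        i0 = int(np.searchsorted(e_arr, read.start, side="right"))
        i1 = int(np.searchsorted(s_arr, read.end, side="left"))
        best_idx, best_ov = -1, 0
        for j in range(i0, i1):
            ov = min(int(e_arr[j]), read.end) - max(int(s_arr[j]), read.start)
            if ov > best_ov:
                best_ov, best_idx = ov, int(idxs[read.chrom][j])
        if best_idx >= 0 and best_ov >= min_overlap_frac * read.length:
            counts[best_idx] += 1
    return counts


def _chi2_stat(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Pearson chi-square statistic, no continuity correction, for the 2×2
    tables [[a, na-a], [b, nb-b]] (vectorized)."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    n = float(na + nb)
    col1 = a + b
    col2 = n - col1
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack(
            [
                na * col1 / n,
                na * col2 / n,
                nb * col1 / n,
                nb * col2 / n,
            ]
        )
        o = np.stack([a, na - a, b, nb - b])
        terms = np.where(e > 0, (o - e) ** 2 / e, 0.0)
    return terms.sum(axis=0)


def test_region(region: MergedRegion) -> DMRRecord:
    """Chi-square test of one merged region (q is set to p; callers doing
    multiple regions should use :func:`call_dmrs` for BH adjustment)."""
    if region.total_a <= 0 or region.total_b <= 0:
        raise ValueError("library sizes must be positive")
    if region.count_a == 0 and region.count_b == 0:
        raise ValueError("uninformative region (zero counts in both samples)")
    chi2 = float(
        _chi2_stat(
            np.array([region.count_a]),
            np.array([region.count_b]),
            region.total_a,
            region.total_b,
        )[0]
    )
    p = float(stats.chi2.sf(chi2, df=1))
    fold = _fold(region)
    direction = "hyper" if fold > 1 else "hypo"
    return DMRRecord(region, chi2, p, p, fold, direction, is_dmr=False)


def _fold(region: MergedRegion) -> float:
    # pseudocount 0.5 on zero cells, for the fold only (not the chi-square)
    ca = region.count_a if region.count_a > 0 else 0.5
    cb = region.count_b if region.count_b > 0 else 0.5
    return (ca / region.total_a) / (cb / region.total_b)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    if len(pvals) == 0:
        return np.array([])
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def test_regions(
    regions: Sequence[MergedRegion],
    alpha: float = 0.05,
    min_fold: float = 2.0,
    min_total_count: int = 5,
    normalize: bool = True,
    use_raw_p: bool = False,
) -> list[DMRRecord]:
    """Vectorized chi-square + BH over merged regions; flags DMRs.

    Regions with fewer than ``min_total_count`` reads summed over both
    samples are dropped before testing (the chi-square approximation is
    invalid there); zero-information regions likewise.  With
    ``normalize=False`` the fold is the raw count ratio (the literal
    reading of "read numbers") instead of the library-size-normalized rate
    ratio.
    """
    kept = [
        r
        for r in regions
        if (r.count_a + r.count_b) >= max(min_total_count, 1)
    ]
    if not kept:
        return []
    a = np.array([r.count_a for r in kept])
    b = np.array([r.count_b for r in kept])
    na = kept[0].total_a
    nb = kept[0].total_b
    for r in kept:
        if r.total_a != na or r.total_b != nb:
            raise ValueError("inconsistent library sizes across regions")
    if na <= 0 or nb <= 0:
        raise ValueError("library sizes must be positive")
    chi2 = _chi2_stat(a, b, na, nb)
    p = stats.chi2.sf(chi2, df=1)
    q = bh_adjust(p)
    ca = np.where(a > 0, a, 0.5)
    cb = np.where(b > 0, b, 0.5)
    if normalize:
        fold = (ca / na) / (cb / nb)
    else:
        fold = ca / cb
    sig = q < alpha if not use_raw_p else p < alpha
    eff = np.maximum(fold, 1.0 / fold)
    records = []
    for i, r in enumerate(kept):
        records.append(
            DMRRecord(
                region=r,
                chi2=float(chi2[i]),
                p=float(p[i]),
                q=float(q[i]),
                fold=float(fold[i]),
                direction="hyper" if fold[i] > 1 else "hypo",
                is_dmr=bool(sig[i] and eff[i] > min_fold),
            )
        )
    return records


def call_dmrs(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    reads_a: Sequence[GenomicInterval],
    reads_b: Sequence[GenomicInterval],
    alpha: float = 0.05,
    min_fold: float = 2.0,
    min_overlap_frac: float = 0.5,
    min_total_count: int = 5,
    normalize: bool = True,
    use_raw_p: bool = False,
) -> list[DMRRecord]:
    """Full DMR pipeline on two samples' peaks and aligned-read intervals.

    Library sizes are the total mapped reads per sample.  Returns the full
    per-region record list (sorted by coordinate) with ``is_dmr`` flags;
    filter on it for the significant set.
    """
    if len(reads_a) == 0 or len(reads_b) == 0:
        raise ValueError("zero total reads in a sample")
    regions = merge_peak_sets(peaks_a, peaks_b)
    counts_a = count_reads(regions, reads_a, min_overlap_frac)
    counts_b = count_reads(regions, reads_b, min_overlap_frac)
    merged = [
        MergedRegion(iv, int(ca), int(cb), len(reads_a), len(reads_b))
        for iv, ca, cb in zip(regions, counts_a, counts_b)
        if ca + cb > 0
    ]
    records = test_regions(
        merged,
        alpha=alpha,
        min_fold=min_fold,
        min_total_count=min_total_count,
        normalize=normalize,
        use_raw_p=use_raw_p,
    )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records


def significant(records: Sequence[DMRRecord]) -> list[DMRRecord]:
    return [r for r in records if r.is_dmr]


def records_to_frame(records: Sequence[DMRRecord]) -> pd.DataFrame:
    """Audit table of every tested region (significant or not)."""
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in records],
            "start": [r.interval.start for r in records],
            "end": [r.interval.end for r in records],
            "count_a": [r.region.count_a for r in records],
            "count_b": [r.region.count_b for r in records],
            "chi2": [r.chi2 for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "fold": [r.fold for r in records],
            "direction": [r.direction for r in records],
            "is_dmr": [r.is_dmr for r in records],
        }
    )


def dmrs_to_bed(records: Sequence[DMRRecord]) -> list[GenomicInterval]:
    """Significant DMRs as BED-ready intervals: name=direction,
    score=-10*log10(q) capped at 1000."""
    out = []
    for r in significant(records):
        score = 1000.0 if r.q <= 0 else min(1000.0, -10.0 * np.log10(r.q))
        out.append(
            GenomicInterval(
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                name=r.direction,
                score=round(score, 2),
            )
        )
    return out


def summarize_dmrs(
    records: Sequence[DMRRecord],
    annotation: FeatureAnnotation,
) -> dict:
    """Hyper/hypo counts plus per-class DMR density.

    Density uses the same definition as methylation density (DMR bp in
    class / class bp), computed separately for hyper and hypo sets over the
    genomic classes (intergenic, gene body, promoter) and repeat families.
    """
    sig = significant(records)
    hyper = [r.interval for r in sig if r.direction == "hyper"]
    hypo = [r.interval for r in sig if r.direction == "hypo"]

    gene_body = IntervalSet()
    for c in ("utr5", "cds", "intron", "utr3"):
        gene_body = gene_body.union(annotation.categories[c])
    grouped = FeatureAnnotation(
        genome=annotation.genome,
        categories={
            "intergenic": annotation.categories["intergenic"],
            "gene_body": gene_body,
            "promoter": annotation.categories["upstream2kb"],
        },
        repeats=annotation.repeats,
    )
    classes = ["intergenic", "gene_body", "promoter", *sorted(annotation.repeats)]
    return {
        "n_hyper": len(hyper),
        "n_hypo": len(hypo),
        "hyper_density": methylation_density(hyper, grouped, classes).densities,
        "hypo_density": methylation_density(hypo, grouped, classes).densities,
    }
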