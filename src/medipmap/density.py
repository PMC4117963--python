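"""Peak-to-feature annotation, methylation density, gene-body metaprofile
and methylated-CGI summaries.

The central definitions: a peak belongs to a feature category when at least
half of the peak lies in that category; methylation density of a class is
the merged-peak base pairs overlapping the class divided by the class's
total base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cgi import CpGIsland
from .genemodel import (
    CATEGORY_ORDER,
    CATEGORY_PRECEDENCE,
    FeatureAnnotation,
    GeneModel,
)
from .intervals import GenomicInterval, IntervalSet


@dataclass
class PeakAssignment:
    """Category membership of one peak under the >= 50%-overlap rule.

    ``category`` is the single partition category the peak maps to (ties at
    exactly 50/50 resolved by precedence; None when no category reaches
    50%, which cannot happen for the disjoint partition since it covers the
    genome).  ``repeat_classes`` lists overlay classes that independently
    reach 50%.
    """

    peak: GenomicInterval
    category: Optional[str]
    repeat_classes: list[str] = field(default_factory=list)
    in_repeat: bool = False


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    annotation: FeatureAnnotation,
    min_frac: float = 0.5,
) -> tuple[list[PeakAssignment], pd.Series]:
    """Assign each peak to feature categories by the >= 50% rule.

    Returns the per-peak assignments and a table row of per-category counts
    (column order: upstream 2 kb ... intergenic, then Repeats).  The repeat
    overlay is counted independently: the Repeats column counts peaks with
    >= 50% of their length in any repeat, and per-class incidences are
    tallied separately, so a peak can appear in a genic column and under
    Repeats — and the per-class incidence total can exceed the peak count.
    """
    repeat_union = annotation.repeat_union
    assignments: list[PeakAssignment] = []
    for peak in peaks:
        if peak.chrom not in annotation.genome:
            raise ValueError(f"peak {peak} outside genome")
        if peak.end > annotation.genome.length(peak.chrom):
            raise ValueError(f"peak {peak} outside chromosome bounds")
        need = min_frac * peak.length
        best: Optional[str] = None
        for cat in CATEGORY_PRECEDENCE:  # precedence order breaks 50/50 ties
            ov = annotation.categories[cat].overlap_length(
                peak.chrom, peak.start, peak.end
            )
            if ov >= need and ov > 0:
                best = cat
                break
        rep_classes = [
            cls
            for cls, track in sorted(annotation.repeats.items())
            if track.overlap_length(peak.chrom, peak.start, peak.end) >= need > 0
        ]
        in_rep = (
            repeat_union.overlap_length(peak.chrom, peak.start, peak.end) >= need > 0
        )
        assignments.append(PeakAssignment(peak, best, rep_classes, in_rep))

    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for a in assignments:
        if a.category is not None:
            counts[a.category] += 1
    row = pd.Series(counts, dtype=int)
    row["repeats"] = sum(a.in_repeat for a in assignments)
    row["total_peaks"] = len(assignments)
    return assignments, row


@dataclass
class DensityProfile:
    """Per-class methylation density: peak bp in class / class bp."""

    densities: dict[str, float]

    def __getitem__(self, cls: str) -> float:
        return self.densities[cls]

    def __contains__(self, cls: str) -> bool:
        return cls in self.densities

    def rank_order(self, classes: Sequence[str]) -> list[str]:
        """Given classes, return them sorted by descending density."""
        return sorted(classes, key=lambda c: -self.densities[c])

    def to_series(self) -> pd.Series:
        return pd.Series(self.densities)


def methylation_density(
    peaks: Sequence[GenomicInterval],
    annotation: FeatureAnnotation,
    classes: Optional[Sequence[str]] = None,
) -> DensityProfile:
    """Methylation density per feature class (and repeat class).

    Peaks are merged first so the density is invariant to how peaks are
    fragmented.  The pseudo-class ``genome`` reports the overall fraction of
    the genome under peaks.  Classes with zero area are omitted rather than
    reported as 0/0.
    """
    peak_set = IntervalSet(peaks)
    tracks: dict[str, IntervalSet] = dict(annotation.categories)
    tracks.update(annotation.repeats)
    if annotation.repeats:
        tracks["repeats"] = annotation.repeat_union
    wanted = list(classes) if classes is not None else [*tracks, "genome"]
    out: dict[str, float] = {}
    for cls in wanted:
        if cls == "genome":
            out["genome"] = peak_set.total_length() / annotation.genome.total_size
            continue
        track = tracks.get(cls)
        if track is None:
            continue
        area = track.total_length()
        if area == 0:
            continue  # empty class: absent, not a zero-division
        out[cls] = track.intersection_length(peak_set) / area
    return DensityProfile(out)


@dataclass
class MetaProfile:
    """Binned mean methylation density around the gene body.

    ``values`` holds, 5'→3' in transcription orientation: ``n_flank_bins``
    fixed-width upstream bins, ``body_bins`` relative gene-body bins, and
    ``n_flank_bins`` downstream bins.  ``n_genes`` is the number averaged;
    ``n_skipped`` counts genes shorter than ``body_bins`` bp.
    """

    values: np.ndarray
    n_flank_bins: int
    body_bins: int
    n_genes: int
    n_skipped: int

    def to_frame(self) -> pd.DataFrame:
        seg = (
            ["upstream"] * self.n_flank_bins
            + ["body"] * self.body_bins
            + ["downstream"] * self.n_flank_bins
        )
        return pd.DataFrame(
            {"bin": range(len(self.values)), "segment": seg, "density": self.values}
        )


def _bin_coverage(peak_set: IntervalSet, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Fraction of each [edges[i], edges[i+1]) bin covered by peaks; float
    edges supported for relative body bins."""
    vals = np.zeros(len(edges) - 1)
    for i in range(len(vals)):
        a, b = edges[i], edges[i + 1]
        if b <= a:
            continue
        ia, ib = int(np.floor(a)), int(np.ceil(b))
        if ib <= ia:
            continue
        # coverage of the fractional span via integer overlap minus edge excess
        cov = 0.0
        s = peak_set._starts.get(chrom)
        if s is None or len(s) == 0:
            continue
        e = peak_set._ends[chrom]
        i0 = int(np.searchsorted(e, a, side="right"))
        i1 = int(np.searchsorted(s, b, side="left"))
        for j in range(i0, i1):
            cov += max(0.0, min(float(e[j]), b) - max(float(s[j]), a))
        vals[i] = cov / (b - a)
    return np.clip(vals, 0.0, 1.0)


def gene_body_profile(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    body_bins: int = 40,
    flank_bin: int = 100,
) -> MetaProfile:
    """Average methylation density across gene bodies and 2-kb flanks.

    Flanks use fixed ``flank_bin``-bp bins; the body uses ``body_bins``
    equal relative bins.  Rows for − strand genes are reversed so bin 0 is
    always the most-upstream flank bin.  Genes shorter than ``body_bins``
    bp are skipped (and counted).
    """
    if flank <= 0 or body_bins < 1 or flank % flank_bin:
        raise ValueError("require flank > 0, body_bins >= 1, flank divisible by flank_bin")
    n_flank = flank // flank_bin
    peak_set = IntervalSet(peaks)
    rows = []
    skipped = 0
    for g in genes:
        iv = g.interval
        if iv.length < body_bins:
            skipped += 1
            continue
        up = np.arange(iv.start - flank, iv.start + 1, flank_bin, dtype=float)
        body = np.linspace(iv.start, iv.end, body_bins + 1)
        down = np.arange(iv.end, iv.end + flank + 1, flank_bin, dtype=float)
        row = np.concatenate(
            [
                _bin_coverage(peak_set, g.chrom, up),
                _bin_coverage(peak_set, g.chrom, body),
                _bin_coverage(peak_set, g.chrom, down),
            ]
        )
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    values = (
        np.mean(rows, axis=0) if rows else np.zeros(2 * n_flank + body_bins)
    )
    return MetaProfile(values, n_flank, body_bins, len(rows), skipped)


@dataclass
class CgiMethylationSummary:
    """Per-category counts of methylated CGIs plus the headline percentage."""

    category_counts: dict[str, int]
    total_methylated: int
    total_cgis: int

    @property
    def percent_methylated(self) -> float:
        return percent_methylated(self.total_methylated, self.total_cgis)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.category_counts, dtype=int)
        s["total_methylated"] = self.total_methylated
        s["total_cgis"] = self.total_cgis
        s["percent_methylated"] = self.percent_methylated
        return s


def percent_methylated(methylated: int, total: int) -> float:
    """Headline percentage, reported to two decimals."""
    return round(100.0 * methylated / total, 2) if total else 0.0


#: Table-2 column order; intergenic and unassignable CGIs fall under "other".
CGI_SUMMARY_CATEGORIES = (
    "upstream2kb",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "downstream2kb",
    "other",
)


def cgi_methylation_summary(
    cgis: Sequence[CpGIsland],
    peaks: Sequence[GenomicInterval],
    annotation: FeatureAnnotation,
    min_overlap_frac: float = 0.0,
) -> CgiMethylationSummary:
    """Count methylated CGIs and attribute them to genomic categories.

    A CGI is methylated when any part of it overlaps a peak (or at least
    ``min_overlap_frac`` of its length, when set).  Each methylated CGI is
    attributed to the single genic category covering >= 50% of it; CGIs in
    intergenic space or splitting below 50% everywhere count under
    ``other``.
    """
    peak_set = IntervalSet(peaks)
    counts = {c: 0 for c in CGI_SUMMARY_CATEGORIES}
    methylated = 0
    for cgi in cgis:
        iv = cgi.interval
        ov = peak_set.overlap_length(iv.chrom, iv.start, iv.end)
        need = min_overlap_frac * iv.length if min_overlap_frac > 0 else 1
        if ov < max(need, 1):
            continue
        methylated += 1
        cat = "other"
        for c in CATEGORY_PRECEDENCE[:-1]:  # genic categories only
            if (
                annotation.categories[c].overlap_length(iv.chrom, iv.start, iv.end)
                >= 0.5 * iv.length
            ):
                cat = c
                break
        counts[cat] += 1
    return CgiMethylationSummary(counts, methylated, len(cgis))
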