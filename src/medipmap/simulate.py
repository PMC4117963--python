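"""Synthetic MeDIP-seq study generator.

Produces a toy multi-chromosome genome with planted CpG islands, gene
models and labelled repeats, plus per-sample methylation peak tracks whose
per-class densities follow a configured profile (coding sequence highest,
promoter/5'UTR lowest, LINE above SINE/LTR among repeats), read intervals
drawn within peaks, paired FASTQ with a configurable fraction of reads
failing each QC criterion, and planted fold-change differences between two
samples.  Ground truth is recorded alongside every output so parameter
recovery can be scored.

Everything is driven by one integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genemodel import FeatureAnnotation, GeneModel, derive_features
from .intervals import GenomeIndex, GenomicInterval, IntervalSet
from .io import Genome, SeqRead, write_bed, write_fastq, write_gff
from .dmr import MergedRegion


class SimulationError(ValueError):
    pass


#: Default per-class peak densities, ordered like the study's qualitative
#: pattern: CDS highest, then intergenic, intron, 3'UTR, downstream flank,
#: upstream flank (promoter), 5'UTR lowest; LINE above SINE and LTR among
#: repeat families.
DEFAULT_CLASS_DENSITY = {
    "cds": 0.35,
    "intergenic": 0.22,
    "intron": 0.16,
    "utr3": 0.12,
    "downstream2kb": 0.09,
    "upstream2kb": 0.06,
    "utr5": 0.025,
    "LINE": 0.25,
    "SINE": 0.14,
    "LTR": 0.10,
    "DNA": 0.08,
    "satellite": 0.06,
    "simple": 0.05,
    "low_complexity": 0.04,
}

DEFAULT_N_REPEATS = {
    "LINE": 40,
    "SINE": 40,
    "LTR": 25,
    "DNA": 15,
    "satellite": 8,
    "simple": 12,
    "low_complexity": 12,
}

#: Repeat element length ranges (bp) per class.
REPEAT_LENGTHS = {
    "LINE": (500, 3000),
    "SINE": (100, 300),
    "LTR": (300, 1000),
    "DNA": (200, 800),
    "satellite": (300, 2000),
    "simple": (50, 200),
    "low_complexity": (50, 300),
}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Densities are coverage fractions in [0, 1]; ``reads_per_peak_mean`` is
    the Poisson mean read count per peak in the baseline sample;
    ``planted_log2_fold`` of 2 with the default mean of 10 realizes the
    40-vs-10 read contrast used for recovery studies.  ``qc_fail_fracs``
    sets the fraction of FASTQ pairs built to fail each QC criterion (the
    remainder, about 84%, is clean).
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 80
    n_repeats: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_REPEATS))
    cgi_per_promoter_prob: float = 0.6
    n_intergenic_cgis: int = 8
    cgi_length_range: tuple[int, int] = (1350, 1500)
    class_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DENSITY)
    )
    n_samples: int = 2
    planted_dmrs: Optional[list[tuple[GenomicInterval, float, str]]] = None
    n_planted_dmrs: int = 30
    planted_log2_fold: float = 2.0
    reads_per_peak_mean: float = 10.0
    read_length: int = 50
    background_peak_rate: float = 0.5  # peaks per Mb outside planted structure
    background_reads_per_mb: float = 100.0
    gc_background: float = 0.41
    flank: int = 2000
    qc_fail_fracs: dict[str, float] = field(
        default_factory=lambda: {
            "n_frac": 0.05,
            "mean_q": 0.045,
            "low_q_frac": 0.045,
            "pair_identical": 0.02,
        }
    )

    def __post_init__(self) -> None:
        for cls, d in self.class_density.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"density for {cls} outside [0, 1]")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if not 0.0 <= self.cgi_per_promoter_prob <= 1.0:
            raise ValueError("cgi_per_promoter_prob outside [0, 1]")

    @property
    def sample_names(self) -> list[str]:
        return [f"sample{chr(ord('A') + i)}" for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground truth serialized alongside the simulated study."""

    cgis: list[GenomicInterval] = field(default_factory=list)
    sample_peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    dmrs: list[dict] = field(default_factory=list)
    class_density: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def spans(ivs):
            return [[iv.chrom, iv.start, iv.end] for iv in ivs]

        with open(path, "w") as fh:
            json.dump(
                {
                    "cgis": spans(self.cgis),
                    "sample_peaks": {s: spans(p) for s, p in self.sample_peaks.items()},
                    "dmrs": self.dmrs,
                    "class_density": self.class_density,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# genome simulation


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Background sequence as a uint8 array: i.i.d. bases at the target GC,
    then 70% of CpG dinucleotides depleted (C->T) to mimic the genome-wide
    CpG deficit that gives island scanning its contrast."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    if n > 1:
        cpg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        hit = cpg[rng.random(len(cpg)) < 0.7]
        arr[hit] = ord("T")
    return arr


def _cgi_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Island sequence: i.i.d. at GC 0.65, CpG O/E ~ 1 by independence.

    The moderate GC keeps the scanning window's boundary smoothing short
    (a window straddling the island edge needs ~75 island bp to qualify),
    so detected islands stay close to the planted extent.
    """
    p = [0.175, 0.325, 0.325, 0.175]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _make_gene(
    rng: np.random.Generator, chrom: str, start: int, length: int, gene_id: str
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(2, 7))
    # 2*n_ex - 1 alternating exon/intron segments, each at least 150 bp
    n_seg = 2 * n_ex - 1
    w = rng.dirichlet(np.ones(n_seg))
    seg = np.maximum((w * length).astype(int), 150)
    seg[-1] = max(150, length - int(seg[:-1].sum()))
    pos = start
    exons: list[tuple[int, int]] = []
    for i, sl in enumerate(seg):
        if i % 2 == 0:
            exons.append((pos, pos + int(sl)))
        pos += int(sl)
    end = exons[-1][1]
    utr5_len = int(rng.integers(50, min(400, exons[0][1] - exons[0][0])))
    utr3_len = int(rng.integers(50, min(400, exons[-1][1] - exons[-1][0])))
    if strand == "+":
        cds = (exons[0][0] + utr5_len, exons[-1][1] - utr3_len)
    else:
        cds = (exons[0][0] + utr3_len, exons[-1][1] - utr5_len)
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=exons,
        cds_span=cds,
    )


def simulate_genome(
    config: SimConfig,
) -> tuple[Genome, list[GeneModel], list[GenomicInterval], SimTruth]:
    """Generate genome FASTA content, gene models, repeat track and truth."""
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(class_density=dict(config.class_density))
    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    # chromosome lengths taper (like a real karyotype) so per-chromosome
    # statistics have variance; mean length equals config.chrom_length
    if config.n_chroms > 1:
        factors = [1.3 - 0.6 * i / (config.n_chroms - 1) for i in range(config.n_chroms)]
    else:
        factors = [1.0]
    chrom_lengths = {
        c: int(config.chrom_length * f) for c, f in zip(chrom_names, factors)
    }
    for chrom in chrom_names:
        seqs[chrom] = _random_background(rng, chrom_lengths[chrom], config.gc_background)

    # genes: non-overlapping with at least `flank` clearance, allocated to
    # chromosomes proportionally to their lengths
    total_len = sum(chrom_lengths.values())
    per_chrom = [
        int(round(config.n_genes * chrom_lengths[c] / total_len)) for c in chrom_names
    ]
    while sum(per_chrom) > config.n_genes:
        per_chrom[per_chrom.index(max(per_chrom))] -= 1
    while sum(per_chrom) < config.n_genes:
        per_chrom[per_chrom.index(min(per_chrom))] += 1
    gid = 0
    for chrom, quota in zip(chrom_names, per_chrom):
        cursor = config.flank + int(rng.integers(0, 5000))
        for _ in range(quota):
            length = int(rng.integers(3000, 12001))
            if cursor + length + 2500 + config.flank > chrom_lengths[chrom]:
                raise SimulationError(
                    f"genes do not fit on {chrom}: increase chrom_length"
                )
            genes.append(_make_gene(rng, chrom, cursor, length, f"gene{gid:04d}"))
            gid += 1
            cursor = genes[-1].interval.end + 2 * config.flank + int(
                rng.integers(500, 8000)
            )

    # CpG islands: promoter-associated and intergenic
    lo, hi = config.cgi_length_range
    for g in genes:
        if rng.random() >= config.cgi_per_promoter_prob:
            continue
        clen = int(rng.integers(lo, hi + 1))
        if g.strand == "+":
            s = max(0, g.tss - int(rng.integers(0, clen // 2)))
        else:
            s = min(
                chrom_lengths[g.chrom] - clen,
                g.tss - clen + int(rng.integers(0, clen // 2)),
            )
        e = s + clen
        seqs[g.chrom][s:e] = _cgi_sequence(rng, clen)
        truth.cgis.append(GenomicInterval(g.chrom, s, e))
    occupied_cgi = IntervalSet(truth.cgis)
    for chrom in chrom_names:
        gene_space = IntervalSet(
            GenomicInterval(
                chrom,
                max(0, g.interval.start - config.flank),
                min(chrom_lengths[chrom], g.interval.end + config.flank),
            )
            for g in genes
            if g.chrom == chrom
        )
        placed = 0
        attempts = 0
        while placed < config.n_intergenic_cgis and attempts < 200:
            attempts += 1
            clen = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(0, chrom_lengths[chrom] - clen))
            if gene_space.covers_any(chrom, s - 300, s + clen + 300):
                continue
            if occupied_cgi.covers_any(chrom, s - 300, s + clen + 300):
                continue
            seqs[chrom][s : s + clen] = _cgi_sequence(rng, clen)
            iv = GenomicInterval(chrom, s, s + clen)
            truth.cgis.append(iv)
            occupied_cgi = occupied_cgi.union(IntervalSet([iv]))
            placed += 1

    # repeats: annotation-only intervals in intron/intergenic space
    exon_space = IntervalSet(
        GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons
    )
    flank_space = IntervalSet(
        GenomicInterval(
            g.chrom,
            max(0, g.interval.start - config.flank),
            min(chrom_lengths[g.chrom], g.interval.end + config.flank),
        )
        for g in genes
    ).subtract(
        IntervalSet(GenomicInterval(g.chrom, g.interval.start, g.interval.end) for g in genes)
    )
    blocked = exon_space.union(flank_space).union(occupied_cgi)
    occupied_rep = IntervalSet()
    for cls in sorted(config.n_repeats):
        quota = config.n_repeats[cls]
        rlo, rhi = REPEAT_LENGTHS.get(cls, (100, 1000))
        placed = 0
        attempts = 0
        while placed < quota and attempts < quota * 50:
            attempts += 1
            chrom = chrom_names[int(rng.integers(0, config.n_chroms))]
            rlen = int(rng.integers(rlo, rhi + 1))
            s = int(rng.integers(0, chrom_lengths[chrom] - rlen))
            if blocked.covers_any(chrom, s, s + rlen):
                continue
            if occupied_rep.covers_any(chrom, s - 1, s + rlen + 1):
                continue
            iv = GenomicInterval(chrom, s, s + rlen, name=cls)
            repeats.append(iv)
            occupied_rep = occupied_rep.union(IntervalSet([iv]))
            placed += 1
        if placed < quota:
            raise SimulationError(
                f"could not place {quota} {cls} repeats (placed {placed}); "
                "genome too small or too crowded"
            )

    genome = Genome(
        {c: seqs[c].tobytes().decode("ascii") for c in chrom_names}, chrom_names
    )
    truth.cgis.sort(key=lambda iv: (iv.chrom, iv.start))
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome, genes, repeats, truth


# ---------------------------------------------------------------------------
# peak placement


def _place_peaks_in_interval(
    rng: np.random.Generator,
    iv: GenomicInterval,
    quota: int,
    min_len: int = 100,
    max_len: int = 500,
) -> list[GenomicInterval]:
    """Place non-overlapping peaks totalling ~``quota`` bp inside ``iv``."""
    if quota < min_len or iv.length < min_len + 2:
        return []
    quota = min(quota, iv.length - 2)
    lens: list[int] = []
    rem = quota
    while rem >= min_len:
        L = int(rng.integers(min_len, max_len + 1))
        L = min(L, rem)
        if L < min_len:
            L = min_len
        lens.append(L)
        rem -= L
    if rem > 0 and lens and lens[-1] + rem <= max_len:
        lens[-1] += rem
    # shrink if peaks plus 1-bp separating gaps exceed the interval
    while lens and sum(lens) + len(lens) + 1 > iv.length:
        lens.pop()
    if not lens:
        return []
    free = iv.length - sum(lens) - (len(lens) - 1)  # interior 1-bp gaps reserved
    cuts = rng.dirichlet(np.ones(len(lens) + 1)) * max(free, 0)
    peaks = []
    pos = iv.start
    for i, L in enumerate(lens):
        pos += int(cuts[i]) + (1 if i else 0)
        pos = min(pos, iv.end - L)
        peaks.append(GenomicInterval(iv.chrom, pos, pos + L))
        pos += L
    return peaks


def _place_class_peaks(
    rng: np.random.Generator,
    space: IntervalSet,
    target_bp: int,
    cls: str,
    min_len: int = 100,
) -> list[GenomicInterval]:
    """Peaks totalling ~``target_bp`` bp across the class space.

    Quota is allocated with a credit-carry sweep over the (shuffled)
    intervals: sub-minimum or over-capacity allocations roll over to later
    intervals, so the realized coverage tracks the target even for classes
    made of many sub-peak-sized fragments (UTRs, short repeats).
    """
    if target_bp <= 0:
        return []
    intervals = [iv for iv in space if iv.length >= min_len + 2]
    total = sum(iv.length for iv in intervals)
    if total == 0:
        return []
    if target_bp > 0.9 * space.total_length():
        raise SimulationError(
            f"class_density unreachable for {cls!r}: "
            f"need {target_bp} bp of peaks in {space.total_length()} bp of space"
        )
    order = rng.permutation(len(intervals))
    peaks: list[GenomicInterval] = []
    credit = 0.0
    for idx in order:
        iv = intervals[idx]
        credit += target_bp * iv.length / total
        placed = _place_peaks_in_interval(rng, iv, int(credit), min_len=min_len)
        credit -= sum(p.length for p in placed)
        peaks.extend(placed)
    return peaks


def simulate_peaks(
    config: SimConfig,
    annotation: FeatureAnnotation,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """One sample's peak track realizing the configured class densities.

    Repeat-class peaks are placed first inside repeat elements; each
    partition category is then topped up in its repeat-free space so both
    the overlay densities and the partition densities land on target.
    """
    peaks: list[GenomicInterval] = []
    for cls in sorted(annotation.repeats):
        d = config.class_density.get(cls)
        if d is None:
            continue
        space = annotation.repeats[cls]
        peaks.extend(_place_class_peaks(rng, space, int(d * space.total_length()), cls))
    placed = IntervalSet(peaks)
    repeat_union = annotation.repeat_union
    for cls, track in annotation.categories.items():
        d = config.class_density.get(cls)
        if d is None:
            continue
        target = int(d * track.total_length())
        already = track.intersection_length(placed)
        free = track.subtract(repeat_union)
        if target - already > 0.9 * free.total_length():
            raise SimulationError(
                f"class_density unreachable for {cls!r} after repeat overlay"
            )
        peaks.extend(_place_class_peaks(rng, free, target - already, cls))
    # sparse background peaks anywhere peaks do not already sit
    n_bg = rng.poisson(
        config.background_peak_rate * annotation.genome.total_size / 1e6
    )
    occupied = IntervalSet(peaks)
    for _ in range(int(n_bg)):
        chrom, clen = annotation.genome.chroms[
            int(rng.integers(0, len(annotation.genome.chroms)))
        ]
        L = int(rng.integers(100, 501))
        s = int(rng.integers(0, clen - L))
        if not occupied.covers_any(chrom, s - 1, s + L + 1):
            peaks.append(GenomicInterval(chrom, s, s + L))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


# ---------------------------------------------------------------------------
# methylome simulation (peaks, reads, FASTQ, planted DMRs)


def simulate_methylome(
    config: SimConfig,
    annotation: FeatureAnnotation,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[GenomicInterval]], SimTruth]:
    """Per-sample peaks and read intervals with planted DMRs.

    All samples share the peak template (the study merges peaks anyway);
    read counts per peak are Poisson with the planted fold applied to the
    hypermethylated side of each DMR.  Returns (peaks, reads, truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    template = simulate_peaks(config, annotation, rng)
    truth = SimTruth(class_density=dict(config.class_density))

    # choose planted DMR peaks (roomy ones, so reads fit comfortably)
    if config.planted_dmrs is not None:
        planted = list(config.planted_dmrs)
    else:
        candidates = [i for i, p in enumerate(template) if p.length >= 200]
        k = min(config.n_planted_dmrs, len(candidates))
        chosen = rng.choice(candidates, size=k, replace=False) if k else []
        planted = [
            (
                template[int(i)],
                config.planted_log2_fold,
                "hyper" if j % 2 == 0 else "hypo",
            )
            for j, i in enumerate(sorted(chosen))
        ]
    dmr_lookup = {
        (iv.chrom, iv.start, iv.end): (2.0**log2f, direction)
        for iv, log2f, direction in planted
    }
    for iv, log2f, direction in planted:
        truth.dmrs.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "log2_fold": log2f,
                "direction": direction,
            }
        )

    peaks: dict[str, list[GenomicInterval]] = {}
    reads: dict[str, list[GenomicInterval]] = {}
    names = config.sample_names
    for si, sample in enumerate(names):
        peaks[sample] = list(template)
        truth.sample_peaks[sample] = list(template)
        sample_reads: list[GenomicInterval] = []
        for peak in template:
            mean = config.reads_per_peak_mean
            key = (peak.chrom, peak.start, peak.end)
            if key in dmr_lookup and si < 2:
                fold, direction = dmr_lookup[key]
                boosted = (direction == "hyper" and si == 0) or (
                    direction == "hypo" and si == 1
                )
                if boosted:
                    mean *= fold
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            span = max(1, peak.length - config.read_length)
            starts = rng.integers(peak.start, peak.start + span, size=n)
            for s in starts:
                s = int(s)
                e = min(s + config.read_length, annotation.genome.length(peak.chrom))
                sample_reads.append(GenomicInterval(peak.chrom, s, e))
        n_bg = int(
            rng.poisson(
                config.background_reads_per_mb * annotation.genome.total_size / 1e6
            )
        )
        for _ in range(n_bg):
            chrom, clen = annotation.genome.chroms[
                int(rng.integers(0, len(annotation.genome.chroms)))
            ]
            s = int(rng.integers(0, clen - config.read_length))
            sample_reads.append(GenomicInterval(chrom, s, s + config.read_length))
        sample_reads.sort(key=lambda r: (r.chrom, r.start))
        reads[sample] = sample_reads
    return peaks, reads, truth


_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_fastq_pairs(
    config: SimConfig,
    genome: Genome,
    read_intervals: Sequence[GenomicInterval],
    rng: np.random.Generator,
    sample: str,
) -> tuple[list[SeqRead], list[SeqRead]]:
    """Paired reads for the QC stage; a configured fraction of pairs is
    built to fail each of the four criteria."""
    modes = list(config.qc_fail_fracs)
    probs = [config.qc_fail_fracs[m] for m in modes]
    p_clean = 1.0 - sum(probs)
    if p_clean < 0:
        raise ValueError("qc_fail_fracs sum above 1")
    r1s: list[SeqRead] = []
    r2s: list[SeqRead] = []
    for i, iv in enumerate(read_intervals):
        seq1 = genome.fetch(iv)
        seq2 = seq1.translate(_COMP)[::-1]
        n = len(seq1)
        q1 = np.clip(rng.normal(38, 2, n).round(), 2, 41).astype(int)
        q2 = np.clip(rng.normal(38, 2, n).round(), 2, 41).astype(int)
        mode = rng.choice(modes + ["clean"], p=probs + [p_clean])
        if mode == "n_frac":
            k = int(np.ceil(0.10 * n))
            pos = rng.choice(n, size=k, replace=False)
            arr = np.frombuffer(seq1.encode(), dtype=np.uint8).copy()
            arr[pos] = ord("N")
            seq1 = arr.tobytes().decode()
        elif mode == "mean_q":
            q1 = np.clip(rng.normal(15, 2, n).round(), 2, 41).astype(int)
        elif mode == "low_q_frac":
            k = int(np.ceil(0.06 * n))
            pos = rng.choice(n, size=k, replace=False)
            q1[pos] = 10
        elif mode == "pair_identical":
            seq2 = seq1
        rid = f"{sample}_read{i:07d}"
        r1s.append(SeqRead(f"{rid}/1", seq1, list(q1)))
        r2s.append(SeqRead(f"{rid}/2", seq2, list(q2)))
    return r1s, r2s


# ---------------------------------------------------------------------------
# file-level entry point


def simulate_study(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Run the full generator and write genome.fa, genes.gff, repeats.bed,
    per-sample peaks/reads BED + FASTQ pairs, and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, repeats, gtruth = simulate_genome(config)
    annotation = derive_features(genes, genome.index, config.flank, repeats)
    rng = np.random.default_rng(config.seed + 1)
    peaks, reads, mtruth = simulate_methylome(config, annotation, rng)
    truth = SimTruth(
        cgis=gtruth.cgis,
        sample_peaks=mtruth.sample_peaks,
        dmrs=mtruth.dmrs,
        class_density=dict(config.class_density),
    )
    genome.to_fasta(outdir / "genome.fa")
    write_gff(genes, outdir / "genes.gff")
    write_bed(repeats, outdir / "repeats.bed")
    for sample in config.sample_names:
        write_bed(peaks[sample], outdir / f"{sample}.peaks.bed")
        write_bed(reads[sample], outdir / f"{sample}.reads.bed")
        r1s, r2s = simulate_fastq_pairs(config, genome, reads[sample], rng, sample)
        write_fastq(r1s, outdir / f"{sample}_1.fastq")
        write_fastq(r2s, outdir / f"{sample}_2.fastq")
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# region-count simulation for DMR calibration and recovery studies


def simulate_region_counts(
    n_null: int,
    n_planted: int = 0,
    fold: float = 4.0,
    mean: float = 10.0,
    null_mean: Optional[float] = None,
    library_size: int = 1_000_000,
    region_length: int = 300,
    seed: int = 0,
) -> tuple[list[MergedRegion], np.ndarray]:
    """Poisson read counts in merged regions, the substrate the chi-square
    DMR test sees.

    Null regions draw both samples at ``null_mean`` (default ``mean``);
    planted regions draw sample A at ``mean * fold`` and sample B at
    ``mean``.  Returns the regions and a boolean planted mask.  Regions
    where both samples drew zero are dropped (they carry no information),
    as in the pipeline.
    """
    rng = np.random.default_rng(seed)
    nm = mean if null_mean is None else null_mean
    n = n_null + n_planted
    a = np.concatenate(
        [rng.poisson(nm, n_null), rng.poisson(mean * fold, n_planted)]
    )
    b = np.concatenate([rng.poisson(nm, n_null), rng.poisson(mean, n_planted)])
    is_planted = np.zeros(n, dtype=bool)
    is_planted[n_null:] = True
    regions = []
    keep = []
    for i in range(n):
        if a[i] + b[i] == 0:
            continue
        start = 1000 + i * (region_length + 700)
        regions.append(
            MergedRegion(
                GenomicInterval("chr1", start, start + region_length),
                int(a[i]),
                int(b[i]),
                library_size,
                library_size,
            )
        )
        keep.append(i)
    return regions, is_planted[keep]
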