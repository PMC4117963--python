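# Methods

This note documents the statistical procedures, the synthetic-study
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Coordinate model

All coordinates are 0-based half-open (BED semantics) internally; the
GFF-lite gene format is 1-based inclusive on disk and converted on read.
Interval tracks are held as merged, sorted, per-chromosome sets; every
algebraic operation (merge, intersect, subtract, per-span overlap) is
verified in the tests against per-base-pair boolean-array oracles, so the
rest of the pipeline can treat the algebra as exact.

## Feature partition

Gene models induce seven categories: upstream 2 kb of the TSS, 5'UTR, CDS,
intron, 3'UTR, downstream 2 kb of the TTS, and intergenic. Flanks follow
transcription orientation and are clipped at chromosome edges. Where
categories of different genes overlap, a fixed per-base-pair precedence
(CDS > 5'UTR > 3'UTR > intron > upstream > downstream > intergenic) makes
the partition disjoint and total — a requirement for density denominators
and a property the tests check exactly. Repeats are an independent overlay
keyed by class (LINE, SINE, LTR, DNA, satellite, simple, low-complexity):
a peak can count both in a genic category and in a repeat class, so repeat
incidence totals may exceed the peak count. Non-coding genes (no CDS span)
contribute their exonic bases to the CDS category as an exon proxy; the
UTR labels are reserved for genes whose coding span is known.

## Read quality filter

The four clean-data criteria are evaluated in order (N fraction ≥ 0.10,
mean quality < 20, fraction of bases under Q20 ≥ 0.05, identical mate
sequences) and a removed pair is attributed to the first criterion that
fails, so the report's counts sum exactly to the total. The
identical-mates rule is the literal reading of an ambiguous criterion and
can be switched off (`pair_identical_filter=False`). Adapter trimming is
expected upstream. The FASTQ Phred offset (33/64) is auto-detected from
the quality byte range and recorded in the report.

## CpG-island scanner

A 200-bp window slides at 1-bp steps; a window qualifies when GC ≥ 0.5 and
O/E ≥ 0.6, computing O/E as (#CpG · N)/(#C · #G) with CpG dinucleotides
counted only when fully inside the window. N positions are excluded from
every denominator and windows that are more than half N are disqualified —
otherwise assembly gaps inflate O/E. Qualifying windows are unioned and
merged; merged candidates of length ≤ 200 are discarded; each survivor is
re-verified on its full extent and, when the criteria fail there, shrunk
one terminal base at a time — dropping the end whose base scores lower
(G/C worth 2, CpG membership 1 more, ties drop the left end) — until the
criteria hold or the candidate reaches the 200-bp floor. This
shrink-from-the-ends rule was chosen over two-phase extension schemes
because it is simple enough to mirror in an exhaustive per-window oracle;
the tests require exact agreement with that oracle and independent
re-verification of the three criteria on every reported island.

## Methylation density and profiles

density(class) = merged-peak bp overlapping the class / class bp. Merging
first makes the statistic invariant to peak fragmentation (tested). The
pseudo-class `genome` gives the overall covered fraction. The gene-body
metaprofile uses 20 fixed 100-bp bins per 2-kb flank and 40 relative bins
across the body (bin counts are configuration, not biology; the defaults
are a plumbing choice), each bin holding the fraction covered by peaks,
rows flipped for − strand genes, averaged unweighted across genes; genes
shorter than the bin count are skipped and counted. A CpG island is
"methylated" when ≥ 1 bp overlaps a peak — the most inclusive reading;
`min_overlap_frac` tightens it — and each methylated island is attributed
to the genic category covering ≥ 50% of it, else to "other". Percentages
are reported to two decimals.

## DMR calling

Merged peak regions are the union's connected components (book-ended
intervals join). A read counts toward a region when ≥ 50% of the read
overlaps it (mirroring the peak-annotation rule) and is assigned at most
once, to the region of maximal overlap. Each region's 2×2 table of region
reads vs rest-of-library per sample is tested by Pearson chi-square with
1 df and no continuity correction; regions with fewer than 5 reads total
are dropped before testing because the chi-square approximation is invalid
there, and zero–zero regions carry no information. The selection threshold
is applied to Benjamini–Hochberg-adjusted values (q < 0.05): the procedure
names an FDR jointly with the test, and an FDR is meaningless unless used
for selection; `use_raw_p=True` restores raw-p thresholding. Fold-change
is computed on library-size-normalized rates — unequal depth otherwise
fabricates DMRs — with a 0.5 pseudocount on zero cells only (the
chi-square sees the raw counts); `normalize=False` reproduces the literal
raw-count ratio. DMRs require fold strictly greater than 2 in either
direction; direction is hyper when sample A's normalized rate is higher.

Calibration, measured by the acceptance machinery on Poisson region
counts: the null raw-p < 0.05 fraction sits near 0.045–0.055, and BH keeps
null calls far below 5%. For 50 planted fold-4 regions (means 40 vs 10)
among 500 nulls, pooled sensitivity is ≈ 0.94 with empirical FDR ≈ 0.04,
and sensitivity is strongly monotone in the planted fold (≈ 0.001 / 0.21 /
0.94 at folds 1.5 / 2.5 / 4). The ≈ 0.94 ceiling is a property of the
procedure at those depths: BH over ~550 tests with ~50 true signals
implies an effective per-test threshold near 0.05 · 50/550 ≈ 4.5×10⁻³,
and the probability that a Poisson(40)-vs-Poisson(10) contrast clears the
corresponding chi-square cut is about 0.94. Deeper coverage or fewer
tested regions raise it; nothing in the calling code can without weakening
the multiplicity correction.

## TSS clustering and correlation

The TSS matrix bins merged intervals over TSS ± 5 kb in 100-bp bins
(coverage fraction per bin, − strand rows reversed). Clustering is
scikit-learn k-means (k-means++ initialization, best of `n_init` restarts,
deterministic under a fixed seed); the tests verify the k = 1 closed form
and, on 6-row instances, equality of best-of-restarts inertia with the
exhaustive minimum over all 2-partitions — tiny instances have deceptive
Lloyd fixed points, so that equivalence is exercised with a generous
restart budget. k defaults to 5 but is a free parameter — published
analyses of this kind variously use 5 to 11 clusters, and nothing in the
method fixes the count. Cluster-significance statistics attached to such
clusterings rarely come with a stated test; `cluster_tightness_pvalue`
provides a clearly-labelled permutation check (within-row shuffles vs
observed inertia), not a replication of any particular one. Pearson correlations of per-chromosome peak
counts against chromosome length and gene count use scipy and error on
zero variance or fewer than three chromosomes.

## Synthetic-study generator

The generator emulates the study's inputs, not its sequencing chemistry.
Background sequence is i.i.d. at GC 0.41 (a mammalian-like baseline chosen
for scanner contrast, not a claim about any genome) with 70% of background
CpG dinucleotides depleted (C→T), mimicking the genome-wide CpG deficit.
Chromosome lengths taper (±30% around the configured mean) so
per-chromosome statistics have variance. Genes are non-overlapping with
≥ 2-kb clearance, 3–12 kb long with 2–6 exons and a CDS leaving 50–400 bp
UTRs; genes are allocated to chromosomes proportionally to length, which
yields the positive peak-count correlations the diagnostics expect.

Planted CpG islands are i.i.d. GC 0.65 sequence (O/E ≈ 1 by independence),
1,350–1,500 bp by default: a 200-bp window straddling an island edge
qualifies once ~75 island bp are inside, so detected islands extend
~120–140 bp per side into background; at these lengths truth and detection
stay within 80% reciprocal overlap, which is what the recovery tests
assert. Shorter islands remain valid configuration but blur that
correspondence.

Peaks (100–500 bp) are placed class by class to hit configured per-class
densities: repeat-class peaks first inside repeat elements, then each
partition category topped up in its repeat-free space, so overlay and
partition densities land on target simultaneously (the generator raises,
naming the limiting class, when a density is unreachable). Within a class,
quota is allocated by a credit-carry sweep over shuffled intervals —
sub-minimum or over-capacity allocations roll to later intervals — which
keeps even fragmented classes (UTRs, short repeats) within ~0.01 of
target; mean absolute density error across classes is ≤ 0.02 at the
default megabase scale (tested). The default density profile follows the
qualitative pattern the analyses expect: CDS 0.35 > intergenic 0.22 >
intron 0.16 > 3'UTR 0.12 > downstream 0.09 > upstream 0.06 > 5'UTR 0.025,
and LINE 0.25 above SINE 0.14 and LTR 0.10.

Both samples share the peak template (downstream analysis merges peaks
anyway). Reads are 50-bp intervals placed uniformly within peaks with
Poisson counts (default mean 10), plus uniform background reads
(100/Mb). Planted DMRs (default 30 peaks, log2 fold 2 — i.e. 40 vs 10
expected reads — alternating hyper/hypo) multiply the Poisson mean on the
boosted side. Paired FASTQ is generated from the read intervals with a
configured mix of QC failures (5% N-rich, 4.5% low mean quality, 4.5%
low-quality-tail, 2% identical mates ⇒ ≈ 84% clean, a clean-data fraction
typical of MeDIP-seq runs). A fixed seed makes every output
file byte-identical across runs.

For DMR calibration and power studies, `simulate_region_counts` generates
the Poisson region counts directly — the exact substrate the chi-square
test consumes — so 200-replicate studies run in seconds; the full
genome-level path is exercised separately by the end-to-end tests.

What the generator does **not** emulate: sequencing errors and quality-by-
cycle structure, fragment-size distributions beyond the uniform peak
lengths, immunoprecipitation efficiency and CpG-density-dependent MeDIP
bias, overdispersed (non-Poisson) counts, and diploid variation. Passing
tests therefore demonstrate correctness of the statistics and the
pipeline's contracts under idealized counts, not robustness to biological
overdispersion — a negative-binomial count model would be the natural
extension if that mattered.

## Problem sizes and runtime

The test suite runs small studies (2–3 chromosomes of 0.1–0.3 Mb) for
speed and one default-scale study (3 chromosomes averaging 1 Mb) for the
density-fidelity and rank-pattern checks; DMR calibration uses 4,000 null
regions and recovery 200 replicates of 550 regions. The acceptance script
repeats the scanner-oracle comparison on fifty 50-kb sequences. Everything
completes in well under a minute on one core.

## Known limitations

- The chi-square DMR test assumes Poisson-like counts; biological
  replicates with overdispersion need a negative-binomial test, which is
  out of scope here.
- Only two-sample comparisons are supported; multi-sample designs must be
  run pairwise.
- One transcript model per gene; alternative isoforms are not represented.
- CGI shores/shelves and promoter-CGI sub-analyses beyond the upstream-2kb
  category are not implemented.
- MeDIP signal is not deconvolved against CpG density; densities are raw
  coverage fractions.
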