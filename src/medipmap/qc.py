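"""Four-criteria paired-end FASTQ filter defining "clean data".

A read pair is discarded when either mate has (1) >= 10% N bases, (2) mean
Phred quality below 20, or (3) >= 5% of bases below quality 20, or when (4)
the two mates carry identical base strings.  Removal is attributed to the
first failing criterion in that order.  Adapter trimming is out of scope and
expected upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .io import SeqRead, detect_phred_offset, read_fastq, write_fastq

CRITERIA = ("n_frac", "mean_q", "low_q_frac", "pair_identical")


@dataclass
class QCThresholds:
    max_n_frac: float = 0.10        # criterion 1: N fraction >= this removes
    min_mean_q: float = 20.0        # criterion 2: mean quality < this removes
    max_low_q_frac: float = 0.05    # criterion 3: fraction of bases with Q < low_q >= this removes
    low_q: int = 20
    pair_identical_filter: bool = True  # criterion 4 switch


@dataclass
class QCReport:
    """Accounting of a filtering run; counts attribute each removed pair to
    its first failing criterion, so kept + removals = total."""

    total_pairs: int = 0
    kept_pairs: int = 0
    removed_by_criterion: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CRITERIA}
    )
    phred_offset: Optional[int] = None

    @property
    def clean_fraction(self) -> float:
        return self.kept_pairs / self.total_pairs if self.total_pairs else 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_pairs": self.total_pairs,
                    "kept_pairs": self.kept_pairs,
                    "removed_by_criterion": self.removed_by_criterion,
                    "clean_fraction": round(self.clean_fraction, 6),
                    "phred_offset": self.phred_offset,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _first_failing(pair: tuple[SeqRead, SeqRead], t: QCThresholds) -> Optional[str]:
    r1, r2 = pair
    for r in (r1, r2):
        n = len(r.bases)
        if n and r.bases.count("N") / n >= t.max_n_frac:
            return "n_frac"
    for r in (r1, r2):
        if r.quals and sum(r.quals) / len(r.quals) < t.min_mean_q:
            return "mean_q"
    for r in (r1, r2):
        if r.quals and sum(q < t.low_q for q in r.quals) / len(r.quals) >= t.max_low_q_frac:
            return "low_q_frac"
    if t.pair_identical_filter and r1.bases == r2.bases:
        return "pair_identical"
    return None


def filter_reads(
    pairs: Iterable[tuple[SeqRead, SeqRead]],
    thresholds: Optional[QCThresholds] = None,
    report: Optional[QCReport] = None,
) -> Iterator[tuple[SeqRead, SeqRead]]:
    """Yield pairs passing all four criteria, preserving input order.

    The report (created if not supplied, and mutated in place so callers can
    pass their own) tallies removals by first failing criterion.
    """
    t = thresholds or QCThresholds()
    rep = report if report is not None else QCReport()
    for pair in pairs:
        rep.total_pairs += 1
        fail = _first_failing(pair, t)
        if fail is None:
            rep.kept_pairs += 1
            yield pair
        else:
            rep.removed_by_criterion[fail] += 1


def filter_fastq_pair(
    in1: str | Path,
    in2: str | Path,
    out_prefix: str | Path,
    thresholds: Optional[QCThresholds] = None,
) -> QCReport:
    """File-level QC: filter R1/R2 FASTQ files, write kept pair + report."""
    offset = detect_phred_offset(in1)
    reads1 = read_fastq(in1, offset=offset)
    reads2 = read_fastq(in2, offset=offset)
    pairs = zip_pairs(reads1, reads2)
    report = QCReport(phred_offset=offset)
    kept1: list[SeqRead] = []
    kept2: list[SeqRead] = []
    for r1, r2 in filter_reads(pairs, thresholds, report):
        kept1.append(r1)
        kept2.append(r2)
    prefix = str(out_prefix)
    write_fastq(kept1, prefix + ".clean_1.fastq")
    write_fastq(kept2, prefix + ".clean_2.fastq")
    report.to_json(prefix + ".qc_report.json")
    return report


def zip_pairs(
    reads1: Iterable[SeqRead], reads2: Iterable[SeqRead]
) -> Iterator[tuple[SeqRead, SeqRead]]:
    """Pair two mate streams positionally, checking id agreement up to the
    conventional /1 /2 suffixes."""
    it1, it2 = iter(reads1), iter(reads2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError("unpaired read at end of FASTQ stream")
        if _base_id(r1.read_id) != _base_id(r2.read_id):
            raise ValueError(f"mate id mismatch: {r1.read_id} vs {r2.read_id}")
        yield r1, r2


def _base_id(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id
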