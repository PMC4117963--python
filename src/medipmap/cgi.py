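"""CpG-island detection by the three classical criteria.

An island must be longer than 200 bp with GC content >= 50% and a CpG
observed/expected ratio >= 0.6.  Detection slides a 200-bp window at 1-bp
steps, marks qualifying windows, merges the marked sequence, and then
re-verifies each merged candidate on its full extent, shrinking greedily
from the ends until the criteria hold or the candidate drops to the length
floor.  N positions are excluded from the composition denominators and
windows that are mostly N are disqualified, so assembly gaps do not inflate
the observed/expected ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval

WINDOW = 200


@dataclass
class CpGIsland:
    """A reported island together with the composition statistics that
    certify it: GC fraction and CpG observed/expected computed on its final
    extent."""

    interval: GenomicInterval
    gc_fraction: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.interval.length


class _SeqStats:
    """Prefix-sum composition counters over one chromosome sequence."""

    def __init__(self, seq: str):
        b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_c = b == ord("C")
        is_g = b == ord("G")
        known = is_c | is_g | (b == ord("A")) | (b == ord("T"))
        cpg = np.zeros(len(b), dtype=bool)
        if len(b) > 1:
            cpg[:-1] = is_c[:-1] & is_g[1:]
        self.n = len(b)
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate([z, np.cumsum(is_c)])
        self.cum_g = np.concatenate([z, np.cumsum(is_g)])
        self.cum_known = np.concatenate([z, np.cumsum(known)])
        self.cum_cpg = np.concatenate([z, np.cumsum(cpg)])

    def stats(self, start: int, end: int) -> tuple[float, float, int]:
        """(gc_fraction, obs_exp, effective_length) on [start, end).

        CpG dinucleotides are counted only when fully inside the span;
        denominators exclude N positions.
        """
        c = int(self.cum_c[end] - self.cum_c[start])
        g = int(self.cum_g[end] - self.cum_g[start])
        n_eff = int(self.cum_known[end] - self.cum_known[start])
        cpg = int(self.cum_cpg[end - 1] - self.cum_cpg[start]) if end - start > 1 else 0
        gc = (c + g) / n_eff if n_eff else 0.0
        oe = (cpg * n_eff) / (c * g) if c and g else 0.0
        return gc, oe, n_eff


def island_criteria_ok(gc: float, oe: float, length: int) -> bool:
    return length > WINDOW and gc >= 0.5 and oe >= 0.6


def _qualifying_window_starts(st: _SeqStats) -> np.ndarray:
    """Start positions of all qualifying 200-bp windows (vectorized)."""
    L = st.n
    if L < WINDOW:
        return np.array([], dtype=np.int64)
    idx = np.arange(L - WINDOW + 1)
    c = (st.cum_c[idx + WINDOW] - st.cum_c[idx]).astype(np.float64)
    g = (st.cum_g[idx + WINDOW] - st.cum_g[idx]).astype(np.float64)
    n_eff = (st.cum_known[idx + WINDOW] - st.cum_known[idx]).astype(np.float64)
    cpg = (st.cum_cpg[idx + WINDOW - 1] - st.cum_cpg[idx]).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_eff > 0, (c + g) / n_eff, 0.0)
        oe = np.where((c > 0) & (g > 0), cpg * n_eff / (c * g), 0.0)
    ok = (n_eff >= WINDOW / 2) & (gc >= 0.5) & (oe >= 0.6)
    return idx[ok]


def _trim_candidate(seq: str, st: _SeqStats, start: int, end: int) -> CpGIsland | None:
    """Re-verify a merged candidate on its full extent; shrink greedily from
    the ends until all three criteria hold, else discard.

    The trim step drops the terminal base with the lower composition score
    (G/C worth 2, membership in a CpG worth 1 more; ties drop the left end),
    which monotonically raises GC until the criteria can be met or the
    candidate falls to the 200-bp floor.
    """

    def score(pos: int) -> int:
        base = seq[pos]
        s = 2 if base in "CG" else 0
        if base == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G":
            s += 1
        if base == "G" and pos > 0 and seq[pos - 1] == "C":
            s += 1
        return s

    while end - start > WINDOW:
        gc, oe, n_eff = st.stats(start, end)
        if n_eff > 0 and gc >= 0.5 and oe >= 0.6:
            return CpGIsland(
                interval=GenomicInterval("chr", start, end),
                gc_fraction=gc,
                obs_exp=oe,
            )
        if score(start) <= score(end - 1):
            start += 1
        else:
            end -= 1
    return None


def scan_cgi_sequence(seq: str, chrom: str = "chr") -> list[CpGIsland]:
    """Scan one sequence for CpG islands; see module docstring for the rule."""
    st = _SeqStats(seq)
    starts = _qualifying_window_starts(st)
    if len(starts) == 0:
        return []
    # union of qualifying windows via a difference array
    diff = np.zeros(st.n + 1, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + WINDOW, -1)
    covered = np.cumsum(diff[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
    islands: list[CpGIsland] = []
    for s, e in zip(edges[::2], edges[1::2]):
        isl = _trim_candidate(seq, st, int(s), int(e))
        if isl is not None:
            islands.append(
                CpGIsland(
                    interval=GenomicInterval(
                        chrom, isl.interval.start, isl.interval.end
                    ),
                    gc_fraction=isl.gc_fraction,
                    obs_exp=isl.obs_exp,
                )
            )
    islands.sort(key=lambda i: i.interval.start)
    return islands


def scan_cgi(genome) -> list[CpGIsland]:
    """Scan every chromosome of a :class:`medipmap.io.Genome` for islands,
    sorted by chromosome order then coordinate."""
    out: list[CpGIsland] = []
    for chrom in genome.index.names:
        out.extend(scan_cgi_sequence(genome.sequence(chrom), chrom))
    return out
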