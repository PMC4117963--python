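"""Independent brute-force oracles used to verify the package's interval
algebra, CGI scanner, chi-square test, BH procedure and k-means results.

Everything here is written as plainly as possible (per-base-pair boolean
arrays, exhaustive enumeration, direct textbook formulas) and shares no
code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# per-base-pair boolean arrays


def bp_mask(length: int, spans) -> np.ndarray:
    """Boolean per-bp occupancy for (start, end) spans on one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for s, e in spans:
        mask[s:e] = True
    return mask


def mask_to_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


# ---------------------------------------------------------------------------
# CGI scanning: exhaustive 200-bp window oracle


def _window_ok(seq: str, s: int, w: int = 200) -> bool:
    sub = seq[s : s + w]
    c = sub.count("C")
    g = sub.count("G")
    n_eff = sum(ch in "ACGT" for ch in sub)
    if n_eff < w / 2 or n_eff == 0:
        return False
    cpg = sum(1 for i in range(len(sub) - 1) if sub[i] == "C" and sub[i + 1] == "G")
    gc = (c + g) / n_eff
    oe = cpg * n_eff / (c * g) if c and g else 0.0
    return gc >= 0.5 and oe >= 0.6


def _span_stats(seq: str, s: int, e: int) -> tuple[float, float]:
    sub = seq[s:e]
    c = sub.count("C")
    g = sub.count("G")
    n_eff = sum(ch in "ACGT" for ch in sub)
    cpg = sum(1 for i in range(len(sub) - 1) if sub[i] == "C" and sub[i + 1] == "G")
    gc = (c + g) / n_eff if n_eff else 0.0
    oe = cpg * n_eff / (c * g) if c and g else 0.0
    return gc, oe


def cgi_oracle(seq: str, w: int = 200, spot_check: bool = True) -> list[tuple[int, int]]:
    """Label every base lying in ANY qualifying 200-bp window, merge runs,
    drop runs of length <= 200, then apply the same end-trim rule as the
    scanner (drop the lower-scoring terminal base until the full-extent
    criteria hold).

    Window counts slide incrementally for speed; a random sample of windows
    is re-evaluated from scratch with :func:`_window_ok` as a self-check.
    """
    L = len(seq)
    covered = np.zeros(L, dtype=bool)
    if L >= w:
        c = seq[:w].count("C")
        g = seq[:w].count("G")
        n_eff = sum(ch in "ACGT" for ch in seq[:w])
        cpg = sum(1 for i in range(w - 1) if seq[i] == "C" and seq[i + 1] == "G")

        def ok() -> bool:
            if n_eff < w / 2 or n_eff == 0 or not c or not g:
                return False
            return (c + g) / n_eff >= 0.5 and cpg * n_eff / (c * g) >= 0.6

        rng = np.random.default_rng(0)
        for s in range(0, L - w + 1):
            if s > 0:
                out_ch, in_ch = seq[s - 1], seq[s + w - 1]
                c += (in_ch == "C") - (out_ch == "C")
                g += (in_ch == "G") - (out_ch == "G")
                n_eff += (in_ch in "ACGT") - (out_ch in "ACGT")
                cpg += (seq[s + w - 2] == "C" and in_ch == "G") - (
                    out_ch == "C" and seq[s] == "G"
                )
            q = ok()
            if spot_check and rng.random() < 0.001:
                assert q == _window_ok(seq, s, w), f"oracle self-check at {s}"
            if q:
                covered[s : s + w] = True
    out = []
    for s, e in mask_to_spans(covered):
        span = _trim(seq, s, e, w)
        if span is not None:
            out.append(span)
    return out


def _score(seq: str, pos: int) -> int:
    base = seq[pos]
    sc = 2 if base in "CG" else 0
    if base == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G":
        sc += 1
    if base == "G" and pos > 0 and seq[pos - 1] == "C":
        sc += 1
    return sc


def _trim(seq: str, s: int, e: int, w: int) -> tuple[int, int] | None:
    while e - s > w:
        gc, oe = _span_stats(seq, s, e)
        if gc >= 0.5 and oe >= 0.6:
            return (s, e)
        if _score(seq, s) <= _score(seq, e - 1):
            s += 1
        else:
            e -= 1
    return None


# ---------------------------------------------------------------------------
# statistics


def chi2_2x2(a: int, b: int, na: int, nb: int) -> float:
    """Textbook Pearson chi-square: direct sum of (O-E)^2/E over the four
    cells of [[a, na-a], [b, nb-b]]."""
    obs = [[a, na - a], [b, nb - b]]
    n = na + nb
    col = [a + b, n - a - b]
    rows = [na, nb]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            exp = rows[i] * col[j] / n
            if exp > 0:
                stat += (obs[i][j] - exp) ** 2 / exp
    return stat


def bh_stepup(pvals) -> np.ndarray:
    """BH adjusted p-values by the literal step-up definition:
    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# clustering


def kmeans_exhaustive_inertia(X: np.ndarray, k: int) -> float:
    """Minimum within-cluster sum of squares over ALL assignments of rows
    to k clusters (feasible only for tiny n)."""
    n = X.shape[0]
    best = np.inf
    for assign in product(range(k), repeat=n):
        inertia = 0.0
        for c in range(k):
            rows = X[[i for i in range(n) if assign[i] == c]]
            if len(rows):
                inertia += ((rows - rows.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return float(best)


def pearson_direct(x, y) -> float:
    """Pearson r via the direct covariance / sigma formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
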