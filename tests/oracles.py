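"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive loops and direct definitions; they never import
the implementation internals they are checking.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_scan(
    tags: list[int],
    bin_width: int,
    init_window: int = 200,
    init_fold: float = 3.0,
    body_fold: float = 3.0,
    min_density: float = 10.0,
    min_length: int = 150,
    max_gap: int = 1000,
    closure_frac: float = 0.1,
) -> list[tuple[int, int]]:
    """Naive per-bin transcript scan over one oriented bin array.

    Rules (applied per scan position, 5'->3'):
      closed  -> open at i when the forward window density clears
                 ``min_density`` and is >= ``init_fold`` x the previous
                 window density (or the previous window is empty);
      open    -> split when i is at least two windows past the start and
                 the window density is >= ``body_fold`` x the running body
                 density; otherwise a window density below
                 ``closure_frac`` x body or below ``min_density`` extends
                 a gap which closes the
                 transcript at the last good bin once it exceeds
                 ``max_gap`` bp; a good window resets the gap.
      close   -> trim both ends to the outermost bins carrying at least
                 ``closure_frac`` of the mean per-bin body signal; drop
                 spans shorter than ``min_length``.
    """
    t = [int(x) for x in tags]
    n = len(t)
    w = init_window // bin_width

    def dens(i: int) -> float:
        j = min(i + w, n)
        return sum(t[i:j]) * 1000.0 / ((j - i) * bin_width)

    def prev_dens(i: int) -> float:
        j = max(i - w, 0)
        if j == i:
            return 0.0
        return sum(t[j:i]) * 1000.0 / ((i - j) * bin_width)

    raw: list[tuple[int, int]] = []
    open_ = False
    s = last_good = 0
    i = 0
    while i < n:
        d = dens(i)
        if not open_:
            p = prev_dens(i)
            if d >= min_density and (p == 0.0 or d >= init_fold * p):
                open_ = True
                s = last_good = i
            i += 1
            continue
        body = sum(t[s : last_good + 1]) * 1000.0 / ((last_good + 1 - s) * bin_width)
        if i - s >= 2 * w and body > 0 and d >= body_fold * body:
            raw.append((s, i))
            s = last_good = i
            i += 1
            continue
        if d < closure_frac * body or d < min_density:
            if (i - last_good) * bin_width > max_gap:
                raw.append((s, last_good + 1))
                open_ = False
        else:
            last_good = i
        i += 1
    if open_:
        raw.append((s, last_good + 1))

    out = []
    for s, e in raw:
        total = sum(t[s:e])
        if total <= 0:
            continue
        tau = closure_frac * total / (e - s)
        while s < e and t[s] < tau:
            s += 1
        while e > s and t[e - 1] < tau:
            e -= 1
        if (e - s) * bin_width < min_length:
            continue
        out.append((s, e))
    return out


def brute_force_bh(pvalues) -> np.ndarray:
    """BH adjusted p by the definition: min over j >= rank(i) of m*p(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        out[idx] = min(1.0, min(candidates))
    return out


def conditional_binomial_p(a: int, b: int, n_a: int, n_b: int) -> float:
    """Poisson-limit exact test: A | A+B ~ Binomial(s, n_a/(n_a+n_b))."""
    s = a + b
    if s == 0:
        return 1.0
    frac = n_a / (n_a + n_b)
    lower = sps.binom.cdf(a, s, frac)
    upper = sps.binom.sf(a - 1, s, frac)
    return float(min(1.0, 2.0 * min(lower, upper)))


def intervals_overlap(a: tuple, b: tuple) -> bool:
    """>= 1 bp overlap of half-open (chrom, start, end) intervals."""
    return a[0] == b[0] and a[1] < b[2] and a[2] > b[1]


def brute_force_cooccurrence(sets: dict[str, list[tuple]]) -> dict[tuple[str, str], float]:
    """Min-set overlap percentage by double loop over every pair of sites."""
    out = {}
    for la, sa in sets.items():
        for lb, sb in sets.items():
            if la == lb:
                out[(la, lb)] = 100.0
                continue
            def frac(small, big):
                hit = sum(any(intervals_overlap(x, y) for y in big) for x in small)
                return 100.0 * hit / len(small)
            if len(sa) < len(sb):
                out[(la, lb)] = frac(sa, sb)
            elif len(sb) < len(sa):
                out[(la, lb)] = frac(sb, sa)
            else:
                out[(la, lb)] = max(frac(sa, sb), frac(sb, sa))
    return out


def brute_force_merge(intervals: list[tuple]) -> list[tuple]:
    merged = []
    for iv in sorted(intervals):
        if merged and iv[0] == merged[-1][0] and iv[1] <= merged[-1][2]:
            merged[-1] = (merged[-1][0], merged[-1][1], max(merged[-1][2], iv[2]))
        else:
            merged.append(iv)
    return merged


def brute_force_venn(a: list[tuple], b: list[tuple], c: list[tuple]) -> dict[int, int]:
    """Category sizes over the merged universe of three interval sets."""
    numbering = {
        frozenset("ABC"): 1, frozenset("AB"): 2, frozenset("BC"): 3,
        frozenset("A"): 4, frozenset("AC"): 5, frozenset("B"): 6, frozenset("C"): 7,
    }
    universe = brute_force_merge(list(a) + list(b) + list(c))
    counts: dict[int, int] = {}
    for region in universe:
        present = frozenset(
            label
            for label, s in (("A", a), ("B", b), ("C", c))
            if any(intervals_overlap(region, iv) for iv in s)
        )
        cat = numbering[present]
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def kruskal_h_by_hand(groups: list[list[float]]) -> float:
    """H statistic from first principles with mid-rank ties."""
    pooled = [x for g in groups for x in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    N = len(pooled)
    offset = 0
    H = 0.0
    for g in groups:
        r = sum(ranks[offset : offset + len(g)])
        H += r * r / len(g)
        offset += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    # tie correction
    _, counts = np.unique(np.asarray(pooled), return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    return H / correction


def validate_truth(truth) -> list[str]:
    """Brute-force check of every planted-feature invariant; returns violations."""
    problems = []
    genes = truth.genes
    for e in truth.intergenic_enhancers:
        for g in genes:
            if g.chrom != e.chrom:
                continue
            if g.start < e.hull[1] and g.end > e.hull[0]:
                problems.append(f"{e.id} overlaps gene {g.gene_id}")
            if abs(e.center - g.tts) <= 3000:
                problems.append(f"{e.id} center within 3 kb of TTS of {g.gene_id}")
        gap = e.plus_span[0] - e.minus_span[1]
        if not 0 <= gap <= 1000:
            problems.append(f"{e.id} divergent gap {gap} outside [0, 1000]")
    host = {g.gene_id: g for g in genes}
    for e in truth.intragenic_enhancers:
        g = host[e.host_gene]
        if not (g.start <= e.start and e.end <= g.end):
            problems.append(f"{e.id} not inside host {g.gene_id}")
        if not 150 <= e.end - e.start <= 500:
            problems.append(f"{e.id} length {e.end - e.start} outside [150, 500]")
        if e.strand == g.strand:
            problems.append(f"{e.id} not antisense to host")
        if not any(
            c == e.chrom and s < e.end and x > e.start for c, s, x in truth.h3k4me2
        ):
            problems.append(f"{e.id} lacks an overlapping H3K4me2 interval")
    return problems
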