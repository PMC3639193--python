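"""Independent brute-force reference implementations used only as test oracles.

These deliberately avoid the vectorized/library code paths of the package:
plain Python loops, exact rational arithmetic where it matters.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def reference_call_footprints(start_counts, min_reads=5, assign_window=10,
                              footprint_len=50):
    """Greedy footprint calls by explicit re-scan of a plain Python list.

    Same rules as the production caller — repeatedly scan for the highest
    remaining count (leftmost tie-break), consume the +/- window, emit — but
    implemented without numpy.
    """
    v = list(int(x) for x in start_counts)
    L = len(v)
    out = []
    while True:
        best, best_pos = -1, -1
        for p in range(L):  # explicit scan; leftmost maximum wins
            if v[p] > best:
                best, best_pos = v[p], p
        if best < min_reads:
            break
        lo = max(0, best_pos - assign_window)
        hi = min(L, best_pos + assign_window + 1)
        reads = sum(v[lo:hi])
        for p in range(lo, hi):
            v[p] = 0
        out.append((best_pos, best_pos, min(best_pos + footprint_len, L), reads))
    return out


def hypergeom_upper_tail(k, m, n, N):
    """P(X >= k) for X ~ Hypergeom(N, m, n), by exact rational summation."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(m, n) + 1):
        acc += Fraction(comb(m, i) * comb(N - m, n - i), total)
    return float(acc)


def bh_stepup(p_values):
    """Direct evaluation of the BH step-up definition, input order preserved."""
    M = len(p_values)
    order = sorted(range(M), key=lambda i: p_values[i])
    q = [None] * M
    running = 1.0
    for rank in range(M, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * M / rank)
        q[i] = running
    return q


def find_seed_matches(site: str, sequence: str):
    """All (overlapping) start positions of ``site`` in ``sequence`` by
    naive character-by-character comparison."""
    hits = []
    n, m = len(sequence), len(site)
    for p in range(n - m + 1):
        if all(sequence[p + j] == site[j] for j in range(m)):
            hits.append(p)
    return hits


def merge_intervals_unionfind(intervals, max_gap):
    """Transitive-closure merge of [start, end) intervals by union-find."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )
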