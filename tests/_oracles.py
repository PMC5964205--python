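"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the mapper oracle is a
full sliding-window Hamming scan, block merging is a pairwise overlap closure
via union-find, and fusion frames are verified by explicitly concatenating and
translating the fusion transcript with Biopython.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def brute_force_map(genome: dict[str, str], flank: str, max_mismatch: int):
    """All placements of `flank` (both strands) within max_mismatch.

    Returns a list of (chrom, start, strand, mismatches); a sliding-window
    scan over every position of every chromosome, no seeding.
    """
    hits = []
    q_fwd = np.frombuffer(flank.encode(), dtype=np.uint8)
    q_rev = np.frombuffer(revcomp(flank).encode(), dtype=np.uint8)
    L = len(flank)
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                hits.append((chrom, int(pos), strand, int(mm[pos])))
    return hits


def best_unique_placement(genome, flank, max_mismatch):
    """Mapper contract applied to the brute-force hit list."""
    hits = brute_force_map(genome, flank, max_mismatch)
    if not hits:
        return ("unmapped", None)
    best_mm = min(h[3] for h in hits)
    best = [h for h in hits if h[3] == best_mm]
    if len(best) > 1:
        return ("multimapped", None)
    return ("unique", best[0])


def overlap_closure(intervals):
    """Union-find transitive closure of pairwise interval overlap.

    `intervals` is a list of (chrom, start, end); returns a sorted list of
    frozensets of member indices.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]
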