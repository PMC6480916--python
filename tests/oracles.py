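"""Independent brute-force oracles used to validate the package.

These deliberately re-implement functionality with the simplest possible
algorithms (full DP, all-pairs clustering, exhaustive search) and stay
decoupled from the package internals they check.
"""

from __future__ import annotations

import numpy as np

MATCH = 2
MISMATCH = -4
GAP_OPEN = -4  # charged once per gap
GAP_EXTEND = -2  # per gapped base


def smith_waterman_score(a: str, b: str) -> float:
    """Optimal local alignment score, affine gaps (len-g gap costs 4 + 2g).

    Plain Gotoh three-state DP, row-vectorized over ``b``.
    """
    n, m = len(a), len(b)
    neg = -1e9
    h = np.zeros(m + 1)  # best ending in match/mismatch or anything
    e = np.full(m + 1, neg)  # gap in a (horizontal)
    best = 0.0
    prev_h = np.zeros(m + 1)
    f_col = np.full(m + 1, neg)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    open_cost = -(abs(GAP_OPEN) + abs(GAP_EXTEND))
    ext_cost = -abs(GAP_EXTEND)
    for i in range(1, n + 1):
        ai = ord(a[i - 1])
        sub = np.where(bb == ai, MATCH, MISMATCH).astype(float)
        diag = prev_h[:-1] + sub
        f_col = np.maximum(prev_h + open_cost, f_col + ext_cost)  # gap in b (vertical)
        h_new = np.zeros(m + 1)
        # e (horizontal) has an intra-row dependency: resolve sequentially
        e_val = neg
        for j in range(1, m + 1):
            e_val = max(h_new[j - 1] + open_cost, e_val + ext_cost)
            h_new[j] = max(0.0, diag[j - 1], e_val, f_col[j])
        best = max(best, h_new.max())
        prev_h = h_new
    return best


def single_linkage_clusters(
    points: list[tuple[int, int]], tol: int
) -> list[list[int]]:
    """All-pairs single-linkage clustering: link if both coordinate deltas
    are within ``tol``. Returns clusters as sorted index lists."""
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(points[i][0] - points[j][0]) <= tol
                and abs(points[i][1] - points[j][1]) <= tol
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values())


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_a, start_b) of the longest exact common substring."""
    best = (0, 0, 0)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def cigar_read_interval(cigar: list[tuple[str, int]], reverse: bool) -> tuple[int, int, int]:
    """(read_start, read_end, read_len) in original read coordinates from a
    CIGAR given in SEQ orientation (clips included)."""
    lead = trail = 0
    ops = [op for op, _ in cigar]
    i = 0
    while i < len(cigar) and cigar[i][0] in "SH":
        lead += cigar[i][1]
        i += 1
    j = len(cigar) - 1
    while j >= 0 and cigar[j][0] in "SH":
        trail += cigar[j][1]
        j -= 1
    aligned = sum(n for op, n in cigar if op in "MI=X")
    total = lead + aligned + trail
    if reverse:
        return trail, trail + aligned, total
    return lead, lead + aligned, total
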