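"""Independent brute-force oracles used to check the package's algorithms.

These deliberately avoid the package's own search/fold/overlap code paths:
the off-target oracle scans every window with a direct Hamming count, the
folding oracle enumerates every pseudoknot-free structure, and the overlap
oracle tests interval intersection pairwise.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

TARGET_LEN = 23
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_hits(
    records: Dict[str, str], query: str, max_mm: int
) -> List[Tuple[str, int, str, int]]:
    """All (chrom, 1-based start, strand, mismatches) placements of a 23-mer.

    Vectorized sliding Hamming count per window; N in the genome never
    matches (the query carries no N).  Sorted (mismatches, chrom, start,
    '+' before '-') to match the reporting order contract.
    """
    out = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for chrom, seq in records.items():
            g = np.frombuffer(seq.encode(), dtype=np.uint8)
            n_win = len(g) - TARGET_LEN + 1
            if n_win <= 0:
                continue
            mm = np.zeros(n_win, dtype=np.int16)
            for k in range(TARGET_LEN):
                mm += g[k : k + n_win] != qa[k]
            for pos in np.nonzero(mm <= max_mm)[0]:
                out.append((chrom, int(pos) + 1, strand, int(mm[pos])))
    out.sort(key=lambda h: (h[3], h[0], h[1], 0 if h[2] == "+" else 1))
    return out


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def max_pairs_enumerated(seq: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Maximum base-pair count over exhaustive structure enumeration.

    Plain recursion over all pseudoknot-free pair sets (no memoization, so
    it shares nothing with a dynamic-programming folder); feasible for
    sequences up to ~15 nt.
    """

    def pairable(a: str, b: str) -> bool:
        return (a, b) in _WC or (allow_gu and (a, b) in _GU)

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pairable(seq[i], seq[k]):
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1) if seq else 0


def overlapping_variants(
    region_start: int, region_end: int, spans: List[Tuple[int, int]]
) -> List[int]:
    """Indices of variant spans intersecting [region_start, region_end]."""
    return [
        i
        for i, (lo, hi) in enumerate(spans)
        if hi >= region_start and lo <= region_end
    ]
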