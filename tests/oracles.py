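"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the package's own algorithms: the alignment
oracle enumerates every local alignment path explicitly, and the AUC
oracle counts concordant pairs directly.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN_TOTAL = 12.0  # first gapped residue: open 11 + extend 1
GAP_EXTEND = 1.0


def _global_alignments_max(s: str, e: str) -> float:
    """Max affine-gap global alignment score of s vs e by path enumeration."""

    def rec(i: int, j: int, last: str) -> float:
        if i == len(s) and j == len(e):
            return 0.0
        best = -float("inf")
        if i < len(s) and j < len(e):
            best = max(best, _BLOSUM62[s[i], e[j]] + rec(i + 1, j + 1, "M"))
        if i < len(s):  # gap in e
            cost = GAP_EXTEND if last == "X" else GAP_OPEN_TOTAL
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < len(e):  # gap in s
            cost = GAP_EXTEND if last == "Y" else GAP_OPEN_TOTAL
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


def brute_force_local_score(s: str, e: str) -> float:
    """Optimal local alignment score: max over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(s)):
        for i2 in range(i1 + 1, len(s) + 1):
            for j1 in range(len(e)):
                for j2 in range(j1 + 1, len(e) + 1):
                    best = max(best, _global_alignments_max(s[i1:i2], e[j1:j2]))
    return best


def brute_force_auc(scores, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
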