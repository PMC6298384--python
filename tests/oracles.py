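"""Independent brute-force oracles used only by the tests.

These re-derive alignment scores and clustering memberships from first
principles (pure-Python dynamic programming), deliberately sharing no code
with the package's alignment engines.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

NEG = float("-inf")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _score(a: str, b: str, match: float, mismatch: float) -> float:
    return match if set(IUPAC[a]) & set(IUPAC[b]) else mismatch


def local_score(query: str, target: str, match=2.0, mismatch=-1.0,
                gap_open=-2.0, gap_extend=-1.0) -> float:
    """Smith-Waterman with affine gaps (Gotoh), score only."""
    n, m = len(query), len(target)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consume query)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume target)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            s = _score(query[i - 1], target[j - 1], match, mismatch)
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s,
                          X[i][j], Y[i][j])
            if M[i][j] > best:
                best = M[i][j]
    return best


def global_score(query: str, target: str, match=2.0, mismatch=-1.0,
                 gap_open=-2.0, gap_extend=-1.0) -> float:
    """Needleman-Wunsch with affine gaps (Gotoh), score only."""
    n, m = len(query), len(target)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
            s = _score(query[i - 1], target[j - 1], match, mismatch)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (diag + s) if diag > NEG else NEG
    return max(M[n][m], X[n][m], Y[n][m])


def edit_distance_dp(a: str, b: str) -> int:
    """Wagner-Fischer unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length, gap-free sequences."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def greedy_cluster_bruteforce(
    uniques: Sequence[Tuple[str, List[str]]], threshold: float
) -> List[List[str]]:
    """The greedy rule re-applied with brute-force alignments.

    ``uniques`` are (sequence, member id list) pairs already sorted by
    abundance. Sequences are compared with a full DP identity; for the
    equal-length substitution-only test inputs this is the Hamming
    identity, which admits no co-optimal-path ambiguity.
    """
    centroids: List[str] = []
    members: List[List[str]] = []
    for seq, ids in uniques:
        best, best_idx = -1.0, -1
        for k, c in enumerate(centroids):
            ident = hamming_identity(seq, c) if len(seq) == len(c) else (
                1.0 - edit_distance_dp(seq, c) / max(len(seq), len(c)))
            if ident > best:
                best, best_idx = ident, k
        if best >= threshold:
            members[best_idx].extend(ids)
        else:
            centroids.append(seq)
            members.append(list(ids))
    return members
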