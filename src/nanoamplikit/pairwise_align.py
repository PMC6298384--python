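"""Deterministic pairwise alignment engine.

Two complementary backends sit behind this module:

* scored affine alignment (``Bio.Align.PairwiseAligner``) for primer
  localisation and evaluation, where the scoring scheme matters and
  degenerate IUPAC codes must count as matches against their expansions;
* unit-cost optimal edit alignment (``edlib``) for the high-throughput
  identity computations used by the tandem-repeat scanner and the greedy
  OTU clustering, where only percent identity is needed.

Identity is always ``100 * matches / columns`` with terminal gap columns
excluded, so a pure coordinate shift between two otherwise identical
windows costs (almost) nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_core import IUPAC_EXPANSION

_IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# edlib treats N as a wildcard so normalised reads never mismatch on it.
_N_EQUALITIES = [("N", c) for c in "ACGT"]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine alignment scores. Defaults find a 20-mer primer at 2-3% error."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    degenerate_aware: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("require match > 0 and mismatch/gap scores <= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment: score, spans, operations and identity."""

    score: float
    query_span: Tuple[int, int]
    target_span: Tuple[int, int]
    ops: Tuple[Tuple[str, int], ...]  # ("=", "X", "I", "D") run-length ops
    matches: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _substitution_matrix(scheme: ScoringScheme):
    m = substitution_matrices.Array(_IUPAC_ALPHABET, dims=2)
    for x in _IUPAC_ALPHABET:
        ex = set(IUPAC_EXPANSION[x])
        for y in _IUPAC_ALPHABET:
            if scheme.degenerate_aware:
                hit = bool(ex & set(IUPAC_EXPANSION[y]))
            else:
                hit = x == y and x in "ACGT"
            m[x, y] = scheme.match if hit else scheme.mismatch
    return m


from functools import lru_cache


@lru_cache(maxsize=32)
def _aligner(scheme: ScoringScheme, mode: str, end_gap_free: bool = False):
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _substitution_matrix(scheme)
    al.open_gap_score = scheme.gap_open
    al.extend_gap_score = scheme.gap_extend
    if end_gap_free:
        # biopython >= 1.82 renamed the end-gap attributes
        try:
            al.end_insertion_score = 0.0
            al.end_deletion_score = 0.0
        except AttributeError:  # pragma: no cover
            al.target_end_gap_score = 0.0
            al.query_end_gap_score = 0.0
    return al


def _result_from_alignment(aln, query: str, target: str, score: float) -> AlignmentResult:
    # biopython's Alignment stores (target, query); we call align(target=query_of_ours)
    # below with sequences (target, query) -> use .aligned [(target blocks),(query blocks)]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return AlignmentResult(score, (0, 0), (0, 0), (), 0, 0)
    ops: List[Tuple[str, int]] = []
    matches = 0
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            if dt:
                ops.append(("D", dt))  # gap in query, target bases consumed
            if dq:
                ops.append(("I", dq))  # gap in target, query bases consumed
        tseg, qseg = target[ts:te], query[qs:qe]
        run_op = None
        run_len = 0
        for a, b in zip(tseg, qseg):
            hit = a == b or "N" in (a, b) or bool(
                set(IUPAC_EXPANSION.get(a, a)) & set(IUPAC_EXPANSION.get(b, b))
            )
            op = "=" if hit else "X"
            if op == run_op:
                run_len += 1
            else:
                if run_op:
                    ops.append((run_op, run_len))
                run_op, run_len = op, 1
            if hit:
                matches += 1
        if run_op:
            ops.append((run_op, run_len))
        prev_t, prev_q = te, qe
    columns = sum(n for _, n in ops)
    return AlignmentResult(
        score=score,
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        target_span=(int(tblocks[0][0]), int(tblocks[-1][1])),
        ops=tuple(ops),
        matches=matches,
        columns=columns,
    )


def local_align(query: str, target: str, scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal Smith-Waterman-style local alignment of query against target."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    al = _aligner(scheme, "local")
    res = al.align(target, query)
    try:
        aln = res[0]
    except IndexError:  # nothing scores above zero
        return AlignmentResult(0.0, (0, 0), (0, 0), (), 0, 0)
    return _result_from_alignment(aln, query, target, res.score)


def global_align(
    query: str,
    target: str,
    scheme: Optional[ScoringScheme] = None,
    end_gap_free: bool = False,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment.

    With ``end_gap_free`` terminal gaps are unpenalised and excluded from
    the identity columns (the BLASTn-like evaluation surrogate).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    al = _aligner(scheme, "global", end_gap_free=end_gap_free)
    res = al.align(target, query)
    return _result_from_alignment(res[0], query, target, res.score)


def _trimmed_cigar_identity(cigar: str) -> Tuple[int, int]:
    """(matches, columns) from an extended cigar, terminal indel runs removed."""
    ops = [(int(n), c) for n, c in _CIGAR_RE.findall(cigar)]
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    cols = sum(n for n, _ in ops)
    matches = sum(n for n, c in ops if c == "=")
    return matches, cols


def edit_identity(a: str, b: str) -> float:
    """Identity fraction from a unit-cost optimal global alignment.

    Terminal gap columns are excluded from the identity denominator.
    Symmetric by construction (arguments are ordered canonically).
    """
    if not a or not b:
        return 0.0
    if (len(a), a) > (len(b), b):
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path",
                      additionalEqualities=_N_EQUALITIES)
    matches, cols = _trimmed_cigar_identity(res["cigar"])
    return matches / cols if cols else 0.0


def edit_distance(a: str, b: str) -> int:
    """Plain unit-cost edit distance (fast best-reference preselection)."""
    return int(edlib.align(a, b, mode="NW",
                           additionalEqualities=_N_EQUALITIES)["editDistance"])


def window_identity(a: str, b: str) -> float:
    """Percent identity between two segments (tandem-repeat comparison)."""
    if not a or not b:
        raise ValueError("segments must be non-empty")
    return 100.0 * edit_identity(a, b)
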