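"""Accuracy and recovery metrics (the BLASTn-against-references surrogate).

Each query is assigned its best reference (fast edit-distance preselect),
then scored from the best local alignment against it — the analogue of a
BLAST primary alignment. Percent identity is computed over the aligned
columns, the aligned fraction is the aligned query span over the query
length (substantially below 1 for uncorrected, circularly permuted reads),
and the alignment-length ratio is the query aligned span over the
reference aligned span (below 1 when deletions dominate). Deletions are
tagged as homopolymer deletions when the deleted reference base lies
within a reference run > 4 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pairwise_align import (
    AlignmentResult,
    ScoringScheme,
    edit_distance,
    global_align,
    local_align,
)
from .seq_core import SequenceRecord, homopolymer_runs, reverse_complement

ERROR_KEYS = ("mismatch", "insertion", "deletion", "homopolymer_deletion")

# BLASTn-like scores: long gap bridges cost at least as much as they gain,
# so a circularly permuted read aligns over its largest colinear segment
# (the primary-alignment behaviour this module emulates).
BLAST_LIKE_SCHEME = ScoringScheme(match=2.0, mismatch=-3.0,
                                  gap_open=-5.0, gap_extend=-2.0)


@dataclass
class QueryAccuracy:
    query_id: str
    reference_id: str
    identity_pct: float
    aligned_fraction: float
    alignment_length_ratio: float
    errors: Dict[str, int]


@dataclass
class AccuracyReport:
    per_query: List[QueryAccuracy]

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(q, attr) for q in self.per_query], dtype=float)

    @property
    def mean_identity(self) -> float:
        return float(self._vals("identity_pct").mean())

    @property
    def sd_identity(self) -> float:
        return float(self._vals("identity_pct").std(ddof=1)) if len(self.per_query) > 1 else 0.0

    @property
    def mean_aligned_fraction(self) -> float:
        return float(self._vals("aligned_fraction").mean())

    @property
    def total_errors(self) -> Dict[str, int]:
        tot = dict.fromkeys(ERROR_KEYS, 0)
        for q in self.per_query:
            for k in ERROR_KEYS:
                tot[k] += q.errors[k]
        return tot

    def summary(self) -> dict:
        return {
            "n": len(self.per_query),
            "mean_identity_pct": self.mean_identity,
            "sd_identity_pct": self.sd_identity,
            "mean_aligned_fraction": self.mean_aligned_fraction,
            "errors": self.total_errors,
        }


@dataclass
class RecoveryReport:
    detected: int
    spurious: int
    missed: int
    per_otu: List[Tuple[str, str, float]]  # (consensus id, best ref id, identity pct)


def classify_errors(result: AlignmentResult, ref: str) -> Dict[str, int]:
    """Type every non-match column of a query-vs-reference alignment.

    ``result`` must come from an alignment where the reference was the
    target. Deletions inside reference homopolymer runs > 4 bp count as
    ``homopolymer_deletion``.
    """
    run_mask = np.zeros(len(ref), dtype=bool)
    for a, b in homopolymer_runs(ref, min_len=5):
        run_mask[a:b] = True
    counts = dict.fromkeys(ERROR_KEYS, 0)
    tpos = result.target_span[0]
    for op, n in result.ops:
        if op == "=":
            tpos += n
        elif op == "X":
            counts["mismatch"] += n
            tpos += n
        elif op == "I":  # query bases absent from the reference
            counts["insertion"] += n
        elif op == "D":  # reference bases missing from the query
            for k in range(n):
                if run_mask[tpos + k]:
                    counts["homopolymer_deletion"] += 1
                else:
                    counts["deletion"] += 1
            tpos += n
    return counts


def _best_reference(query: str, refs: Sequence[SequenceRecord]) -> int:
    """Preselect the best reference by unit-cost edit distance (fast)."""
    dists = [edit_distance(query, r.seq) for r in refs]
    return int(np.argmin(dists))


def _best_reference_stranded(query: str, refs: Sequence[SequenceRecord]) -> Tuple[int, str]:
    """Best (reference, orientation) pair by edit distance, both strands."""
    rc = reverse_complement(query)
    best = (None, None, None)
    for ri, r in enumerate(refs):
        for strand, q in (("plus", query), ("minus", rc)):
            d = edit_distance(q, r.seq)
            if best[0] is None or d < best[0]:
                best = (d, ri, strand)
    return best[1], best[2]


def reference_accuracy(
    queries: Sequence[SequenceRecord],
    refs: Sequence[SequenceRecord],
    scheme: Optional[ScoringScheme] = None,
) -> AccuracyReport:
    """Align each query to its best reference; collect accuracy metrics."""
    if not queries or not refs:
        raise ValueError("queries and references must be non-empty")
    out: List[QueryAccuracy] = []
    for q in queries:
        ri, strand = _best_reference_stranded(q.seq, refs)
        ref = refs[ri]
        qseq = q.seq if strand == "plus" else reverse_complement(q.seq)
        res = local_align(qseq, ref.seq, scheme or BLAST_LIKE_SCHEME)
        q_aln = res.query_span[1] - res.query_span[0]
        t_aln = res.target_span[1] - res.target_span[0]
        out.append(QueryAccuracy(
            query_id=q.id,
            reference_id=ref.id,
            identity_pct=res.identity_pct,
            aligned_fraction=q_aln / len(q.seq),
            alignment_length_ratio=q_aln / t_aln if t_aln else 0.0,
            errors=classify_errors(res, ref.seq),
        ))
    return AccuracyReport(per_query=out)


def otu_recovery(
    consensus_set: Sequence[SequenceRecord],
    truth_refs: Sequence[SequenceRecord],
    match_threshold: float = 0.97,
) -> RecoveryReport:
    """Score recovered consensus sequences against the true references.

    detected = references matched by >= 1 consensus at the threshold;
    spurious = consensuses matching nothing, plus duplicate assignments to
    an already-matched reference; missed = references with no consensus.
    """
    assigned: Dict[str, List[Tuple[str, float]]] = {}
    per_otu: List[Tuple[str, str, float]] = []
    spurious = 0
    for cons in consensus_set:
        ri = _best_reference(cons.seq, truth_refs)
        ref = truth_refs[ri]
        res = global_align(cons.seq, ref.seq, BLAST_LIKE_SCHEME, end_gap_free=True)
        ident = res.identity_pct / 100.0
        per_otu.append((cons.id, ref.id, res.identity_pct))
        if ident >= match_threshold:
            assigned.setdefault(ref.id, []).append((cons.id, ident))
        else:
            spurious += 1
    for ref_id, hits in assigned.items():
        spurious += len(hits) - 1  # duplicates beyond the first
    detected = len(assigned)
    missed = len(truth_refs) - detected
    return RecoveryReport(detected=detected, spurious=spurious, missed=missed,
                          per_otu=per_otu)
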