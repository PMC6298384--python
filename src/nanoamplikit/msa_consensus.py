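"""Multiple sequence alignment of within-OTU reads and majority consensus.

The internal aligner builds a backbone (star) alignment: the read whose
6-mer profile is closest on average to all others (the medoid; ties to the
lowest index) serves as the backbone, every other read is aligned to it
with a unit-cost optimal global alignment, and the pairwise alignments are
stacked into one column system — backbone columns interleaved with
insertion columns (left-aligned, padded with gaps). For within-OTU reads
(>= 97% mutually identical) this is as accurate as a progressive profile
alignment at a small fraction of the cost, and it is exactly what majority
consensus needs: reads agreeing on a base always place it in the same
column.

An external MAFFT backend (G-INS-i style, global pairwise guidance) can be
selected when the binary is on PATH; its output is parsed into the same
:class:`MultipleAlignment` type.

Consensus rules (documented choices): per column the most frequent symbol
wins; a column whose strict plurality is the gap is dropped; a base-vs-gap
tie retains the base (the platform's dominant error is deletion, so
gap-favouring ties would compound that bias); base-vs-base ties resolve
lexicographically (A < C < G < T); N never beats a concrete base.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

_GAP = "-"
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows; ungapping row i returns input sequence i."""

    rows: Tuple[str, ...]
    ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(_GAP, "")


def _kmer_profile(seq: str, k: int = 6) -> np.ndarray:
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    v = lut[code]
    if len(v) < k:
        return np.zeros(4 ** k)
    idx = np.zeros(len(v) - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + v[j:j + len(idx)]
    return np.bincount(idx, minlength=4 ** k).astype(np.float64)


def _medoid_index(seqs: Sequence[str], k: int = 6) -> int:
    """Index of the sequence with minimal summed 6-mer distance to the rest."""
    profiles = np.vstack([_kmer_profile(s, k) for s in seqs])
    # pairwise Euclidean distances via the Gram trick
    sq = (profiles ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    return int(np.argmin(np.sqrt(d2).sum(axis=1)))


def _align_to_backbone(seq: str, backbone: str) -> Tuple[List[str], Dict[int, str]]:
    """Per-backbone-position symbols and insertion strings for one read.

    Returns ``(body, inserts)`` where ``body[p]`` is the read symbol aligned
    to backbone position p ('-' if deleted) and ``inserts[p]`` is the string
    inserted before backbone position p (p == len(backbone) for a trailing
    insertion).
    """
    res = edlib.align(seq, backbone, mode="NW", task="path")
    body = [_GAP] * len(backbone)
    inserts: Dict[int, str] = {}
    qi = ti = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in ("=", "X", "M"):
            for _ in range(n):
                body[ti] = seq[qi]
                qi += 1
                ti += 1
        elif op == "I":  # read bases absent from the backbone
            inserts[ti] = inserts.get(ti, "") + seq[qi:qi + n]
            qi += n
        elif op == "D":  # backbone bases absent from the read
            ti += n
    return body, inserts


def progressive_msa(
    seqs: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    backend: str = "internal",
) -> MultipleAlignment:
    """Multiple alignment of >= 2 sequences (deterministic).

    The internal backend stacks unit-cost optimal pairwise alignments
    against the 6-mer medoid backbone; ``backend='mafft'`` shells out to
    MAFFT with global pairwise guidance when the binary is available.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("sequences must be non-empty")
    ids = tuple(ids) if ids is not None else tuple(f"seq{i}" for i in range(len(seqs)))
    if backend == "mafft":
        return _mafft_msa(seqs, ids)
    if backend != "internal":
        raise ValueError(f"unknown msa backend {backend!r}")

    b = _medoid_index(seqs)
    backbone = seqs[b]
    aligned = [_align_to_backbone(s, backbone) for s in seqs]
    n_pos = len(backbone)
    max_ins = [0] * (n_pos + 1)
    for _, inserts in aligned:
        for p, s in inserts.items():
            if len(s) > max_ins[p]:
                max_ins[p] = len(s)

    rows: List[str] = []
    for body, inserts in aligned:
        parts: List[str] = []
        for p in range(n_pos + 1):
            if max_ins[p]:
                ins = inserts.get(p, "")
                parts.append(ins + _GAP * (max_ins[p] - len(ins)))
            if p < n_pos:
                parts.append(body[p])
        rows.append("".join(parts))
    return MultipleAlignment(rows=tuple(rows), ids=ids)


def _mafft_msa(seqs: Sequence[str], ids: Sequence[str]) -> MultipleAlignment:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fasta"
        with open(fin, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{i}\n{s}\n")
        out = subprocess.run(
            ["mafft", "--globalpair", "--maxiterate", "0", "--quiet", str(fin)],
            capture_output=True, text=True, check=True,
        ).stdout
    rows: List[str] = []
    cur: List[str] = []
    order: List[int] = []
    for line in out.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            order.append(int(line[1:].strip()))
        else:
            cur.append(line.strip().upper())
    if cur:
        rows.append("".join(cur))
    restored: List[Optional[str]] = [None] * len(seqs)
    for row, i in zip(rows, order):
        restored[i] = row
    return MultipleAlignment(rows=tuple(restored), ids=tuple(ids))


def majority_consensus(aln: MultipleAlignment) -> str:
    """Column-wise majority call with the documented tie rules."""
    if len(aln.rows) < 2:
        raise ValueError("consensus requires at least 2 rows")
    mat = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    symbols = np.frombuffer(b"ACGTN-", dtype=np.uint8)
    counts = np.zeros((len(symbols), mat.shape[1]), dtype=np.int32)
    for si, s in enumerate(symbols):
        counts[si] = (mat == s).sum(axis=0)
    base_counts = counts[:4]          # A C G T
    n_counts = counts[4]
    gap_counts = counts[5]
    best_base_idx = np.argmax(base_counts, axis=0)  # lexicographic tie-break
    best_base_cnt = base_counts[best_base_idx, np.arange(mat.shape[1])]
    out = []
    bases = b"ACGTN"
    for j in range(mat.shape[1]):
        bb = int(best_base_cnt[j])
        if bb == 0 and n_counts[j] > 0 and gap_counts[j] <= n_counts[j]:
            out.append(bases[4:5])    # all-N column
            continue
        if gap_counts[j] > bb:        # gap strictly most frequent: drop column
            continue
        if bb == 0:
            continue                  # all-gap column
        out.append(bases[best_base_idx[j]:best_base_idx[j] + 1])
    return b"".join(out).decode()
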