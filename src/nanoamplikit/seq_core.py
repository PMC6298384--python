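"""Sequence primitives and FASTA/FASTQ I/O shared by every pipeline stage.

Reads are plain nucleotide strings over ``{A, C, G, T, N}``; primers may
carry the full IUPAC degenerate alphabet (the standard 16S primers 8F and
1387R contain R, M and W). Parsing normalises case, maps U to T and
replaces stray non-IUPAC symbols with N (with a warning) so that every
downstream alignment sees a canonical alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger("nanoamplikit")

# IUPAC nucleotide codes and their expansion into concrete bases.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_CODES = set(IUPAC_EXPANSION)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

# Primer pair used throughout: near full-length 16S rRNA gene.
FORWARD_PRIMER_8F = "AGRGTTTGATCMTGGCTCAG"
REVERSE_PRIMER_1387R = "GGGCGGWGTGTACAAG"


class SequenceError(ValueError):
    """Raised for malformed records or invalid nucleotide input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence moving through the pipeline."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: sequence is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DegeneratePrimer:
    """A primer sequence over the IUPAC alphabet with a role label."""

    label: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - IUPAC_CODES
        if bad or not self.seq:
            raise SequenceError(
                f"primer {self.label!r}: invalid IUPAC characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", self.seq.upper())


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map U->T and replace non-IUPAC symbols with N (warning)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_CODES
    if bad:
        logger.warning(
            "record %s: replacing non-IUPAC characters %s with N",
            record_id, sorted(bad),
        )
        s = "".join(c if c in IUPAC_CODES else "N" for c in s)
    return s


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen = set()
    for idx, rec in enumerate(records):
        if rec.id in seen:
            raise SequenceError(f"duplicate id {rec.id!r} at record index {idx}")
        seen.add(rec.id)


def parse_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Parse a FASTA file into normalised records, preserving order.

    Raises :class:`SequenceError` naming the offending record index for
    empty sequences or duplicate ids.
    """
    records: List[SequenceRecord] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not rec.id:
            raise SequenceError(f"record index {idx}: empty header")
        if not seq:
            raise SequenceError(f"record index {idx} ({rec.id!r}): empty sequence")
        records.append(
            SequenceRecord(rec.id, normalize_sequence(seq, rec.id), rec.description)
        )
    _check_unique_ids(records)
    return records


def parse_fastq(path: Union[str, Path]) -> List[SequenceRecord]:
    """Parse FASTQ, discarding qualities (read-only convenience)."""
    records = [
        SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id), rec.description)
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    _check_unique_ids(records)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], wrap: int = 60
) -> Path:
    """Write records as FASTA with lines wrapped at ``wrap`` columns.

    Round-trips through :func:`parse_fasta` to an identical record list.
    """
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")
    return path


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise SequenceError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def degenerate_match(base: str, code: str) -> bool:
    """True iff concrete ``base`` is in the expansion set of IUPAC ``code``."""
    if base not in "ACGT":
        raise SequenceError(f"base must be one of A/C/G/T, got {base!r}")
    if code not in IUPAC_CODES:
        raise SequenceError(f"invalid IUPAC code {code!r}")
    return base in IUPAC_EXPANSION[code]


def homopolymer_runs(seq: str, min_len: int = 5) -> List[tuple]:
    """Half-open (start, end) spans of homopolymer runs of >= min_len bases."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs
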