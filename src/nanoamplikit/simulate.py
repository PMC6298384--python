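"""Synthetic concatemer-consensus reads with a ground-truth ledger.

The simulator emulates what the upstream concatemer-consensus step hands to
the pipeline, without a sequencer: full-length 16S-like amplicons flanked
by the 8F/1387R primer pair, where each read is

* a consensus over ``nc`` physically linked concatemer copies (nc drawn
  from a truncated geometric on [3, 21]); the residual idiosyncratic error
  rate per base is the majority-vote flip probability
  ``P(Binomial(nc, e0) > nc/2)`` at raw per-base error ``e0`` = 0.10, so
  3-concatemer reads carry ~2.8% error while 6+-concatemer reads are clean
  — the strongly bimodal quality profile characteristic of this data;
* systematically missing one base in homopolymer runs > 4 bp (per-read
  probability ``homopolymer_del_boost``), the platform's signature error
  that survives consensus calling;
* with probability ``p_tandem`` carrying a tandem-repeat insertion (2-3
  adjacent copies of a local segment, log-normal copy length);
* circularly permuted (primers co-located mid-read) and reverse
  complemented with probability 1/2.

Every stochastic choice is recorded in a per-read ground-truth entry;
replaying an entry reproduces the read byte-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chopseq import ChopParams, scan_tandem_repeats
from .pairwise_align import edit_identity
from .seq_core import (
    FORWARD_PRIMER_8F,
    IUPAC_EXPANSION,
    REVERSE_PRIMER_1387R,
    SequenceRecord,
    homopolymer_runs,
    reverse_complement,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class MockSpec:
    """A mock community: species count, divergence, abundances, depth."""

    n_species: int = 10
    amplicon_len: int = 1400
    min_pairwise_divergence: float = 0.05
    abundances: Optional[Tuple[float, ...]] = None  # None = equimolar
    reads_total: int = 1000
    seed: int = 0
    n_homopolymer_runs: int = 4

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.amplicon_len < 200 or self.reads_total < 0:
            raise ValueError("invalid mock specification")
        if self.abundances is not None:
            if len(self.abundances) != self.n_species:
                raise ValueError("abundances length must equal n_species")
            if abs(sum(self.abundances) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")

    @property
    def abundance_vector(self) -> np.ndarray:
        if self.abundances is None:
            return np.full(self.n_species, 1.0 / self.n_species)
        return np.asarray(self.abundances, dtype=float)


@dataclass(frozen=True)
class ErrorModel:
    """Concatemer-consensus residual error model (defaults = study conditions).

    ``raw_error_rate`` is the per-base error of a single concatemer pass;
    the per-read residual rate follows from strict-majority voting over the
    read's concatemer count. ``homopolymer_del_boost`` is the per-read
    probability of one extra deletion within each homopolymer run > 4 bp
    (a systematic, signal-level effect shared across reads).
    """

    raw_error_rate: float = 0.10
    concatemer_geom_p: float = 0.5
    concatemer_min: int = 3
    concatemer_max: int = 21
    sub_frac: float = 0.80
    del_frac: float = 0.15
    ins_frac: float = 0.05
    homopolymer_del_boost: float = 0.95
    p_tandem: float = 0.7
    tandem_median_bp: float = 30.0
    tandem_sigma: float = 0.6
    tandem_heavy_tail_p: float = 0.01
    tandem_max_bp: int = 1500
    chemistry: str = "2d"  # "1d2" adds a long second mode to repeat lengths
    p_revcomp: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.raw_error_rate, self.homopolymer_del_boost, self.p_tandem,
                  self.p_revcomp, self.tandem_heavy_tail_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.sub_frac + self.del_frac + self.ins_frac - 1.0) > 1e-9:
            raise ValueError("error split fractions must sum to 1")
        if self.chemistry not in ("2d", "1d2"):
            raise ValueError("chemistry must be '2d' or '1d2'")

    # --- derived quantities -------------------------------------------------
    def concatemer_probs(self) -> Tuple[np.ndarray, np.ndarray]:
        ncs = np.arange(self.concatemer_min, self.concatemer_max + 1)
        w = (1 - self.concatemer_geom_p) ** (ncs - self.concatemer_min)
        w = w * self.concatemer_geom_p
        return ncs, w / w.sum()

    def per_read_error_rate(self, nc: int) -> float:
        """Majority-vote flip probability per base for nc concatemer copies."""
        e0 = self.raw_error_rate
        return float(sum(
            math.comb(nc, k) * e0 ** k * (1 - e0) ** (nc - k)
            for k in range(nc // 2 + 1, nc + 1)
        ))

    @property
    def expected_error_rate(self) -> float:
        """Mean idiosyncratic per-base error over the concatemer mixture."""
        ncs, w = self.concatemer_probs()
        return float(sum(wi * self.per_read_error_rate(int(n))
                         for n, wi in zip(ncs, w)))

    @property
    def p_sub(self) -> float:
        return self.sub_frac * self.expected_error_rate

    @property
    def p_del(self) -> float:
        return self.del_frac * self.expected_error_rate

    @property
    def p_ins(self) -> float:
        return self.ins_frac * self.expected_error_rate

    def sample_tandem_length(self, rng: np.random.Generator) -> int:
        if rng.random() < self.tandem_heavy_tail_p:
            return int(rng.integers(350, self.tandem_max_bp + 1))
        if self.chemistry == "1d2" and rng.random() < 0.3:
            # second, longer mode seen with the unlinked-strand chemistry
            w = rng.lognormal(math.log(4.0 * self.tandem_median_bp), 0.4)
        else:
            w = rng.lognormal(math.log(self.tandem_median_bp), self.tandem_sigma)
        # observed insert lengths start at 10 bp, the scanner's minimum window
        return max(10, int(round(w)))


@dataclass
class GroundTruthEntry:
    """Per-read provenance: replaying it reproduces the read byte-exactly."""

    read_id: str
    species: int
    concatemers: int
    rotation: int            # breakpoint in post-insertion coordinates
    strand: str              # "plus" | "minus"
    repeat: Optional[Tuple[int, int, int]]  # (start, window, n_copies) or None
    edits: List[Tuple]       # ("sub", pos, base) | ("del", pos) | ("ins", pos, base)

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Ledger for a simulated run."""

    references: List[SequenceRecord]
    entries: List[GroundTruthEntry] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "references": {r.id: r.seq for r in self.references},
            "reads": [e.to_json() for e in self.entries],
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in _BASES else IUPAC_EXPANSION[c][int(rng.integers(len(IUPAC_EXPANSION[c])))]
        for c in primer
    )


def _break_long_runs(seq: List[str], protected: List[Tuple[int, int]]) -> None:
    """Cap homopolymer runs at 4 bp outside protected spans (in place)."""
    n = len(seq)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i > 4 and not any(s <= i < e or s < j <= e for s, e in protected):
            for k in range(i + 4, j):
                seq[k] = _BASES[(_BASES.index(seq[k]) + 1) % 4]
        i = j


def synth_references(
    spec: MockSpec,
    forward_primer: str = FORWARD_PRIMER_8F,
    reverse_primer: str = REVERSE_PRIMER_1387R,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 20,
) -> List[SequenceRecord]:
    """Generate mutually divergent reference amplicons sharing the primer pair.

    All species derive from one random ancestor by substitutions in the
    core (primers untouched), so every reference begins with a sequence
    matching the forward primer under degenerate matching and ends with the
    reverse complement of the reverse primer. References carry exactly
    ``spec.n_homopolymer_runs`` homopolymer runs > 4 bp of length 5-7
    (16S-like composition; runs elsewhere are capped at 4 bp), and contain
    no tandem self-similarity detectable by the chopSeq scanner, so an
    error-free read is exactly reconstructable.
    """
    rng = rng or np.random.default_rng(spec.seed)
    fwd = _instantiate_primer(forward_primer, rng)
    rev_rc = reverse_complement(_instantiate_primer(reverse_primer, rng))
    core_len = spec.amplicon_len - len(fwd) - len(rev_rc)
    if core_len < 100:
        raise ValueError("amplicon_len too short for the primer pair")
    scan_params = ChopParams()

    for _ in range(max_tries):
        core = [_BASES[i] for i in rng.integers(0, 4, core_len)]
        # plant homopolymer runs on a coarse grid, then cap all others
        grid = np.arange(40, core_len - 40, 30)
        pos = rng.choice(grid, size=spec.n_homopolymer_runs, replace=False)
        planted = []
        for p in sorted(int(x) for x in pos):
            b = _BASES[int(rng.integers(4))]
            ln = int(rng.integers(5, 8))
            core[p:p + ln] = [b] * ln
            planted.append((p, p + ln))
        _break_long_runs(core, planted)
        ancestor = fwd + "".join(core) + rev_rc

        refs: List[SequenceRecord] = []
        n_mut = int(round(spec.min_pairwise_divergence * core_len))
        for s in range(spec.n_species):
            mutated = list(core)
            sites = rng.choice(core_len, size=n_mut, replace=False)
            for site in sites:
                old = mutated[site]
                mutated[site] = _BASES[(_BASES.index(old) + 1 + int(rng.integers(3))) % 4]
            _break_long_runs(mutated, planted)
            refs.append(SequenceRecord(f"species_{s:02d}", fwd + "".join(mutated) + rev_rc))

        ok = all(not scan_tandem_repeats(r.seq, scan_params) for r in refs)
        if ok and spec.n_species > 1:
            for i in range(len(refs)):
                for j in range(i + 1, len(refs)):
                    if edit_identity(refs[i].seq, refs[j].seq) >= 1 - spec.min_pairwise_divergence:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            return refs
    raise RuntimeError("could not satisfy the divergence constraint; "
                       "lower min_pairwise_divergence or n_species")


def apply_errors(
    seq: str,
    model: ErrorModel,
    rng: np.random.Generator,
    nc: Optional[int] = None,
) -> Tuple[str, List[Tuple], int]:
    """Sample per-base errors; returns (read, edit list, concatemer count).

    Edits are recorded against reference coordinates: ("sub", pos, base),
    ("del", pos), ("ins", pos, base) with insertions placed after ``pos``.
    """
    if nc is None:
        ncs, w = model.concatemer_probs()
        nc = int(rng.choice(ncs, p=w))
    rate = model.per_read_error_rate(nc)
    p_sub, p_del = model.sub_frac * rate, model.del_frac * rate
    p_ins = model.ins_frac * rate

    hp_dels = set()
    for a, b in homopolymer_runs(seq, min_len=5):
        if rng.random() < model.homopolymer_del_boost:
            hp_dels.add(int(rng.integers(a, b)))

    out: List[str] = []
    edits: List[Tuple] = []
    for i, base in enumerate(seq):
        if i in hp_dels:
            edits.append(("del", i))
            continue
        u = rng.random()
        if u < p_del:
            edits.append(("del", i))
        elif u < p_del + p_sub:
            nb = _BASES[(_BASES.index(base) + 1 + int(rng.integers(3))) % 4] \
                if base in _BASES else _BASES[int(rng.integers(4))]
            out.append(nb)
            edits.append(("sub", i, nb))
        else:
            out.append(base)
        if rng.random() < p_ins:
            nb = _BASES[int(rng.integers(4))]
            out.append(nb)
            edits.append(("ins", i, nb))
    return "".join(out), edits, nc


def replay_edits(ref: str, edits: Sequence[Tuple]) -> str:
    """Reapply an edit list to its reference (ground-truth invariant)."""
    by_pos: Dict[int, List[Tuple]] = {}
    for e in edits:
        by_pos.setdefault(e[1], []).append(e)
    out: List[str] = []
    for i, base in enumerate(ref):
        emitted = base
        for e in by_pos.get(i, ()):  # at most one sub/del plus one ins per pos
            if e[0] == "del":
                emitted = None
            elif e[0] == "sub":
                emitted = e[2]
        if emitted is not None:
            out.append(emitted)
        for e in by_pos.get(i, ()):
            if e[0] == "ins":
                out.append(e[2])
    return "".join(out)


def make_read(
    ref: SequenceRecord,
    model: ErrorModel,
    rng: np.random.Generator,
    read_id: str = "read",
    species: int = 0,
    primer_margin: int = 25,
) -> Tuple[SequenceRecord, GroundTruthEntry]:
    """One simulated read: errors -> tandem insertion -> rotation -> strand.

    The tandem segment and the rotation breakpoint are sampled away from the
    primer spans and from each other, mirroring the typical read in which
    the breakpoint falls in the amplicon body (a breakpoint inside a primer
    or a repeat is unrecoverable by design for any splitter).
    """
    errored, edits, nc = apply_errors(ref.seq, model, rng)
    seq = errored
    repeat = None
    if rng.random() < model.p_tandem:
        w = model.sample_tandem_length(rng)
        w = min(w, len(seq) - 2 * primer_margin - 10)
        n_copies = int(rng.integers(2, 4))
        start = int(rng.integers(primer_margin, len(seq) - primer_margin - w + 1))
        segment = seq[start:start + w]
        seq = seq[:start + w] + segment * (n_copies - 1) + seq[start + w:]
        repeat = (start, w, n_copies)

    # rotation breakpoint outside primers and outside the repeat span
    lo, hi = primer_margin, len(seq) - primer_margin
    valid = list(range(lo, hi))
    if repeat is not None:
        s, w, n = repeat
        valid = [v for v in valid if not (s < v < s + n * w)]
    valid = [0] + valid
    rotation = int(valid[int(rng.integers(len(valid)))])
    rotated = seq[rotation:] + seq[:rotation]

    strand = "minus" if rng.random() < model.p_revcomp else "plus"
    final = reverse_complement(rotated) if strand == "minus" else rotated
    rec = SequenceRecord(read_id, final, f"species={species}")
    entry = GroundTruthEntry(read_id=read_id, species=species, concatemers=nc,
                             rotation=rotation, strand=strand, repeat=repeat,
                             edits=edits)
    return rec, entry


def replay_entry(ref: str, entry: GroundTruthEntry) -> str:
    """Rebuild the emitted read from its ground-truth entry."""
    seq = replay_edits(ref, entry.edits)
    if entry.repeat is not None:
        s, w, n = entry.repeat
        seq = seq[:s + w] + seq[s:s + w] * (n - 1) + seq[s + w:]
    seq = seq[entry.rotation:] + seq[:entry.rotation]
    if entry.strand == "minus":
        seq = reverse_complement(seq)
    return seq


def simulate_run(
    spec: MockSpec, model: Optional[ErrorModel] = None
) -> Tuple[List[SequenceRecord], GroundTruth]:
    """A full simulated sequencing run: reads plus the ground-truth ledger."""
    model = model or ErrorModel()
    rng = np.random.default_rng(spec.seed)
    refs = synth_references(spec, rng=rng)
    truth = GroundTruth(references=refs)
    reads: List[SequenceRecord] = []
    species_draws = rng.choice(spec.n_species, size=spec.reads_total,
                               p=spec.abundance_vector)
    for i, s in enumerate(species_draws):
        rec, entry = make_read(refs[int(s)], model, rng,
                               read_id=f"read_{i:05d}", species=int(s))
        reads.append(rec)
        truth.entries.append(entry)
    return reads, truth


def simulate_per_species(
    spec: MockSpec, reads_per_species: int, model: Optional[ErrorModel] = None
) -> Tuple[List[SequenceRecord], GroundTruth]:
    """Exactly ``reads_per_species`` reads per species (consensus experiments)."""
    model = model or ErrorModel()
    rng = np.random.default_rng(spec.seed)
    refs = synth_references(spec, rng=rng)
    truth = GroundTruth(references=refs)
    reads: List[SequenceRecord] = []
    i = 0
    for s, ref in enumerate(refs):
        for _ in range(reads_per_species):
            rec, entry = make_read(ref, model, rng,
                                   read_id=f"read_{i:05d}", species=s)
            reads.append(rec)
            truth.entries.append(entry)
            i += 1
    return reads, truth
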