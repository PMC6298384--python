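"""Reproducible pipeline experiments shared by the tests and the
acceptance script: mock-community OTU recovery and the
consensus-accuracy-versus-reads-used measurement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .chopseq import ChopParams, run_chopseq
from .evaluate import otu_recovery, reference_accuracy
from .nanoclust import parse_partition_limits, run_nanoclust
from .simulate import ErrorModel, MockSpec, simulate_per_species, simulate_run


@dataclass
class MockRunResult:
    n_otus: int
    detected: int
    spurious: int
    missed: int
    consensus_mean_identity: float


def run_mock_community(
    seed: int,
    n_species: int = 10,
    reads_total: int = 1000,
    partitions: str = "0,450,451,900,901,1300",
    threshold: float = 0.97,
    model: Optional[ErrorModel] = None,
) -> MockRunResult:
    """Simulate an equimolar mock, run chopSeq + nanoClust, score recovery."""
    spec = MockSpec(n_species=n_species, reads_total=reads_total, seed=seed)
    reads, truth = simulate_run(spec, model)
    corrected, _ = run_chopseq(reads, ChopParams())
    table, bins, _ = run_nanoclust(
        corrected, parse_partition_limits(partitions), threshold=threshold)
    consensus = [b.consensus for b in bins if b.consensus is not None]
    if consensus:
        recovery = otu_recovery(consensus, truth.references, threshold)
        acc = reference_accuracy(consensus, truth.references)
        mean_id = acc.mean_identity
        det, spur, miss = recovery.detected, recovery.spurious, recovery.missed
    else:
        det = spur = 0
        miss = n_species
        mean_id = 0.0
    return MockRunResult(n_otus=len(table.rows), detected=det, spurious=spur,
                         missed=miss, consensus_mean_identity=mean_id)


def consensus_accuracy_experiment(
    seed: int,
    n_otus: int = 20,
    reads_per_otu: int = 10,
    model: Optional[ErrorModel] = None,
    overgenerate: int = 6,
) -> float:
    """Mean within-OTU consensus identity (%) over ``n_otus`` simulated OTUs.

    Per OTU: simulate reads from one reference, correct them with chopSeq,
    call a majority consensus from the first ``reads_per_otu`` corrected
    reads, and measure identity to the true reference. A few extra reads
    are generated per OTU to absorb chopSeq discards.
    """
    from .nanoclust import OTUBin, build_otu_consensus

    spec = MockSpec(n_species=n_otus, reads_total=0, seed=seed)
    reads, truth = simulate_per_species(spec, reads_per_otu + overgenerate, model)
    corrected, _ = run_chopseq(reads, ChopParams())
    species_of = {e.read_id: e.species for e in truth.entries}
    by_species: Dict[int, List] = {}
    for rec in corrected:
        by_species.setdefault(species_of[rec.id], []).append(rec)
    consensus = []
    refs_used = []
    for s, recs in sorted(by_species.items()):
        recs = recs[:reads_per_otu]
        if len(recs) < 2:
            continue
        mean_len = sum(len(r) for r in recs) / len(recs)
        gated = [r for r in recs if abs(len(r) - mean_len) <= 0.10 * mean_len]
        b = OTUBin(otu_id=f"otu_{s:03d}", members=recs, mean_len=mean_len,
                   gated=gated if len(gated) >= 2 else recs)
        consensus.append(build_otu_consensus(b, max_reads=reads_per_otu))
        refs_used.append(truth.references[s])
    per_id = []
    for cons, ref in zip(consensus, refs_used):
        acc = reference_accuracy([cons], [ref])
        per_id.append(acc.mean_identity)
    return float(np.mean(per_id))
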