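import numpy as np
import pytest

from nanoamplikit import ChopParams, ErrorModel, MockSpec, run_chopseq, simulate_run

# Error-free study conditions for round-trip checks: repeats are planted
# within the scanner's 10-350 bp window range (the rare >350 bp heavy-tail
# inserts are irrecoverable by construction and are discarded by size
# selection, as in the real workflow).
ERROR_FREE = ErrorModel(raw_error_rate=0.0, homopolymer_del_boost=0.0,
                        tandem_heavy_tail_p=0.0)


@pytest.fixture(scope="session")
def small_run():
    """One small simulated mock run shared by read-level tests."""
    spec = MockSpec(n_species=5, reads_total=200, seed=20240917)
    reads, truth = simulate_run(spec)
    return reads, truth


@pytest.fixture(scope="session")
def small_corrected(small_run):
    reads, truth = small_run
    corrected, outcomes = run_chopseq(reads, ChopParams())
    return corrected, outcomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
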