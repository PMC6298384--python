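import numpy as np
import pytest

from nanoamplikit import (
    ChopParams,
    SequenceRecord,
    TandemRepeat,
    collapse_repeats,
    locate_primers,
    reverse_complement,
    run_chopseq,
    scan_tandem_repeats,
    split_and_reorient,
    threshold_for_window,
)
from nanoamplikit.seq_core import FORWARD_PRIMER_8F, REVERSE_PRIMER_1387R
from nanoamplikit.simulate import MockSpec, synth_references
from .conftest import ERROR_FREE

F = "AGAGTTTGATCATGGCTCAG"          # concrete instance of the forward primer
R_RC = reverse_complement("GGGCGGAGTGTACAAG")  # rc of a concrete reverse primer


def make_amplicon(rng, core_len=1360):
    core = "".join(rng.choice(list("ACGT"), core_len))
    return F + core + R_RC


class TestLocatePrimers:
    def test_already_oriented_read(self, rng):
        amp = make_amplicon(rng)
        rep = locate_primers(SequenceRecord("r", amp), ChopParams())
        assert rep.chosen_strand == "plus"
        assert rep.rotation_point == 0
        assert rep.found_forward and rep.found_reverse

    def test_reverse_complemented_read(self, rng):
        amp = make_amplicon(rng)
        rep = locate_primers(SequenceRecord("r", reverse_complement(amp)), ChopParams())
        assert rep.chosen_strand == "minus"
        assert rep.rotation_point == 0

    def test_rotation_point_equals_planted_breakpoint(self, rng):
        amp = make_amplicon(rng)
        for r in (137, 700, 1250):
            rotated = amp[r:] + amp[:r]
            rep = locate_primers(SequenceRecord("r", rotated), ChopParams())
            assert rep.rotation_point == len(amp) - r

    def test_primerless_read_reports_flags_not_errors(self, rng):
        junk = "".join(rng.choice(list("ACGT"), 500))
        rep = locate_primers(SequenceRecord("r", junk), ChopParams())
        assert not (rep.found_forward and rep.found_reverse)


class TestSplitAndReorient:
    def test_already_oriented_gives_whole_read(self, rng):
        amp = make_amplicon(rng)
        rec = SequenceRecord("r", amp)
        fsplit, rsplit, trimmed = split_and_reorient(rec, locate_primers(rec, ChopParams()))
        assert (fsplit, rsplit, trimmed) == (amp, "", 0)

    @pytest.mark.parametrize("r", [60, 444, 1200])
    def test_rotated_read_reconstructs_exactly(self, rng, r):
        amp = make_amplicon(rng)
        rec = SequenceRecord("r", amp[r:] + amp[:r])
        fsplit, rsplit, _ = split_and_reorient(rec, locate_primers(rec, ChopParams()))
        assert fsplit + rsplit == amp

    def test_overhang_after_reverse_primer_is_trimmed(self, rng):
        amp = make_amplicon(rng)
        r = 400
        rotated_with_junk = amp[r:] + "TTTTT" + amp[:r]  # junk follows the amplicon end
        rec = SequenceRecord("r", rotated_with_junk)
        fsplit, rsplit, trimmed = split_and_reorient(rec, locate_primers(rec, ChopParams()))
        assert trimmed == 5
        assert fsplit + rsplit == amp

    def test_missing_primer_is_an_error(self, rng):
        junk = "".join(rng.choice(list("ACGT"), 500))
        rec = SequenceRecord("r", junk)
        with pytest.raises(ValueError):
            split_and_reorient(rec, locate_primers(rec, ChopParams()))


class TestThresholdSchedule:
    PARAMS = ChopParams(tr_threshold_at_min=90.0, tr_threshold_at_max=70.0)

    @pytest.mark.parametrize("window,expected", [(10, 90.0), (350, 70.0), (180, 80.0)])
    def test_linear_interpolation(self, window, expected):
        assert threshold_for_window(window, self.PARAMS) == pytest.approx(expected)

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            threshold_for_window(5, self.PARAMS)


class TestTandemScan:
    def test_exact_triplication(self):
        params = ChopParams(tr_min_window=4, tr_max_window=6)
        reps = scan_tandem_repeats("ACGTACGTACGT", params)
        assert len(reps) == 1
        assert (reps[0].window, reps[0].n_copies, reps[0].start) == (4, 3, 0)

    def test_random_sequences_yield_no_false_positives(self):
        rng = np.random.default_rng(20240917)
        params = ChopParams()
        hits = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 500))
            hits += len(scan_tandem_repeats(seq, params))
        assert hits == 0

    def test_planted_repeat_recovered_at_locus(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 1200))
        seq = ref[:600] + ref[560:600] * 2 + ref[600:]  # three adjacent copies
        reps = scan_tandem_repeats(seq, ChopParams())
        assert any(r.window == 40 and r.n_copies >= 3 and abs(r.start - 560) <= 40
                   for r in reps)

    def test_seeded_scan_matches_exhaustive_on_planted_case(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 400))
        seq = ref[:200] + ref[170:200] * 2 + ref[200:]
        params = ChopParams()
        fast = scan_tandem_repeats(seq, params)
        slow = scan_tandem_repeats(seq, params, exhaustive=True)
        assert [(r.start, r.window, r.n_copies) for r in fast] == \
               [(r.start, r.window, r.n_copies) for r in slow]


class TestCollapseRepeats:
    def test_triplication_collapses_to_single_copy(self):
        rep = TandemRepeat(start=0, window=4, n_copies=3, identity_pct=100.0)
        assert collapse_repeats("ACGTACGTACGT", [rep]) == ("ACGT", 8)

    def test_no_repeats_is_identity(self):
        assert collapse_repeats("ACGT", []) == ("ACGT", 0)

    def test_planted_duplication_restores_original(self, rng):
        amp = make_amplicon(rng)
        seq = amp[:640] + amp[600:640] + amp[640:]  # one extra 40 bp copy
        reps = scan_tandem_repeats(seq, ChopParams())
        out, removed = collapse_repeats(seq, reps)
        assert out == amp
        assert removed == 40

    def test_overlapping_repeats_rejected(self):
        reps = [TandemRepeat(0, 4, 3, 100.0), TandemRepeat(6, 4, 2, 100.0)]
        with pytest.raises(ValueError):
            collapse_repeats("ACGTACGTACGTACGT", reps)

    def test_mass_conservation(self, rng):
        amp = make_amplicon(rng)
        seq = amp[:500] + amp[460:500] * 2 + amp[500:]
        reps = scan_tandem_repeats(seq, ChopParams())
        out, removed = collapse_repeats(seq, reps)
        assert len(out) == len(seq) - removed


class TestRunChopseq:
    def test_error_free_simulated_reads_reconstruct_exactly(self, rng):
        from nanoamplikit.simulate import make_read
        spec = MockSpec(n_species=3, reads_total=0, seed=5)
        refs = synth_references(spec, rng=np.random.default_rng(5))
        reads, src = [], {}
        for i in range(30):
            ref = refs[i % 3]
            rec, _ = make_read(ref, ERROR_FREE, rng, read_id=f"r{i}")
            reads.append(rec)
            src[rec.id] = ref.seq
        corrected, outcomes = run_chopseq(reads)
        assert len(corrected) == 30
        assert all(c.seq == src[c.id] for c in corrected)

    def test_short_merged_read_discarded_by_length(self, rng):
        amp = F + "".join(rng.choice(list("ACGT"), 1160)) + R_RC  # 1196 bp
        corrected, outcomes = run_chopseq([SequenceRecord("r", amp)])
        assert corrected == []
        assert outcomes[0].status == "discarded_length"

    def test_idempotent_on_corrected_output(self, rng):
        amp = make_amplicon(rng)
        reads = [SequenceRecord("r", amp[300:] + amp[:300])]
        once, _ = run_chopseq(reads)
        twice, _ = run_chopseq(once)
        assert [r.seq for r in once] == [r.seq for r in twice]

    def test_empty_input_gives_empty_output(self):
        assert run_chopseq([]) == ([], [])


def test_noisy_reads_align_nearly_fully_after_correction(small_corrected):
    """Directional check: after correction, >= 95% of noisy reads align to
    their reference over >= 98% of their length (uncorrected reads align
    over far less because of rotation and repeat inserts)."""
    from nanoamplikit import reference_accuracy
    corrected, _, truth = small_corrected
    acc = reference_accuracy(corrected[:100], truth.references)
    frac_ok = sum(1 for q in acc.per_query if q.aligned_fraction >= 0.98) / len(acc.per_query)
    assert frac_ok >= 0.95
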