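import numpy as np
import pytest

from nanoamplikit import (
    OTUBin,
    Partition,
    SequenceRecord,
    UniqueSequence,
    build_otu_consensus,
    dereplicate,
    flag_chimeras,
    greedy_cluster,
    parse_partition_limits,
    partition_reads,
    pick_best_partition,
    recruit_full_length,
    run_nanoclust,
)
from nanoamplikit.nanoclust import ClusteringResult
from .oracles import greedy_cluster_bruteforce


class TestPartitionLimits:
    def test_default_three_partition_scheme(self):
        scheme = parse_partition_limits("0,450,451,900,901,1300")
        assert scheme.limits == ((0, 450), (451, 900), (901, 1300))
        read = "A" * 1300
        lengths = [len(read[a:b]) for a, b in scheme.slices()]
        assert lengths == [450, 450, 400]

    def test_single_partition_is_whole_read(self):
        scheme = parse_partition_limits("0,1300")
        assert scheme.slices() == [(0, 1300)]

    @pytest.mark.parametrize("raw", ["0,450,400,900", "0,450,451", "abc", ""])
    def test_malformed_limits_rejected(self, raw):
        with pytest.raises(ValueError):
            parse_partition_limits(raw)


class TestPartitionReads:
    def test_default_scheme_slice_lengths(self):
        scheme = parse_partition_limits("0,450,451,900,901,1300")
        reads = [SequenceRecord("a", "A" * 1300)]
        parts = partition_reads(reads, scheme)
        assert [len(p.records[0].seq) for p in parts] == [450, 450, 400]

    def test_long_read_third_slice_capped_at_pair_end(self):
        scheme = parse_partition_limits("0,450,451,900,901,1300")
        parts = partition_reads([SequenceRecord("a", "A" * 1450)], scheme)
        # pair end is 1300: trailing 150 bp are unused
        assert len(parts[2].records[0].seq) == 400

    def test_short_read_contributes_available_suffix(self):
        scheme = parse_partition_limits("0,450,451,900,901,1300")
        parts = partition_reads([SequenceRecord("a", "A" * 1000)], scheme)
        assert len(parts[1].records[0].seq) == 450
        assert len(parts[2].records[0].seq) == 100

    def test_empty_input(self):
        scheme = parse_partition_limits("0,450")
        assert all(not p.records for p in partition_reads([], scheme))


class TestDereplicate:
    def test_grouping_and_abundance_order(self):
        part = Partition(0, [SequenceRecord("r1", "ACGT"),
                             SequenceRecord("r2", "ACGT"),
                             SequenceRecord("r3", "ACGA")])
        uniq = dereplicate(part)
        assert [(u.seq, u.abundance) for u in uniq] == [("ACGT", 2), ("ACGA", 1)]

    def test_all_distinct_preserves_input_order(self):
        part = Partition(0, [SequenceRecord(f"r{i}", s)
                             for i, s in enumerate(["TT", "GG", "AA"])])
        assert [u.seq for u in dereplicate(part)] == ["TT", "GG", "AA"]

    def test_matches_pairwise_comparison_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
        part = Partition(0, [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)])
        uniq = dereplicate(part)
        # brute-force: group indices by pairwise string equality
        groups = {}
        for i, s in enumerate(seqs):
            groups.setdefault(s, []).append(f"r{i}")
        assert {u.seq: u.member_ids for u in uniq} == groups
        assert sum(u.abundance for u in uniq) == 20


class TestChimeraFlagging:
    @staticmethod
    def _mock_parents(rng):
        a = "".join(rng.choice(list("ACGT"), 400))
        b = "".join(rng.choice(list("ACGT"), 400))
        return a, b

    def test_constructed_two_parent_chimera_flagged(self, rng):
        a, b = self._mock_parents(rng)
        chimera = a[:200] + b[200:]
        uniques = [UniqueSequence(a, [f"a{i}" for i in range(10)]),
                   UniqueSequence(b, [f"b{i}" for i in range(10)]),
                   UniqueSequence(chimera, ["c0"])]
        kept, removed = flag_chimeras(uniques)
        assert [u.seq for u in removed] == [chimera]

    def test_sequence_identical_to_parent_never_flagged(self, rng):
        a, b = self._mock_parents(rng)
        uniques = [UniqueSequence(a, [f"a{i}" for i in range(10)]),
                   UniqueSequence(b, [f"b{i}" for i in range(10)]),
                   UniqueSequence(a, ["c0"])]
        kept, removed = flag_chimeras(uniques)
        assert removed == []

    def test_no_sufficiently_abundant_parents_no_flagging(self, rng):
        a, b = self._mock_parents(rng)
        chimera = a[:200] + b[200:]
        uniques = [UniqueSequence(a, ["a0"]), UniqueSequence(b, ["b0"]),
                   UniqueSequence(chimera, ["c0"])]
        kept, removed = flag_chimeras(uniques)
        assert removed == []


class TestGreedyCluster:
    def test_two_divergent_groups_give_two_clusters(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for i in rng.choice(100, size=10, replace=False):  # 90% identity
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        uniques = [UniqueSequence(a, ["a0", "a1", "a2"]),
                   UniqueSequence(b, ["b0", "b1"])]
        res = greedy_cluster(uniques)
        assert len(res.clusters) == 2
        assert res.n_otus_nonsingleton == 2

    def test_threshold_one_reproduces_dereplication(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(12)]
        uniques = [UniqueSequence(s, [f"r{i}"]) for i, s in enumerate(seqs)]
        res = greedy_cluster(uniques, threshold=1.0)
        assert len(res.clusters) == len(set(seqs))

    def test_membership_matches_bruteforce_oracle(self, rng):
        """100 trials of substitution-derived uniques vs the brute-force rule.

        Substitutions are planted away from the sequence ends so that every
        optimal alignment of any pair is the substitution-only diagonal and
        both routes compute one well-defined identity (near the ends, a
        substitution admits a co-optimal terminal indel pair and percent
        identity becomes path-dependent; terminal-gap handling is covered
        by its own unit tests).
        """
        for _ in range(100):
            n_base = int(rng.integers(2, 4))
            bases = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(n_base)]
            uniques = []
            for i in range(int(rng.integers(4, 11))):
                seq = list(bases[int(rng.integers(n_base))])
                sites = 5 + rng.choice(50, size=int(rng.integers(0, 3)), replace=False)
                for s in sites:
                    seq[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[s]]
                uniques.append(UniqueSequence("".join(seq), [f"r{i}"]))
            got = [sorted(m) for _, m in greedy_cluster(uniques).clusters]
            want = [sorted(m) for m in greedy_cluster_bruteforce(
                [(u.seq, u.member_ids) for u in uniques], 0.97)]
            assert got == want


class TestPickBestPartition:
    @staticmethod
    def _result(idx, n_nonsingleton, reads_each=10):
        clusters = [(UniqueSequence("A" * 20, [f"p{idx}c{i}m0"]),
                     [f"p{idx}c{i}m{j}" for j in range(reads_each)])
                    for i in range(n_nonsingleton)]
        return ClusteringResult(partition_index=idx, clusters=clusters)

    def test_max_nonsingleton_count_wins(self):
        results = [self._result(0, 3), self._result(1, 5), self._result(2, 4)]
        assert pick_best_partition(results).partition_index == 1

    def test_tie_broken_by_reads_retained(self):
        r0 = self._result(0, 5, reads_each=8)
        r1 = self._result(1, 5, reads_each=10)
        assert pick_best_partition([r0, r1]).partition_index == 1

    def test_single_result_returned_as_is(self):
        r = self._result(0, 2)
        assert pick_best_partition([r]) is r


class TestRecruitAndConsensus:
    def test_uniform_length_bin_gates_everything(self, rng):
        reads = [SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 1400)))
                 for i in range(10)]
        best = ClusteringResult(0, [(UniqueSequence("A", ["r0"]),
                                     [r.id for r in reads])])
        bins = recruit_full_length(best, reads)
        assert len(bins[0].gated) == 10

    def test_length_gate_excludes_outlier(self, rng):
        reads = [SequenceRecord(f"r{i}", "A" * 1400) for i in range(9)]
        reads.append(SequenceRecord("r9", "A" * 1200))
        best = ClusteringResult(0, [(UniqueSequence("A", ["r0"]),
                                     [r.id for r in reads])])
        bins = recruit_full_length(best, reads)
        # mean 1380; 1200 < 0.9 * 1380 = 1242 -> excluded
        assert bins[0].mean_len == pytest.approx(1380.0)
        assert [r.id for r in bins[0].gated] == [f"r{i}" for i in range(9)]

    def test_unresolvable_member_id_is_hard_error(self):
        best = ClusteringResult(0, [(UniqueSequence("A", ["rX"]), ["rX", "rY"])])
        with pytest.raises(KeyError):
            recruit_full_length(best, [SequenceRecord("rX", "AAAA")])

    def test_consensus_of_identical_reads_is_that_read(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        reads = [SequenceRecord(f"r{i}", seq) for i in range(50)]
        b = OTUBin("otu_001", reads, 300.0, reads)
        cons = build_otu_consensus(b, max_reads=50)
        assert cons.seq == seq
        assert b.n_reads_used == 50

    def test_consensus_requires_two_reads(self):
        b = OTUBin("otu_001", [SequenceRecord("r0", "ACGT")], 4.0,
                   [SequenceRecord("r0", "ACGT")])
        with pytest.raises(ValueError):
            build_otu_consensus(b)


class TestRunNanoclust:
    def test_small_mock_recovers_all_species(self, small_corrected):
        corrected, _, truth = small_corrected
        table, bins, best = run_nanoclust(corrected)
        assert len(table.rows) == 5
        # every read id appears exactly once in the OTU membership
        ids = [rec.id for b in bins for rec in b.members]
        assert len(ids) == len(set(ids))
        assert table.total_reads <= len(corrected)
        assert all(count >= 2 for _, count, _ in table.rows)

    def test_empty_input_gives_empty_table(self):
        table, bins, best = run_nanoclust([])
        assert table.rows == [] and bins == []
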