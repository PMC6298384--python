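# nanoamplikit

De novo error correction and OTU clustering for concatemer-consensus
nanopore amplicon reads — full-length 16S rRNA gene profiling of mixed
microbial communities without a reference database.

## The problem

Rolling-circle concatemer sequencing turns a single 16S amplicon into a
long nanopore read carrying several linked copies; majority-voting those
copies yields a *concatemer-consensus read* at 97–98% accuracy. Those
reads cannot be used directly: they are circular permutations of the
amplicon (both primers sit co-located mid-read, on either strand), 60–75%
of them contain spurious tandem-repeat insertions, and their residual
2–3% error — dominated by deletions in homopolymer runs > 4 bp — makes
direct 97% OTU clustering collapse into singletons.

`nanoamplikit` implements the two algorithms that fix this, plus a
simulator and evaluation tools so the whole pipeline runs and is tested
with no sequencer and no downloads:

* **chopSeq** — locates the degenerate primers (8F
  `AGRGTTTGATCMTGGCTCAG`, 1387R `GGGCGGWGTGTACAAG`) in all four
  orientation hypotheses, re-orients the read at the highest mean primer
  score, removes the overhang, excises tandem repeats found by comparing
  co-occurring 10–350 bp windows under a linearly diminishing similarity
  threshold, merges the splits and keeps reads of 1300–1450 bp.
* **nanoClust** — slices corrected reads into fixed partitions (default
  positions 1–450 / 451–900 / 901–1300), dereplicates, removes two-parent
  chimeras and greedily clusters each partition at 97% identity, keeps
  the partition with the most non-singleton OTUs, recruits each OTU's
  full-length reads, gates them to ±10% of the bin mean length, and calls
  a majority consensus from the first 50 gated reads. Output: an OTU
  table (singletons discarded) and one consensus sequence per OTU at
  ~99.5%+ accuracy.
* **simulator** — emulates concatemer-consensus output: per-read error
  drawn as the binomial majority-vote residue over the read's concatemer
  count (3–21), systematic homopolymer deletions, tandem-repeat
  insertions, circular permutation and strand flips, with a byte-exact
  ground-truth ledger.
* **evaluation** — best-reference identity, aligned fraction,
  alignment-length ratio, typed error profiles and OTU recovery counts.

## Worked example

```bash
nanoamplikit simulate --species 10 --reads 1000 --seed 42 -o sim/
nanoamplikit chopseq  -i sim/reads.fasta -o corrected.fasta --outcomes outcomes.tsv
nanoamplikit nanoclust -i corrected.fasta -o otus/ -s 0,450,451,900,901,1300
nanoamplikit evaluate --queries otus/consensus.fasta --refs sim/refs.fasta -o report.tsv
```

prints (seed 42, this package):

```
1000 reads for 10 species -> sim
992/1000 reads corrected -> corrected.fasta
10 OTUs (796 reads) from partition 0 -> otus
mean identity 99.76% (aligned fraction 1.000) -> report.tsv
```

Reading: 8 of 1000 simulated reads carried artifacts beyond repair (e.g.
tandem inserts longer than the 350 bp scan ceiling) and were discarded by
size selection; the three partitions each recovered 10 non-singleton OTUs
(ties resolve toward the partition retaining the most reads, here
partition 0 with 796 of 992); each OTU's 50-read majority consensus
matches its true reference at 99.76% mean identity, the residue being
single-base deletions in homopolymer runs — the one error class that
survives majority voting.

The same pipeline is available as library calls (`simulate_run`,
`run_chopseq`, `run_nanoclust`, `reference_accuracy`, `otu_recovery`) —
see `docs/methods.md` for the models, parameter defaults and their
rationale.

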