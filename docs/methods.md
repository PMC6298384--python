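# Methods

`nanoamplikit` reconstructs accurate full-length 16S rRNA gene sequences
from concatemer-consensus nanopore amplicon reads, entirely de novo. This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data generator does and does not emulate.

## The input and its three artifacts

The pipeline's input unit is a *concatemer-consensus read*: one sequence
obtained by aligning the physically linked tandem copies of a single
amplicon within one long nanopore read (produced upstream by rolling-circle
amplification of self-ligated amplicons) and calling their consensus.
Three artifacts dominate such reads:

1. **Circular permutation.** Fragmentation of the rolling-circle product is
   sequence-agnostic, so the consensus read is a rotated version of the
   amplicon: the forward and reverse primers sit co-located somewhere
   mid-read, on either strand, instead of at the ends.
2. **Tandem-repeat insertions.** The concatemer-consensus step occasionally
   emits 2–3 adjacent near-identical copies of a local segment (typically
   tens of bp, rarely > 1 kb). Roughly 60–75% of reads carry one.
3. **Residual error, 2–3%, deletion-biased.** Majority voting over a
   read's concatemer copies leaves residual errors whose rate depends
   steeply on the copy number, plus systematic single-base deletions in
   homopolymer runs longer than 4 bp that survive any amount of voting
   because the signal itself is ambiguous there.

## chopSeq: orientation correction and repeat removal

Both primers are located in the read by scored local alignment (default
scheme +2/−1, gap −2/−1; degenerate IUPAC codes in the primer count as
matches against their expansion). Two strand hypotheses are scored — the
read as given versus its reverse complement — each by the mean of its two
primer-hit scores; a hit is accepted when it reaches 60% of the maximal
attainable score, and a hypothesis missing a hit scores −∞. The read is
re-oriented to the winning strand and chopped at the forward-primer start;
any overhang beyond the reverse-primer end is removed (trimming never cuts
into a primer match).

Tandem repeats are then removed from the forward and reverse splits
independently: adjacent windows `seq[i:i+w]` vs `seq[i+w:i+2w]` are
compared for window sizes 10–350 bp under a similarity threshold that
falls linearly from 95% at 10 bp to 70% at 350 bp (longer repeats are less
similar to each other; the steep small-window end keeps the false-positive
rate on repeat-free sequence at effectively zero — at 90% a 10 bp window
admits one mismatch and fires ~0.02–0.03 times per read on random
sequence). Candidate window sizes come from exact 8-mer seed pairs; every
position is screened per candidate window with a vectorised Hamming
profile and verified with the gapped window identity, so the scan is exact
for near-identical copies at ~1% of the cost of an exhaustive sweep (an
exhaustive mode exists and is tested equivalent on planted cases). Windows
are processed largest-first and winners claim their spans, so a long
repeat is never fragmented into short ones; copies 2..n are excised.
Merged reads outside 1300–1450 bp are discarded — this is also what
removes reads whose repeat insert exceeded the 350 bp scan ceiling.

## nanoClust: partitioned clustering and consensus

Direct 97% clustering of full-length 2% error reads shatters into
singletons because ~28 absolute errors accrue per read. nanoClust instead
slices every corrected read at fixed coordinates (default partitions
1–450, 451–900, 901–1300), and within each partition: dereplicates
(abundance-sorted, ties first-seen), removes two-parent chimeras, and
greedily clusters at 97% identity. The partition with the most
non-singleton OTUs wins (ties: most reads retained, then lowest index);
its per-OTU read ids recruit the full-length reads, each bin is gated to
±10% of its mean length, and a majority consensus is called from the
first 50 gated reads in input order.

Numerical choices that matter:

* **Clustering identity** is computed from a unit-cost optimal global
  alignment (edlib) as matches over columns with *terminal indel runs
  excluded*. The exclusion is essential: indels upstream of a partition
  shift the slice window, and an identity that charged the shift at both
  ends would fragment later partitions by drift class. Terminal gaps are
  penalised during alignment and excluded only from the identity — a true
  ends-free optimisation would degenerate (a chance 10 bp exact match
  would score 100%).
* **Greedy rule**: each unique joins the best-identity centroid at or
  above threshold (ties to the earliest centroid), else founds a new
  centroid. A shared-8-mer prescreen skips hopeless comparisons and a
  conservative bound stops the search once a near-perfect hit is found;
  both are disabled for short sequences so the full path is exercised by
  the oracle tests.
* **Chimera test** (simplified relative to uchime, and switchable off):
  in abundance order, a candidate is flagged when the best split of its
  prefix/suffix across two earlier uniques — both at ≥ 2× its abundance —
  reaches 99% combined identity and beats the best single parent by ≥ 2
  percentage points. Only the candidate's top-4 k-mer-sharing parents are
  tested (a chimera's true donors are its top sharers).
* **Consensus rules**: per column the plurality symbol wins; a column
  whose strict plurality is the gap is dropped; base-vs-gap ties retain
  the base (the platform's dominant error is deletion — gap-favouring
  ties would compound it); base-vs-base ties resolve A < C < G < T; N
  never beats a concrete base.
* **MSA**: the internal aligner stacks unit-cost pairwise alignments of
  every read against the 6-mer-profile medoid read (backbone/star
  construction, insertions left-aligned per backbone position). A
  progressive profile-merge variant guided by a k-mer tree was
  implemented first and measured substantially worse — the consensus
  anchor mapping drifts as groups grow — while the star construction
  recovers a 1 kb reference exactly from 5–50 reads at 2% error. MAFFT
  (global-pairwise guidance) is available as an optional backend and is
  cross-checked in the tests to agree with the internal consensus within
  0.2 percentage points.

All tie-breaks are deterministic; two runs on the same input are
byte-identical.

## The simulator: what it emulates

The generator produces study-condition reads with a per-read ground-truth
ledger (species, concatemer count, rotation, strand, repeat, exact edit
list; replaying a ledger entry reproduces the read byte-exactly).

**References.** All species derive from one random ancestor by core
substitutions (default 5% divergence, verified pairwise by alignment);
every reference is flanked by the 8F/1387R primer pair (degenerate
positions instantiated once). References carry exactly 4 planted
homopolymer runs of 5–7 bp (16S-like composition; other runs are capped
at 4 bp so the systematic-error burden is controlled), and are rejected if
they contain tandem self-similarity detectable by the chopSeq scanner —
otherwise an error-free read would not be exactly reconstructable.

**Error model.** A read's idiosyncratic error rate is the majority-vote
flip probability `P(Binomial(nc, e0) > nc/2)` at raw per-base error `e0 =
0.10` over its concatemer count `nc ~ truncated geometric(0.5) on [3, 21]`
(the workflow's minimum is 3 copies). This makes quality strongly bimodal
— 3-copy reads carry ~2.8% error, 6+-copy reads are effectively clean —
which is the property that lets 97% clustering work at all: dereplicated
partitions surface an abundant error-free modal sequence that becomes the
centroid, clean reads join it, and the noisy 3-copy tail falls out as
singletons (mirroring the sizeable read loss the real workflow shows at
its clustering step). A flat independent error model at the same mean rate
was prototyped first and makes 97% clustering mathematically impossible
(read-to-read identity ~95%), so it cannot be what the real pipeline saw.
Errors split sub:del:ins = 0.80:0.15:0.05 — deletions three times
insertions, with the deletion bias concentrated in the systematic channel:
each reference homopolymer run > 4 bp loses one base per read with
probability 0.95 (`homopolymer_del_boost`). The substitution-leaning
idiosyncratic residue is deliberate: indel-heavy idiosyncratic noise would
impose per-read coordinate drift on fixed partition slices that the real
data demonstrably does not have (it clustered correctly). Expected totals:
~1.65% idiosyncratic + ~0.27% systematic ≈ 1.9% mean error (97–98.5%
identity band), and the consensus retains one deletion per homopolymer run
(~99.7% consensus accuracy — the residual errors are homopolymer
deletions).

**Artifacts.** With probability 0.7 a read receives a tandem duplication:
2–3 total copies of a segment of log-normal length (median 30 bp, σ=0.6,
floored at 10 bp — the smallest observed insert and the scanner's window
floor), plus a 1% heavy tail up to 1500 bp; the `1d2` chemistry preset
adds a longer second mode. The read is rotated at a uniform breakpoint and
reverse-complemented with probability 0.5. Breakpoints and repeat loci
avoid the primer spans and each other: a breakpoint inside a primer or a
repeat is unrecoverable for any splitter, and modelling those rare reads
would only convert "exact reconstruction" checks into coverage statements.

**What the simulator does not emulate**: pass/fail basecalling yields,
chimeric concatemers (removed upstream in the real workflow), abundance
bias, inter-operon variation within a genome, and any sequence-context
error structure beyond homopolymers. Passing tests therefore demonstrate
the algorithmic contracts (orientation recovery, repeat excision,
partition selection, consensus behaviour) under controlled artifact
statistics — not performance on any particular real run.

## Evaluation

Queries are assigned to references by unit-cost edit distance over both
strands, then scored from the best local alignment under BLASTn-like
scores (+2/−3, gap −5/−2). The scores matter: under the mild default
scheme an optimal alignment of a rotated read *bridges* both segments
through two huge internal gaps (gain 2/col beats extension −1/col),
destroying the identity/coverage decomposition; under BLASTn-like costs
the primary alignment covers the largest colinear segment, so identity
stays an error measurement and the aligned fraction diagnoses
misorientation. Deletions whose reference base lies in a run > 4 bp are
typed as homopolymer deletions.

## Problem sizes

Default study conditions: 10 species × 100 reads, 1400 bp amplicons;
recovery statistics use 20 independent seeds; consensus-accuracy
experiments use 20 OTUs at 10 or 50 reads each. One mock run takes ~20 s
on one CPU; the full acceptance recomputation 6-10 minutes.

## Known limitations

* The tandem scanner's 350 bp window ceiling means reads with larger
  inserts are discarded by size selection rather than repaired.
* Percent identity from an optimal alignment path is path-dependent within
  a few bases of the sequence ends (a boundary substitution admits a
  co-optimal terminal indel pair); all identities here are deterministic
  but may differ from another optimal-path convention by ~0.1–0.3
  percentage points near thresholds.
* Species within 97% identity would merge into multi-species OTUs by
  construction; the generator's 5% divergence floor sidesteps this
  deliberately.
* The chimera stage is a two-parent test on partition slices, not a full
  uchime reimplementation; with the default error model real chimeras are
  absent and the stage is exercised by constructed cases in the tests.
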