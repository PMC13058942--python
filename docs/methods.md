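# Methods

## Distances and stratification

Pairwise evolutionary distances are patristic path sums on a user-supplied
Newick guide tree (every edge must carry a length). Without a tree, the
fallback is a pairwise global alignment (fixed scores +1 match, −1
mismatch, −2 per gap position, so distances are reproducible) followed by
the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) of the mismatch
fraction p over aligned columns; p ≥ 0.75 raises a saturation error. When
both tree and sequences are available the tree wins. Note that above
roughly 40 % divergence the optimal alignment genuinely starts to differ
from the generating homology, so alignment-based distances are only
trustworthy well below saturation — one reason the method excludes very
distant promoters anyway.

Promoters are stratified by distance to the target into three bins with
cut points 0.05 / 0.31 / 0.55 / 0.73. The written ranges share endpoints,
so the implementation fixes a half-open convention: [0.05, 0.31),
[0.31, 0.55), and closed-top [0.55, 0.73]. Below 0.05 a promoter is too
similar to be informative (background has accumulated too few
substitutions to contrast with a conserved site); above 0.73 it is outside
the supported range. Both kinds of exclusion are logged, never silent.

## Bootstrap subset generation

With subgroup sizes (s₁, s₂, s₃) and quota q = (3, 3, 6), the maximum
number of complete disjoint subsets is M = min_k ⌊s_k/q_k⌋, and
N = rounds·M subsets (default rounds = 2) are drawn in epochs. Within an
epoch each subgroup is shuffled once and consumed without replacement, so
no promoter appears twice per epoch and, when M·q_k = s_k, every promoter
of subgroup k is used exactly `rounds` times over the plan — maximal but
not exhaustive reuse, realized deterministically rather than only in
expectation. "With replacement" thus operates across epochs.

The diversity rule is a minimum pairwise distance among subset members
(default 0.02, configurable — no published value exists). A candidate that
violates it against the current members is skipped (retry budget 100 per
slot); if no candidate passes, the constraint is waived for that slot with
a warning, because quota exactness is the harder invariant. The target
promoter is appended after quota checks and never counts toward quota or
diversity. A subgroup smaller than its quota makes M = 0, which is an
error with guidance (relax the stratification) rather than a silent quota
shrink.

## Motif discovery and voting

Two built-in finders implement the discovery contract behind a pluggable
interface (the interface exists so external finder binaries can be
adapted in; none are required):

* **Gibbs site sampler** — one site per sequence (OOPS), both strands.
  Initialization uniform; each sweep holds out one sequence, builds the
  PWM from the remaining sites (pseudocount 0.5), and resamples the
  held-out site proportional to the PWM/background likelihood ratio over
  every offset on both strands. The best information-content configuration
  is tracked; a restart stops after 500 sweeps or 50 sweeps without
  improvement; 5 restarts, best kept. Fully seeded.
* **Consensus (word) finder** — enumerates every W-mer present in the data
  (both strands, W ≤ 12 as an enumeration guard); a word supports a
  sequence if an occurrence lies within Hamming distance 1 (default).
  Ranking is (supporting sequences, total occurrences, lexicographic);
  the motif is built from the best occurrence per supporting sequence.
  Note a word and its reverse complement always tie on counts; the
  lexicographic rule picks the smaller deterministically.

Defaults scan widths {8, 10, 12, 14, 16} per finder (the consensus finder
contributes up to its W ≤ 12 guard) and keep the top motif per width.

**Voting.** Instances from different finders are grouped (union-find) when
they lie on the same promoter and strand and overlap by ≥ 0.5 of the
shorter width; instances of one source motif always stay together. A group
survives with instances from ≥ 2 distinct finders (quorum auto-drops to 1
when only one finder ran). Each surviving group yields one merged motif:
all locations are re-anchored into the coordinate frame — and width — of
the group's highest-IC source motif, correcting other finders' anchors by
their modal shift against that reference, one instance per promoter/strand
location (best-ranked source wins). Early versions merged by per-promoter
interval intersection extended to the modal group width; that smeared
column registration whenever finders disagreed by different amounts on
different promoters and truncated width on ties, measurably degrading both
PWM information content and downstream database discrimination, so the
reference-frame rule replaced it. A shift that would detach a site from
its own evidence falls back to the source interval, so no merged instance
ever lacks an overlapping input instance.

Ambient N bases contribute the background distribution to counts and score
zero log-odds everywhere.

## Histogram, peaks

A run's combined motifs are projected onto the target only if they have a
target instance and instances on ≥ 6 distinct non-target promoters (half
the default subset) — the footprinting requirement of simultaneous
detection in orthologs, which no published threshold quantifies. Within a
run, covered target positions are OR-ed (a run votes 0/1 per position, so
the histogram reads as "fraction of runs", and wide or duplicated motifs
cannot inflate it); runs are then summed.

Peaks are maximal segments with count ≥ ⌈0.25·N⌉, merged when separated by
< 5 positions, discarded when narrower than 6 bp, and numbered left to
right. All three thresholds are declared engineering defaults, all
configurable; no smoothing and no FDR model over peak heights. The
histogram is exported as BedGraph always and BigWig when a writer backend
is installed.

## PWM–database comparison

For a query PWM against each database motif, every ungapped offset with
overlap ≥ 5 columns is scored in both orientations. Column similarity is
the Pearson correlation of the two frequency 4-vectors (zero-variance
columns — e.g. N-padded — correlate 0 by convention, keeping degenerate
columns well-defined). The alignment score sums column similarities over
the overlap and divides by the query width, so query columns left
unaligned count as zero: without this, a chance 5-column perfect overlap
can outscore a full-width good match, which demonstrably inverts
implant-vs-decoy rankings on synthetic benchmarks.

Significance is empirical: the identical scan statistic is recomputed for
1,000 column-shuffled copies of the database motif; the p-value is the
add-one-corrected fraction of shuffles scoring at least as well
(resolution 1/1001), and E-value = p × database size. Under a random
query the observed scan is exchangeable with the shuffled ones, so null
p-values are uniform — verified by KS test in the suite. Reverse
complementation of a PWM reverses column order and complements each
column (which, over ACGT, reverses the 4-vector).

Across runs, one E-value per factor per run (the run's best) enters the
per-peak statistics: median, quartiles, fraction below the 5 %
significance threshold, and the top-candidate frequency — the fraction of
all runs in which the factor was the peak's best match (runs with no match
count in the denominator, so frequencies sum to ≤ 1; ties at the empirical
p-value floor break on alignment score).

## Consolidated alignments and presence map

For each peak, every run's peak-overlapping motif contributes: its
non-target instances are re-anchored so the instance start aligns with the
run's target instance, trimmed/extended to peak width ('−' strand rows
reverse-complemented; rows crossing a promoter boundary are N-padded and
flagged). When runs disagree about a promoter's position, the most
frequently detected one wins, ties to the leftmost. The stacked rows give
a PWM (pseudocount 0.5) that is itself compared to the database — peak
width, not motif width, defines the alignment length, deliberately
including conserved flanks. The presence map marks, per taxon, whether any
run detected the motif in that taxon's promoter, and separately whether
the taxon was ever sampled into a subset (absence of evidence vs evidence
of absence).

## Synthetic data

The simulator emulates exactly the structure footprinting assumes. A
pure-birth tree (birth rate 1) is reshaped so the target leaf's distances
to the other leaves take prescribed values spanning the three
stratification bins in 1:1:2 proportion (matching the 3:3:6 draw): the
whole tree is scaled until shared paths sit below the smallest prescribed
distance, then each non-target pendant edge is set to land exactly on its
value. The root promoter (default 250 bp) is i.i.d. background with motif
columns sampled from the implant PWM (default: 12 columns, 0.85 dominance,
~13.8 bits); each branch of length d substitutes background sites with
probability (3/4)(1 − e^(−4d/3)) and motif sites with the same expression
at c·d (default conservation c = 0.1), so motif divergence grows with
distance but slower than neutral — rate scaling, not per-leaf resampling.

Defaults (30 taxa, giving subgroup sizes near (8, 7, 15), M = 2, N = 4
runs; one implant; 19 matched-specificity decoys in the test database)
are the conditions under which all end-to-end guarantees are stated. Not
emulated: indels and rearrangements (the projection logic assumes
positionally stable promoters), non-stationary composition, correlated
motif columns, and operon structure — so passing tests demonstrate the
statistical machinery, not robustness to alignment error in real genomes.
Because all leaves descend from a single root draw of the implant, the
realized site can deviate from the PWM consensus (~15 % of columns in
expectation), which is precisely why single-run database matches are
sometimes ambiguous and the multi-run statistics are needed.

## Determinism and problem sizes

One master seed drives everything; per-run finder seeds derive as
seed + run_id (so adding runs never reshuffles earlier ones) salted by
width. Identical configuration and seed give byte-identical TSV/BED/FASTA/
MEME artifacts. The suite's end-to-end checks use 20 seeded replicates of
the default 30-taxon simulation; unit-level checks use smaller scaled-down
pools chosen to exercise the same code paths at interactive speed.
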