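# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package; nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Sequence model and alphabet

A satellite array is a DNA string over `{A,C,G,T,N}` presumed to contain
head-to-tail ~171-bp alphoid monomers on either strand.  Consensus
sequences use an extended alphabet: concrete bases, IUPAC degeneracy codes
(`R`, `Y`, `S`, `W`, `K`, `M`, `B`, `V`, `N`, …), and gap codes for
positions that are either absent or a fixed base: `F` = −/A, `I` = −/C,
`J` = −/G.  The published code list has no symbol for −/T; this package
uses `O` for that case (configurable in the consensus builder).  The 19
shipped gorilla consensus entries were transcribed from the published
table and verified: each entry's character count equals its printed size,
counting gap codes as one position each.

## Alignment

All pairwise alignments use `Bio.Align.PairwiseAligner` with BLASTN-style
scoring: match +1, mismatch −2, and affine gaps costing 5 + 2·L for a gap
of length L (the convention under which "open 5, extend 2" describes a
1-bp gap costing 7).  A degenerate symbol scores as a match against any
base of its expansion; `N` matches everything.  The first optimal
alignment reported by the aligner is used throughout, which is
deterministic for fixed inputs.

## Monomer segmentation

Segmentation is an exact dynamic program that tiles the array with copies
of a reference consensus (default: the 172-bp general gorilla consensus),
minimizing the total unit-cost edit distance of the intervals to the
reference.  State `M[i, j]` is the minimal cost of explaining the first
`j` array bases with complete monomers plus a partial monomer that has
consumed `i` reference positions; completing a monomer (`i = m → 0`) is a
free transition.  Degenerate reference symbols match their expansion bases
at zero cost; gap-code positions may be deleted for free (their "optional"
reading).  The first and last monomers may start or end mid-reference:
such flanks are emitted with `partial=True` when ≥ 100 bp
(`min_flank_keep`), else dropped.  Traceback prefers boundary, then
diagonal, then deletion, then insertion moves, and takes the deepest
reference offset at the array end — this makes boundary placement
deterministic and exact on noise-free tandem input (asserted by tests).
Partial monomers are excluded from all downstream statistics.  The DP is
O(n·m) (array length × reference length) and JIT-compiled with numba.

Phase (where monomer 1 starts) is implied by the globally optimal tiling
rather than chosen by a separate leading-monomer rule; on noise-free input
the two coincide, and the global rule is the simpler deterministic
contract.

Orientation is decided by the better of the two strandwise local-alignment
scores of the reference against the array; a best score below 50 (random
1-kb sequence scores ~10–30 under this scoring) is reported as "no alphoid
signal".  Deeply diverged monomeric arrays (per-monomer divergence drawn
up to 40%) occasionally fall below this floor; the pipeline records the
error for that array and continues.

The tandem period estimate is the lag `k ∈ [140, 220]` maximizing the
shift-match fraction `mean(s[i] == s[i+k])`; a maximum below 0.5 (random
sequence: ~0.25) is reported as non-tandem.  This is an alignment-free
stand-in for "align the first monomer against the whole sequence" and is
exact on noise-free tandem arrays.

## PRD motifs and A/B typing

The pJα motif `CTAPyGGTGPuAAAAGGAA` and CENP-B box `PyTTCGTTGGAAPuCGGGA`
are scanned as degenerate 17-mers at every offset of a monomer (motifs are
never split across monomer boundaries, and the simulator never splits
them).  The best hit minimizes mismatches, with ties broken toward pJα and
then the smallest offset; hits with more than 5 mismatches are discarded.
CENP-B "core" positions default to the nine invariant
`TTCG…A…CGGG` nucleotides of the 17-mer, i.e. positions
{2,3,4,5,10,13,14,15,16}; the published account cites nine essential
positions without listing them, so the set is configurable.  pJα has no
published core; the default is all 15 non-degenerate positions, likewise
configurable.

A monomer is typed A or B by p-distance to the general A- and B-type
consensuses after global alignment; the strictly nearer one wins (tie
margin δ = 0), and monomers whose nearer distance exceeds 0.40 — the top
of the published monomeric divergence range — are left undetermined.
Applied to the published family consensuses themselves, this reproduces
the published compositions: SF2 = B–B–B–A–B–A–B–A (5 B / 3 A), SF3 =
B–B–B–A–A (3 B / 2 A).

## Consensus building

Monomers are aligned pairwise-globally to a reference and projected into
reference coordinates; insertions relative to the reference open new
columns only when shared by a strict majority of rows, otherwise they are
kept as per-row metadata (so each row still reconstructs its monomer
exactly).  This reference-projection replaces progressive multiple
alignment: it is deterministic, testable, and adequate for near-identical
monomer sets; it is *not* adequate for aligning deeply diverged sequence
families.  Per column, a symbol (including gap) present in more than 50%
of rows is emitted (majority gap deletes the column); otherwise the
ambiguity code covering the symbols at frequency ≥ 0.2
(`min_component_freq`, filtering rare noise bases) is emitted, with
gap codes for one-base-plus-gap sets and `N` where no code exists.
Exactly-50% columns are never emitted as a single base.

## HOR detection

For the ordered monomers of an array, `d[k]` is the mean p-distance
between monomers `i` and `i+k` over all valid `i` — the diagonal means of
the full pairwise distance matrix (which doubles as dot-plot data).
Distances come from pairwise global alignment with gap and ambiguous
columns removed, so the 18-bp insertion block of an extra-long monomer is
automatically excluded when only one of the pair carries it; no special
masking is needed and SF2's period survives its length-variant monomers.
A period `k` is called when (i) `d[k] ≤ 0.10` (`max_dist`, between
within-HOR divergence, ≲6%, and monomeric divergence, ≳10%), (ii)
`d[k] ≤ 0.5 ×` median of `d` over offsets that are not multiples of `k`
(`dominance`), and (iii) at least 2 full units fit.  The smallest
qualifying `k` is reported (distances at multiples of a perfect period
also vanish, so the fundamental period wins); `k = 1` means a homogenized
(monomeric) array, and no qualifying `k` means a monomeric array.  Arrays
are treated as linear; no wrap-around pairs.  The published work judged
higher-order structure by TRF/dot-plot inspection without a stated
threshold; this rule is the package's explicit operationalization.

## SF assignment

Each monomer is assigned its nearest family consensus among the 16
family/monomeric entries (ties, which tests show do not occur for the
published set itself, go to the smallest name and are logged).  An array
is assigned to SF1/SF2/SF3 only on concordant evidence: HOR period equals
the family's unit count *and* at least 80% of monomers are nearest to that
family's units (the 0.8 majority tolerates the unit truncations that make
tetrameric SF3 stretches more common than pentameric ones); optionally the
cyclic succession of nearest-unit names must match the published unit
order up to rotation.  Arrays whose HOR call is monomeric are labelled
monomeric; everything else is unassigned.  A human consensus set is not
shipped (the 12 human consensus sequences are not printed in the source
table) but any `ConsensusSet` can be supplied in its place.

## Insertion characterization

Extra-long monomers (≥ 180 bp, non-partial) are aligned to a B-type
reference.  Because gap placement inside a tandem duplication is
ambiguous, the duplication is characterized by direct phase search around
the inserted region: for unit lengths 14–30 and all phases, consecutive
unit-sized blocks are chained while adjacent blocks stay within 4 edits;
the best chain (longest, then fewest edits, then longest unit) gives the
duplication unit and `copies = chain − 1`.  On the published extra-long
consensus this recovers the 22-bp unit `CTTTGAGGATTTCGTTGGAAAC` — the
unfinished CENP-B box plus upstream bases — with one copy and a net 18-bp
gain versus gD1.0, matching the published 22-bp-duplication +
4-bp-deletion model; the report's notes record the equivalent
shorter-perfect-duplication reading.  `box_break_pos` is the first
position of the 17-mer pattern (Py = position 1) at which the upstream
interrupted copy diverges: 14 for the published sequence, consistent with
"the 13th position" when counting from the first invariant T.  The
regenerated box is any core-intact CENP-B window whose completion lies
beyond the last inserted copy.

## Phylogenetics

p-distances use pairwise deletion: columns where either row is not a
concrete base are removed per pair; a pair with no comparable column is an
error.  Neighbor-joining follows Saitou–Nei (Q-matrix minimization,
standard two-branch length formulas, final three-cluster star join) with
ties broken by the lexicographically smallest label pair; negative branch
lengths are clamped to zero and flagged.  On additive matrices the tree
reproduces all path lengths to < 1e−9 (tested against random trees and
cross-checked against scikit-bio's implementation).  Bootstrap resamples
alignment columns with replacement, rebuilds the NJ tree per replicate,
and reports bipartition recovery percentages on the full-data tree;
replicates that produce a pair with no comparable columns are skipped.

## Simulator

The simulator is the package's definition of the study conditions.  An SF
array is the family's consensus unit (published succession), ambiguity
resolved once per array (uniform draws; gap codes draw absent/base), tiled
`n_units` times with i.i.d. substitutions — defaults 1–2% match the
published within-HOR divergence regime.  A monomeric array draws each
monomer from gM1 and mutates it at a per-monomer rate uniform in
[0.10, 0.40], the published monomeric divergence range.  `insertion_copies`
2 or 3 inserts extra copies of the 22-bp duplication unit (derived at run
time by characterizing gD1.4 against gD1.0) into the extra-long monomer.
Indels are off by default (no published indel rate); when enabled, truth
boundaries are recomputed from the mutated monomer lengths.
`protect_motifs` (off by default) exempts each monomer's PRD window from
substitution so motif-conservation statistics can be varied independently
of background divergence.  Truth records boundaries in forward
coordinates; reverse-complemented output is flagged by strand.

What the simulator does not emulate: homogenization dynamics (unequal
crossover, gene conversion), N-runs and assembly artifacts of real WGSS
contigs, non-alphoid interruptions, and inter-chromosomal structure.
Passing tests therefore demonstrate correctness of the algorithms under
the published divergence regimes, not performance on raw genome assemblies.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale inputs chosen to
exercise every code path in seconds: HOR units tiled 1–6 times (arrays up
to ~5.5 kb), 10–20 replicate seeds for recovery properties, bootstrap at
30–500 replicates on ≤ 10 leaves, and NJ property checks on ≤ 9 taxa.
Floating-point outputs in pipeline artifacts are serialized at fixed
precision (6 digits) so reruns are byte-identical.  The full-scale
published dataset (2521 monomers from specific GenBank/WGSS accessions,
and derived counts such as the 104 extra-long units or the tree with
branch-length sum 77.65…) requires those exact retrievals and is out of
scope; the property suite and worked-example targets substitute for it.

## Known limitations

- Reference-projected alignment underestimates shared insertions present
  in ≤ 50% of rows (kept as metadata, absent from the consensus).
- The segmentation DP assumes one reference consensus per run; arrays
  mixing families with very different monomer lengths segment against a
  single 172-bp reference (adequate for the 167–189-bp range tested).
- The orientation floor (local score 50) can reject genuine but deeply
  diverged (>~35%) monomeric arrays.
- HOR calls for nested or mixed periodicities report only the smallest
  qualifying period.
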