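# Methods

This note documents the models behind `paleomito`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions at degenerate inputs.

## The identification problem

Competitive mapping identifies a sample by how well its reads fit each
candidate reference. Two summary statistics carry the signal:

- **Normalized read counts.** Reads are mapped against each reference
  *independently* (not joint best-of-panel), and per-reference counts
  after filtering are expressed as percentages of the best reference
  (the argmax gets exactly 100). Independent mapping means a read can
  count for several references; the *ratio* between them is the
  evidence.
- **Evenness.** With *S* aligned bases, *L* the reference length and
  *B* the number of positions covered at least once, mean coverage is
  *C* = *S*/*L* and mean depth over covered positions *D* = *S*/*B*.
  Evenness *C*/*D* = *B*/*L* is exactly breadth of coverage. Computing
  depth over covered positions only (the convention of `samtools
  depth`, which omits zero rows) is what makes the identity hold; the
  defining ratio is still computed and asserted equal in tests. A
  conspecific reference is covered essentially everywhere (evenness
  ≈ 0.98–1.0); a reference several percent divergent loses reads
  wherever local divergence exceeds the mismatch budget, leaving
  uncovered patches. Zero-coverage references get evenness 0 by
  convention (the ratio is 0/undefined).

A species call combines these with optional tree placement. Each line
*names* a reference or *abstains*: the count line abstains when the top
count is within 10 % of the runner-up (our formalization of "clearly
more reads"; an even two-species mixture should not produce a
confident call), the evenness line abstains only on an exact tie, and
the tree line reports the assigned clade or nothing. The verdict is
concordant iff every available line names the same target reference.
The human reference is carried as a contaminant control: it can never
be the verdict, but topping the raw counts earns a "low endogenous
content" note, the typical signature of a poorly preserved sample.

## Read mapping

A deliberately small, exactly testable mapper replaces a production
aligner; its contracts (length ≥ 30 filter, MAPQ ≥ 30 filter, duplicate
removal) mirror the standard aDNA workflow, and externally produced SAM
can be ingested instead.

- **Model.** Ungapped placement of the whole read, both strands, best
  (fewest-mismatch) position wins; ties break deterministically by
  (mismatches, position, strand). Gapless alignment is adequate because
  reads are ≤ 75 bp and mitochondrial indels between close canids are
  rare at that scale; it also keeps the brute-force oracle exact.
- **Seeds.** Non-overlapping exact k-mer seeds with k = 7 guarantee by
  pigeonhole that any placement within the mismatch budget
  ⌊0.1 · len⌋ shares at least one seed (⌊30/7⌋ = 4 seeds vs budget 3 at
  the shortest legal read; the margin grows with length). The unit
  suite verifies equality with an exhaustive all-positions scan.
- **Circularity.** References are indexed with the first
  `max_read_len − 1` bases appended, so origin-spanning placements are
  ordinary slices; reported starts are in [0, L), ends may exceed L
  before the modular wrap. SAM output writes such reads at their start
  with a full-length match (documented convention); depth computation
  wraps them.
- **MAPQ proxy.** 60 when the second-best placement has ≥ 3 more
  mismatches, 25·Δ for margins 1–2, 0 on ties. Any monotone uniqueness
  score filtered at a comparable threshold preserves the contract;
  repeats get 0 and are removed by the ≥ 30 filter.
- **Damage tolerance** is absorbed by the symmetric mismatch budget
  (default fraction 0.1), not by asymmetric scoring.
- **Duplicates.** One record per (start, end, strand); the survivor is
  the highest-MAPQ record, ties to the lexicographically smallest read
  id, so deduplication is deterministic and idempotent.

## Damage profiling and authenticity

Post-mortem deamination shows as C→T mismatches at 5′ read ends and
G→A at 3′ ends. The profile counts, per offset *i* from the terminus
(window 15 — beyond that the signal is negligible for ≤ 75 bp reads),
the fraction of reads whose reference base is C (resp. G) and read base
T (resp. A); reverse-strand alignments are complement-flipped into read
orientation first, so both strands feed one profile. The decay is
modelled as geometric, freq(i) = d·rⁱ — a standard single-strand
approximation — and (d, r) are recovered by weighted log-linear least
squares over the first six offsets (weights n·f, the approximate
inverse variance of log f). Full 12-class mismatch tables are available
behind a flag. Bayesian damage modelling and quality rescaling are out
of scope.

## Consensus

Per reference position: depth < 3 → N; otherwise the plurality base is
called if its frequency is ≥ 0.5 (inclusive — the threshold convention
is documented rather than inherited from any tool) and strictly unique;
top ties → N. Insertions relative to the reference are not represented.
An optional damage-aware mode excludes each read's terminal bases from
the pileup, useful for libraries without UDG treatment; it is off by
default since partially UDG-treated libraries carry little terminal
damage and depth is usually the binding constraint.

## Anchored alignment and diversity statistics

Consensus and reference sequences are each globally aligned to one
anchor reference (Biopython `PairwiseAligner`, match 1, mismatch −1,
gap open −5, gap extend −1) and stacked on the anchor's coordinates;
insertions relative to the anchor are dropped. The affine gap penalty
matters: a unit-cost aligner absorbs runs of substitutions into
spurious indel pairs on ~5–8 % divergent mitogenomes, which would leak
gap columns into downstream statistics. For ≥ 90 %-identical sequences
the anchor-stacked alignment is, after column stripping, essentially
what a progressive MSA would give, and it is exactly reproducible;
externally produced alignments can be imported to bypass the step.
Sequences whose alignment exceeds a 45 % edit fraction are rejected as
unalignable (near saturation).

Column stripping keeps exactly the columns where no sequence has a gap
or N, optionally excising the control region by its annotated 1-based
inclusive interval on the anchor; the anchor-coordinate map survives
filtering, and the operation is idempotent. All downstream statistics
require the stripped (gap/N-free) alignment, which also makes the
"pairwise vs complete deletion" distinction moot for pairwise
differences. Variable sites have ≥ 2 states; parsimony-informative
sites have ≥ 2 states each in ≥ 2 sequences. Pairwise differences are
absolute Hamming counts with within-group mean ± sample standard
deviation for groups of ≥ 2 (smaller groups are flagged). Percent
identity is matches over aligned columns, excluding columns with a gap
or N in either sequence.

## Median-joining networks

Identical rows collapse into haplotypes (frequency = multiplicity).
The network iterates to a fixed point: (1) the ε-relaxed
minimum-spanning network over Hamming distances — a pair is connected
iff its distance is at most the level at which whole-level Kruskal
merging first joins the pair's components, plus ε (default 0, the
common software default); (2) every mutually connected triplet proposes
its column-wise majority vector (three-way ties resolve to the first
node in a canonical ordering), added when it shortens the minimum
spanning tree over the node set; (3) non-sampled nodes with network
degree < 3 are pruned. Candidate generation from connected triplets is
the classical formulation and exhaustive search is fine at ≤ 100
haplotypes. Nodes are ordered canonically (lexicographically by state
vector), so the construction is invariant to input order.

One structural point deserves emphasis: the output is the
minimum-spanning *network*, the union of all minimum spanning trees.
Where equal-weight alternative connections exist its total edge weight
exceeds any single spanning tree; the guarantee is that the network
*contains* a spanning structure for the sampled haplotypes no heavier
than their MST, with medians (Steiner points) only ever shortening it.
The triplet {000, 110, 101} is the canonical case: the median 100 is
inserted and total length drops from 4 to the Steiner-optimal 3.

## Distances, neighbor joining, placement

Distances from the stripped alignment: p-distance (differing fraction),
JC69 −(3/4)·ln(1 − 4p/3), K80 from transition/transversion proportions
−(1/2)·ln((1 − 2P − Q)·√(1 − 2Q)); saturated pairs raise an error
naming the pair. Neighbor joining uses the Q-criterion with
deterministic tie-breaks (taxon order) and clamps negative
branch-length estimates to zero, counting them on the tree. NJ + K80
stands in for likelihood/Bayesian tree building: for the placement
question — which clade a sample joins — distance methods suffice at
mitogenome scale and are exactly testable (NJ returns additive-matrix
trees exactly; the suite cross-checks topology against an independent
NJ implementation and an exhaustive topology enumeration). External
newick trees can be imported for placement if users run ML elsewhere.

Bootstrap resamples columns with replacement, rebuilds the tree per
replicate, and maps bipartition frequencies (percent) onto the
full-data tree. The tree is rooted on the outgroup's pendant edge
(split at its midpoint; rooting is idempotent). A query's assignment is
the target reference that is its closest leaf by patristic distance
within its smallest ancestral clade with support ≥ 50 (the root always
qualifies); if that clade holds no target reference the line reports
nothing. This rule is a formalization of reading clade membership off a
figure, and reports flag it as such.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis relies
on, with defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| ref_length | 16,500 bp | mitogenome scale |
| pairwise_divergence | 0.08 | dhole-wolf ballpark (~92 % identity) |
| fragment length | lognormal, mean 55 sd 15, truncated [30, 75] | right-skewed aDNA profile under a 75 bp single-end, ≥ 30 bp regime |
| d5 = d3 | 0.2 | moderate terminal deamination (partially UDG-treated libraries show reduced damage) |
| decay_r | 0.5 | geometric decay halving per position |
| seq_error | 0.005 | Illumina-scale per-base error |
| dup_rate | 0.05 | modest PCR duplication |

Panels evolve from a random ancestor by substitutions only (star
topology; per-reference branch overrides allow a distant outgroup or a
human-like contaminant at ~25–30 %). Substitution-only evolution keeps
coordinates shared across the panel, so the generator's mutation log is
an exact oracle for alignment and identity statistics; indel robustness
is exercised separately with constructed fixtures. Reads start
uniformly on the circle (origin-spanning fragments allowed), damage is
applied before sequencing error, duplicates copy a parent's coordinates
and damaged sequence and receive independent sequencing error, and
every read name carries a parseable truth tag.

Not emulated: real fragment-length spectra (the lognormal parameters
are conventions, not measured values), capture bias — including the
cross-species bait bias that can depress coverage of low-identity
regions — paired-end reads, adapter read-through, heteroplasmy, and
indel evolution. Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to every
property of real libraries.

## Problem sizes and numerical conventions

The validation studies run at the scale of the intended use case:
species assignment uses 20 replicates of 5,000 reads against four
16.5 kb references; damage recovery uses 20,000 reads on a 3 kb
reference (the profile depends on read termini, not reference length);
consensus accuracy uses ~15× mean depth on 16.5 kb; tree recovery uses
additive matrices of 4–6 taxa and an 8-leaf tree with 20 kb of
sequence at low divergence. The whole battery completes in about two
minutes on one CPU.

Conventions at degenerate inputs: empty alignment sets yield flagged
("no_data") profiles and zero-valued coverage summaries; all-zero count
vectors normalize to all-zero percentages with a flag; empty FASTQ
inputs produce a `no_data` report and a non-zero exit from the CLI;
stripping that removes every column flags the empty alignment; an
absent outgroup, a saturated distance pair, and mixed-reference
deduplication raise errors naming the offender. All randomness flows
through explicit integer seeds; identical seeds give byte-identical
FASTQ, JSON and network artifacts.

## Known limitations

- The mapper is desk-scale: linear scan per read over seed candidates,
  suitable for ~10⁴–10⁵ reads × mitogenome references, not for nuclear
  genomes.
- Gapless alignment means reads spanning a true indel map with inflated
  mismatch counts or not at all; at canid-mitogenome divergences this
  loss is negligible, and SAM import offers an escape hatch.
- The anchored MSA inherits the anchor's coordinate system; regions
  deleted in the anchor are invisible to all downstream statistics.
- Evenness saturates at 1.0 once every position is covered, so at very
  high depth it loses discriminatory power between references that are
  both fully covered; counts and placement carry the call there.
- `clade_of` depends on bootstrap support values; with very short
  alignments supports are noisy and the tree line abstains more often.
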