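# Methods

This note documents the model behind `haplosample`, its tunable
parameters, the numerical choices made where the design was open, what
the synthetic generator does and does not emulate, and the known limits.

## Graph model and clipping

Graphs are bidirected sequence graphs: nodes carry DNA labels, undirected
edges join node *sides*, and named oriented paths spell haplotypes (a
forward step reads the label and exits the right side; a reverse step
reads the reverse complement and exits the left side). I/O is GFA
1.0/1.1 restricted to S, L (overlap `0M` or `*`), P and W records; P
records are reference paths, W records haplotype walks. Self-loops and
parallel edges are accepted by the data model but rejected later by the
chain decomposition — I/O stays permissive, the algorithm constrains
where it must.

The **clip filter** repeatedly removes nodes that have one side of
degree 0 and are not on a reference path, and removes edges hanging off
the outer ends of each reference path. The result has exactly two tips
(degree-0 node sides) per component — the two ends of the reference.
Haplotype paths touched by clipping are trimmed when only a prefix/suffix
was removed and dropped when internal material was removed; the rule is
this package's choice, since clipping targets dangling off-reference
material and precedes indexing.

## Chain decomposition without a snarl tree

A full snarl decomposition is not implemented. Instead, a component's
**boundary nodes** are the nodes that every haplotype pass through the
component visits exactly once, in a single shared order and orientation
(up to whole-pass reversal). On graphs whose components form one
top-level chain this recovers the chain's node-and-bubble skeleton, and
it provides exactly the guarantee block sampling needs: every sampled
path visits the same boundary nodes in the same order, so any
recombination of per-block selections is a plausible haplotype. If two
passes imply inconsistent orders (impossible under a well-formed chain),
offending nodes are removed via longest-common-subsequence against the
reference pass order until the orders agree — a deterministic, order-free
fallback.

Passes are obtained by splitting each path at its visits to the two tip
nodes; passes that run right-tip-to-left-tip are normalized by reversal.
The **minimum distance** between consecutive boundaries is the minimum
over passes of the summed node lengths in between (counting each shared
boundary node once) — the same semantics a minimum distance index gives,
computed directly at this scale.

**Blocks** merge consecutive boundary intervals greedily left to right
until the running minimum length first reaches `b` (default 10 000 bp);
a trailing remainder forms the final, possibly shorter, block. Each
pass's slice between a block's two boundary nodes is one **local
haplotype**; a path crossing the component twice contributes two, and all
row orderings use (path name, visit ordinal) so runs are reproducible.
Reference paths contribute local haplotypes like any other path.

## k-mers

Within each block, haplotypes are described by canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement; k odd so no
k-mer is self-complementary; k-mers containing N are invalid).
Subsampling uses minimizers: in every window of `w` consecutive k-mers,
the k-mer with the smallest key is selected. The key is a constant-seeded
invertible 64-bit mix (murmur-style finalizer) of the 2-bit-packed
canonical k-mer — plain lexicographic keys would oversample poly-A runs.
The brute-force oracle used in the tests applies the same key function,
one k-mer at a time.

Minimizers are scanned per embedded-path sequence and located on the
graph (node, orientation, offset; spanning node boundaries along the
path's edges). Only k-mers whose set of distinct graph positions has size
one — **graph-unique** k-mers — are kept; occurrences are only visible
along embedded paths, mirroring a haplotype-based index. A block's
presence matrix takes the graph-unique k-mers located inside the block
and drops columns present in every local haplotype or in none. Defaults
`k = 29`, `w = 11`, `b = 10 000`.

## Read profile

Canonical k-mer counts come from any FASTA/FASTQ (the internal counter
joins reads with `N` separators and counts all valid windows
vectorized), or from a two-column TSV written by an external counter.
Singleton counts are dropped on loading; for sampling, counts are
restricted to the k-mers used in presence matrices.

**Coverage estimation.** `c` is the expected count of a k-mer present on
both haplotypes of the diploid sample; heterozygous k-mers peak near
`c/2`. The estimator builds the count histogram, lightly smoothed with a
±1 moving average (the empirical mode of a Poisson peak otherwise
flickers between tied neighbour bins), and proceeds:

1. if the smoothed mode is strictly above the median of the stored
   counts, the (raw-histogram-refined) mode is the estimate;
2. otherwise a secondary peak is sought within ±25% of twice the mode:
   it must lie above the median, be a local maximum of the smoothed
   histogram, and carry at least 50% of the primary peak's (smoothed)
   mass — this is the het-dominated case, where the mode sits at `c/2`;
3. otherwise, a mode within `max(2, 0.1·median)` bins of the median is
   still accepted as a single coverage peak straddling the median;
4. otherwise estimation fails and the user must supply `--coverage`
   (a dedicated CLI exit code).

The branch-2 predicate ("good enough secondary peak") and the branch-3
tolerance are this package's calibrated choices; both are exposed as
parameters. Step 3 exists because with every count stored, a lone
Poisson(c) peak has mode ≈ median and would otherwise never satisfy a
strict inequality.

**Classification.** Each matrix k-mer is classified by `count / c`:
absent < 0.25, heterozygous < 0.75, homozygous < 1.75, frequent ≥ 1.75
(configurable; recorded in the profile). The bands are midpoints between
the expected peaks at 0, c/2, c and repeats. Frequent k-mers are excluded
from all scoring. Classification is noisy per k-mer — at c ≈ 24 (30×
reads of 150 bp, k = 29) roughly 5–10% of k-mers land one band off — and
is only useful on aggregate; see Limitations.

## Sampling

Scoring constants (per k-mer, as (present, absent) pairs): homozygous
(+1, −1); absent-class (−0.8, +0.8); heterozygous (0, 0). A haplotype's
score is the sum over its row of the matrix. Greedy selection picks the
arg-max row (ties → lowest row order; totals compared at 1e-9 resolution
so mathematically equal sums tie regardless of floating-point summation
order), then updates: homozygous k-mers present in the pick have *both*
pair entries multiplied by 0.9 (the discount shrinks the k-mer's whole
influence, keeping signs); heterozygous k-mers move 0.05 from the side
matching the pick to the opposite side, preserving their zero sum. The
first pick approximates the consensus. Rows are never reselected while
unselected rows remain; if `n` exceeds the number of rows, the greedy
order repeats cyclically (with a warning) so every block contributes the
same number of selections.

**Diploid mode** evaluates every unordered candidate pair, including a
row paired with itself (a homozygous block); expected copies `x` come
from the class (absent 0, het 1, hom 2), realised copies `y` count the
pair members containing the k-mer, and the pair score is
`Σ (1 − |x − y|)`. Ties go to the lexicographically first pair in row
order; the per-block report counts tied blocks as an observability hook.
Blocks whose matrix has no scorable column (or fewer than two rows) fall
back to the first `n` rows in row order with reference rows first.

**Stitching** concatenates the i-th selection of each block in chain
order, merging the shared boundary node; a junction between selections
from different (path, visit) sources is a recombination. Reference paths
are appended on request. The stitched paths induce the output subgraph —
nodes and edges are subsets of the input's by construction, so any
alignment against the sampled graph is valid in the original. Components
are processed independently and the whole pipeline is deterministic:
fixed inputs give byte-identical output GFA.

## Synthetic data

The generator emulates the target setting at desk scale: a panel of
haplotypes derived from one random base sequence by SNPs (default rate
1/500), small indels (1–10 bp, rate 1/5000) and structural indels
(50–2000 bp, rate 1/20 000), with per-site alternate-allele frequencies
drawn from Beta(0.5, 0.5) so common and rare variants both occur.
Variants are non-overlapping with at least one reference base between
them and use padded (VCF-style) alleles, so the graph — one node per
inter-variant segment and per used allele — is a chain of biallelic
bubbles with exactly two tips. Reads are drawn uniformly from the two
haplotypes of a diploid sample (random strand, i.i.d. substitution
errors, default 0.1%); "30×" means 30× base coverage of the diploid
genome, i.e. ~15× per haplotype and a homozygous k-mer coverage of about
`30·(L−k+1)/L ≈ 24`. Recombinant samples switch donors at stated
breakpoints, emulating a sample absent from the panel.

Not emulated: inversions and other reversals (chain handling of reversed
passes is exercised with hand-built toys instead), nested variation,
overlapping variants, quality-score error models, PCR/optical artifacts,
and population structure beyond per-site frequencies. Passing tests on
these panels therefore demonstrate the algorithmic contracts — oracle
equivalence, subgraph and reconstruction invariants, aggregate recovery
under Poisson-like count noise — not performance on real human graphs.

## Evaluation harness and problem sizes

`haplosample.evaluation` reruns per-block selection against recorded
truth. A block is *informative* when each donor's local haplotype carries
at least 5 matrix k-mers separating it from the other donor's. *Pair
recovery* asks the selected pair to equal the donor pair's local
haplotypes as step sequences; *donor match* (used for recombinants, whose
genome-wide haplotypes are not in the panel) asks each selected local
haplotype to equal one of the two donors' locals. The study-condition
scenario is a 10-haplotype 100 kb panel at the default rates, 150 bp
reads at 30× with 0.1% errors, diploid selection from 32 (clamped)
candidates. The acceptance script aggregates three such replicates
(~30 informative blocks) per metric; the test suite additionally checks
50 smaller (10 kb) seeded scenarios for the subgraph invariant and 1 000
random 1 kb sequences for minimizer correctness.

## Limitations

- Per-k-mer classification noise at desk scale occasionally lets a wrong
  candidate pair outscore the true one: across study-condition
  replicates, pair recovery sits around 94–97% of informative blocks,
  with misses confined to pairs confused with panel rows 7–12 matrix
  k-mers away. Larger blocks (more distinguishing k-mers) and deeper
  coverage push the rate up; the miss mechanism is the classification
  noise the method explicitly tolerates on aggregate, not a selection
  defect (the wrong pair genuinely scores higher under the noisy
  classes, and supplying the exact coverage does not change it).
- Coverage estimation needs a recognisable peak structure; with very few
  matrix k-mers (small panels, short genomes) it fails by design and the
  coverage must be supplied.
- The boundary-node decomposition assumes one top-level chain per
  component (guaranteed after clipping); general nested snarl forests
  and within-component reversals that break the tip-to-tip pass model
  are out of scope.
- Presence matrices are stored uncompressed; k-mers with multiple graph
  hits are discarded rather than indexed.
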