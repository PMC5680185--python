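# Methods

## Data model

A genome is an ordered list of linear chromosomes; a chromosome is an
ordered list of signed family IDs (sign = strand, IDs may repeat for
duplicated genes).  Files use the GRIMM dialect (`>name`, whitespace
separated signed integers, `$` per chromosome).  Circular chromosomes are
rejected.  Every gene contributes two extremities, head (5′) and tail (3′);
an adjacency is the unordered pair {right extremity of a, left extremity of
b} for consecutive a, b, stored canonically with tail ordered before head
within a family.  That ordering is what makes the encoded column layout of
the two-genome worked example come out in the conventional order.

## Binary encoding

`encoding.encode` produces a taxa × characters 0/1 matrix: one column per
adjacency observed in any genome, one per gene family.  Telomeric
adjacencies are excluded from the matrix by default (they are still tracked
separately for assembly's telomere rules); the `include_telomeres` flag
exposes the alternative.  Copy numbers ≥ 2 go to a side table keyed by
(taxon, family); the presence character stays binary, and adjacency
characters are defined on family extremities so duplicate copies can
contribute distinct adjacency columns.  Export to relaxed PHYLIP and TSV is
provided for interoperability with external ML programs.

## Evolutionary model

Each character evolves independently as a two-state continuous-time Markov
chain, states {absent, present}, gain rate μ (0→1) and loss rate λ (1→0):

    P(1→0; t) = λ/(λ+μ) (1 − e^{−(λ+μ)t}),
    P(0→1; t) = μ/(λ+μ) (1 − e^{−(λ+μ)t}).

The DCJ event framework fixes the *prior* scale of these rates: with n
genes and C chromosomes a genome carries n + C adjacencies out of
C(2n+2, 2) possible end pairs, and each event removes and creates two, so
the per-event loss probability is 2(R+D+I+d)/(n+C) and the gain probability
2(R+D+I+d)/C(2n+2,2).  Only the gain/loss *ratio* is identifiable once
branch lengths are free, so the default model sets λ = 1 (branch lengths in
expected losses per present character) and μ/λ = (n+C)/C(2n+2,2); the event
total cancels.

`phylogeny.fit_model` then estimates by maximum likelihood, per character
class (adjacency vs content): a rate multiplier (content evolves much more
slowly than adjacencies) and a gain/loss ratio, profiled one parameter at a
time on the log scale and alternated with branch-length sweeps.  Fitting
the content gain rate matters: with the adjacency-derived ratio forced on
content characters, families inserted inside one clade can only be
explained as ancestral-plus-many-losses and ancestral gene sets inflate
badly (content accuracy drops from ~0.97 to ~0.53 in the simulation study).

DCJ distances between two genomes are computed on shared content after
exemplar reduction (first occurrence of each family kept) via the adjacency
graph: d = N − (cycles + odd_paths/2).  Event breakdowns add content set
differences as gene losses/gains.  No among-character rate variation is
modeled; that is an extension point.

## Tree inference

Likelihood uses Felsenstein pruning with per-node rescaling; the root term
weights states by the chain's stationary distribution, making the
likelihood invariant to re-rooting.  Search: neighbor joining (scikit-bio)
on weighted Jaccard distances between matrix rows as the start tree, then
first-improvement NNI hill climbing with bounded univariate branch-length
optimization per edge (tolerance 1e−6, lengths in [1e−8, 50]).  The
nonparametric bootstrap resamples columns with replacement (implemented as
column weights), and supports are bipartition frequencies classified
strong (> 90) / medium (60–90) / weak (< 60).

## Ancestral reconstruction

For each of the (leaves − 2) internal nodes the tree is re-rooted there and
every character's posterior is computed by Bayes' rule from the pruning
partials of all three incident subtrees, with prior f_G = the character's
empirical leaf frequency (the only frequency available at reconstruction
time).  A zero normalizer (degenerate prior contradicting the data) falls
back to the prior.  Genes with posterior strictly above the threshold
(default 0.5) form the ancestral content; a posterior of exactly 0.5 is
excluded.  A post-WGD ancestor is produced only by the explicit
chromosome-doubling operation, never inferred.

## Assembly

Maximizing the product of adjacency posteriors over a gene order is a TSP:
each selected gene is one node with two ports (head/tail, forced pairing by
contraction), one cap node stands for chromosome ends, and edge cost is
−log(ε + P) with ε = 1e−9.  When no telomeric posteriors exist the cap
uses the ε floor, which parks the cap at the least-supported junction.
Construction is greedy edge matching (adjacencies accepted by decreasing
posterior under degree and no-premature-cycle constraints); improvement is
full 2-opt plus segment relocation on instances ≤ 16 genes and
candidate-list 2-opt/relocation (scanning both tour orientations) above
that; chained double-bridge perturbations with a fixed seed keep the best
tour.  Held–Karp dynamic programming provides exact solutions up to 12
genes and is the oracle in tests.

The tour is opened at the cap and cut into chromosomes at junctions whose
created extremities are telomeric in the neighbor genomes, in strict
priority: (1) parent and both children, (2) both children, (3) any two of
the three, (4) parent only, (5) one child; ties break on lower junction
posterior, then position.  Rule (3) is implemented literally ("any two of
the three"), which subsumes (2) except for priority order.  The target
chromosome count is the median of the available neighbor counts (rounded
half up when only two are available) — the stopping rule is ambiguous in
prose, and the median is a symmetric, reproducible reading; it is
overridable.  If telomere candidates run out, the lowest-posterior
junctions are cut and a warning is logged.  Output chromosomes are flipped
so the first family ID is ≤ the last (determinism).  In the pipeline,
ancestors are assembled in post-order from a designated root so both
child-side neighbors are always concrete genomes; the rootward neighbor
fills the parent slot when already assembled.

## Simulator

Defaults reproduce the reference validation protocol: 20 genomes, a root
of 5,000 genes split evenly over 8 chromosomes, and a per-edge
adjacency-change budget drawn uniformly from [2750, 8250].  Events are
drawn from a configurable mix — inversion 0.70, translocation 0.10, fusion
0.02, fission 0.02, deletion 0.08, insertion 0.04, duplication 0.04 — with
geometric segment lengths (mean 5, truncated at 50).  The fitted yeast
event rates behind the original protocol were never published; these
weights are this package's documented defaults and are config-overridable.
Adjacency change is accounted as the size of the symmetric difference of
the telomere-inclusive adjacency sets before/after each event (the only
unit-consistent reading of "gene adjacency changes"), maintained
incrementally as a multiset so full-size replicates take seconds.  Every
intermediate ancestor and every concrete move is recorded; replaying the
log reproduces each leaf exactly, which is asserted in tests.

What the simulator does *not* emulate: gene conversion, unequal family
sizes, assembly artifacts (fragmented contigs), sequence-level divergence,
or any correlation between event types.  Passing tests therefore show the
pipeline recovers ancestors under its own generative model, not that real
genomes satisfy that model.

## Validation scales and a known information limit

The simulation study in `tests/test_acceptance.py` and
`scripts/acceptance.py` runs at a 1000-gene scale with the per-edge budget
scaled by the same 1/5 factor (U[550, 1650]), 2–3 replicates; this keeps a
full run in minutes while preserving per-adjacency churn rates.  Parameter
recovery uses 6 taxa, 200 genes, budget U[10, 30].

At the full-protocol churn, roughly half of a genome's adjacencies are
removed on every edge.  Two consequences follow directly and are *not*
implementation artifacts:

- An adjacency conserved across all 20 leaves must survive every edge of
  the tree (survival ≈ 0.45³⁷ ≈ 10⁻¹³), so the expected number of
  "non-split" adjacencies is 0, not a handful.
- An ancestor's adjacency is recoverable only if it survives to at least
  two of its three neighbor subtrees (probability ≈ 0.5), which caps
  adjacency-level reconstruction accuracy near 50% regardless of method.
  Gene content churns far more slowly, so content accuracy stays ≈ 97%.

Both are reported as computed; at lower event rates (the parameter-recovery
setting) adjacency and content recovery are both high.

## Numerical choices

Pruning partials are rescaled per node by their maximum (log-scale
accumulators), so deep trees cannot underflow.  Transition matrices use the
closed form, verified against the matrix exponential.  Branch-length and
rate optimization use bounded Brent (scipy `minimize_scalar`).  NNI
tie-breaking is first-improvement in sorted edge order; all stochastic
components (bootstrap, TSP perturbation, simulation) consume
`numpy.random.default_rng(seed)` streams, and the pipeline writes sorted,
fixed-format outputs so equal seeds give byte-identical artifacts.
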