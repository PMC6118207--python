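# Methods

This note documents the models, algorithms and design choices behind
`tigerpart`, in the order data flows through the package.

## Site rates from set-partition agreement

Each alignment column induces a set partition of the taxa: one block
per observed canonical nucleotide, with gapped, unknown (`?`, `N`) and
IUPAC-ambiguous taxa excluded from all blocks.  Ambiguity codes are
treated as missing throughout because the block construction needs an
unambiguous state per taxon; this is a package-level convention, stated
here once and applied consistently to the rate computation and to the
missing-data site filter.

The agreement of site *j* with a reference site *i* is the fraction of
*j*'s blocks whose members all fall inside a single block of *i*.  Taxa
that are missing at the *reference* site are unconstrained: a block of
*j* is tested after restriction to the taxa actually scored at *i*
(equivalently, missing taxa belong to every reference block).  This
convention is what makes the anchor property hold exactly — a site with
at most one observed state is compatible with every other site and
receives a rate of exactly 1 — including on matrices with missing data.
A site with zero blocks (entirely missing) carries no grouping
information and neither constrains others nor is penalised itself.

The rate of site *i* is the mean agreement over all other sites.
Identical columns are collapsed to unique patterns with multiplicities,
so the pairwise sweep is O(U²·B) in the number of unique patterns U and
blocks B (≤ 4), with taxa held as 64-bit masks so each containment test
is a couple of bitwise operations.  Because every pairwise agreement is
a multiple of 1/12 (1–4 blocks), the per-site sum is accumulated as an
exact integer numerator and divided once at the end: the result is the
correctly rounded rational, independent of summation order, and
bit-identical to a naive brute-force implementation.

The original bin-based workflow of excluding the fastest bins is
deliberately not provided; rate files (one float per line, site order)
are the only output, feeding the span algorithm below.

## Rate-span partitioning

Given rates in [0, 1], the observed maximum `x` and minimum `y`, and a
division factor `d > 1`, boundaries are iterated as
`z = x − (x−y)/d` for the first span and `z = x − (x−y)/(d + 0.3 p)`
for span `p > 1`, the previous lower limit becoming the next upper
limit.  Iteration stops when fewer than 10% of sites remain
unassigned (checked after each span, so a scheme always has at least
one partition); the leftovers become the final, fastest partition.

Decisions the formulas leave open, fixed as follows:

- Membership is `z < r ≤ x`; the first span is closed at the top so
  maximum-rate sites are always captured.  Sites at exactly the
  minimum rate are therefore reachable only through the remainder rule.
- Degenerate input (all rates equal) returns a single partition rather
  than iterating on a zero-width range.
- Termination guards: if the remaining range drops below 1e−12, or 50
  consecutive spans capture no site, all remaining sites are dumped
  into the final partition.  This guarantees halting when ≥ 10% of
  sites share the minimum rate.
- Spans that capture no sites are dropped from the output (downstream
  model fitters reject empty subsets) and the survivors renamed
  `p1..pk`, slowest to fastest.

Writers produce RAxML (`DNA, p1 = 1-3,7`), NEXUS `sets`-block
(`charset`) and PartitionFinder `[data_blocks]` dialects with maximal
range compression; a reader round-trips all three.  `d` is never chosen
automatically — the CLI supports scanning several values and reports
subset counts, nothing more.

## Sequence simulation

The benchmark simulates DNA on two fixed 17-leaf topologies (16
ingroup taxa plus an outgroup): a fully pectinate ladder and a fully
balanced tree, terminal branches 0.1 expected substitutions/site,
internal branches per condition.  An alignment is four concatenated
1,000-site blocks, each with its own model — base composition,
F81 or GTR exchangeabilities, proportion of invariant sites, gamma
shape and internal branch length per the built-in table of fourteen
conditions `S1..S14` (easy: long internals; hard: 0.001 internals
and/or extreme among-site rate variation; odd-numbered conditions have
no invariant sites, even-numbered ones add per-block P-inv of
0.80/0.60/0.40/0.20; two conditions vary gamma shape per block, two
vary internal branch length per block).

Mechanics: the GTR rate matrix is normalised to one expected
substitution per unit branch length at stationarity; root states are
drawn from the stationary frequencies; a site is invariant with
probability `p_inv`, otherwise it gets a *continuous* gamma(α, mean 1)
rate multiplier (no renormalisation of the non-invariant sites —
standard I+Γ simulation); states evolve down the tree with per-site
transition matrices from the eigendecomposition of the symmetrised
rate matrix.  All randomness flows through `numpy` `SeedSequence`
spawning, so each block of each replicate is reproducible in
isolation.

Missing data mimics a locus absent for some taxa: each of three
randomly chosen non-outgroup taxa has one randomly chosen 1,000-site
block replaced by `?`.  Blocks are drawn independently per taxon by
default (a flag selects one shared block instead); the outgroup is
excluded so the unrooted comparison never loses its reference.

What the simulator does *not* emulate: indels and alignment error,
codon structure, non-stationary composition, linkage between sites.
Benchmarks passing here show the partitioning machinery behaves under
controlled heterogeneity; they do not certify behaviour on real data
with those complications.

## Likelihood engine and tree inference

The pruning likelihood supports GTR with four discrete gamma
categories (mean of equal-probability quantile slices) and optionally
a proportion of invariant sites; missing or ambiguous tips integrate
over all four bases.  Site patterns are compressed per subset; partial
likelihoods are rescaled per node with per-pattern log accumulators.
Under a partition scheme all subsets share the topology and branch
lengths; each subset has its own substitution model plus a
multiplicative rate scale (the first subset's scale is fixed to 1),
the linked-branch-lengths convention of partitioned ML programs.

Because the models are time-reversible, the engine caches directional
messages on every edge; the likelihood restricted to a single branch
then costs O(patterns), which makes branch-length optimisation
(Brent per edge, cycled with message refreshes and a halving
safeguard against overshoot) and nearest-neighbour-interchange
scoring cheap.  The built-in tree search starts from a JC-distance
neighbour-joining tree, fits per-subset models (empirical base
frequencies held fixed during search — the usual fast setting), and
hill-climbs: all 28 NNI candidates are scored with the focal branch
re-optimised and everything else held, the best is applied, branch
lengths re-optimised, until no candidate improves.  If the topology
moved, models are refitted once and the search repeated; then two
ratchet cycles perturb the best tree with four random NNIs
(deterministically seeded) and climb again, keeping the best tree by
likelihood — cheap insurance against local optima on near-star trees.
Adapters with the same `infer(alignment, scheme)` contract drive
FastTree (no partition support — cross-checks only), RAxML and
IQ-TREE when those binaries are available; a pure distance-NJ backend
exists for smoke tests.

## Robinson–Foulds scoring

Distances are symmetric differences of non-trivial bipartitions,
treating trees as unrooted; the normalised form divides by 2(n−3).
Benchmark tables report the raw count (0–28 for 17 taxa) — on these
tree sizes raw counts are the informative scale, and both forms are
always available.  Replicate summaries are arithmetic means and sample
standard deviations.

## BIC scheme scoring

Schemes are compared on a fixed, user-supplied topology:
`BIC = −2 lnL + K ln N` with N the total site count.  Per subset the
fit maximises 5 exchangeabilities, 3 free base frequencies and the
gamma shape (L-BFGS-B on log/softmax-transformed parameters,
convergence 1e−6 in lnL at default settings); K adds one rate scale
per subset after the first and the 2n−3 shared branch lengths once.
A subset with no variable sites leaves the gamma shape unidentifiable;
the fit is flagged rather than failed.  The scorer is deliberately a
desk-scale tool for *ordering* candidate schemes — its absolute values
are not comparable to other programs' BIC numbers, which differ in
search strategy and parameter conventions.  The discrete-gamma
likelihood is also knowingly asymmetric to the simulator's continuous
gamma; that mismatch is shared by all schemes being compared.

## Benchmark design and problem sizes

The benchmark pipeline simulates replicates per condition and shape,
partitions each replicate by the true simulated blocks ("4part") and
by TIGER rates + rate-spans ("tiger", division factor 4.0 — the upper
range that BIC comparisons on empirical data favour), infers an ML
tree per strategy and reports raw RF to the generating topology.  The
default is 10 replicates per condition.  The acceptance script runs
the hard condition S5, the missing-data condition S2 and the
symmetric-tree S6 at 10 replicates, and the full 14-condition
asymmetric sweep at 3 replicates per condition (a scaled-down version
of the full design chosen to keep a complete from-scratch rerun around
fifteen minutes on one CPU); the test suite uses 2 replicates for the
sweep.  Tree inference for benchmark numbers always uses the built-in
partitioned search, the only backend that both honours partition
schemes and requires no external program.

## Known limitations

- DNA only; the rate machinery generalises to amino acids and
  morphology but is not exercised here.
- The NNI+ratchet search is weaker than SPR-based searches of
  dedicated ML programs on rugged landscapes; benchmark RF means on
  the hardest conditions (internal branches of 0.001) can sit slightly
  above what a stronger search would give.
- No automatic choice of the division factor `d`.
- BIC scoring fixes topology and branch lengths (up to per-subset
  scales); it does not re-estimate trees per scheme.
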