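# Methods

## The problem

Genus-level morphological matrices for fossil-rich radiations combine
discrete anatomical characters (some with a natural linear ordering), a
minority of continuous measurements, very high levels of homoplasy, and
taxa scored for only a fraction of characters. Unconstrained parsimony on
such data routinely contradicts well-corroborated molecular relationships
among the living members. The workflow implemented here addresses that by
(i) putting all character kinds on a common cost scale through range
normalisation, (ii) restricting tree search with a molecular backbone
("scaffold") over designated taxa while letting all fossils float, and
(iii) quantifying the outcome with strict consensus, relative Bremer
support over near-optimal tree pools, Templeton's topology tests, ensemble
homoplasy indices and synapomorphy lists.

## Data model

A `CharacterMatrix` is a taxa × characters grid of cells. Each character is
unordered (uniform cost 1 between distinct states), ordered (linear cost
|i − j|) or continuous (linear cost |x − y| on reals). Cells are single
states, polymorphic state sets, finite real values, missing (`?`) or
inapplicable (`-`). Inapplicable is stored distinctly but scored exactly
like missing: no published convention for inapplicable-aware costing is
assumed, and the distinction is preserved only for round-tripping files.
Continuous cell values are taken as supplied (per-taxon means computed
upstream of the matrix); the package never aggregates specimens.

## Range-normalised weighting

For every active character the observed range — over non-missing cells,
with polymorphic cells contributing both their extreme states — defines the
weight:

- continuous: `w = 1/(max − min)`; spanning the full observed range then
  costs exactly one weighted step;
- ordered: `w = 1/(max state − min state)` over *observed* states (a
  character scored only as 1 and 3 has range 2 regardless of how many
  states were defined), so a three-state 0–2 character weighs 0.5;
- unordered and binary: weight 1 (no normalisation is needed);
- zero-range (invariant) characters are deactivated with reason
  `invariant` and excluded from every scoring sum.

Weighting depends only on observed cells, hence is idempotent.

`discretize_continuous` produces the "traditionally discrete" matrix
variant: equal-width half-open bins `[lo + k·w, lo + (k+1)·w)` over the
observed range, last bin closed, giving ordered states `0..n_bins−1`
(default 4 bins). The binning scheme used by the original analyses of such
data is generally unreported; equal-width binning is the simplest
reproducible default and is isolated in this one function.

## Parsimony scoring

Unordered characters are scored by uniform-cost Sankoff dynamic
programming (equivalent to Fitch on binary trees, exact on polytomies,
and polymorphic terminals may realise any member state at zero cost).
Ordered and continuous characters share a linear-cost DP over a finite
candidate grid: declared states for ordered characters, the sorted observed
leaf values for continuous ones. For L1 costs the optimum of the Steiner
problem on a tree is always attained at input values, so the restriction is
exact; the per-node transition `min_t D(t) + |v_s − v_t|` is computed in
O(K) by forward/backward sweeps. Ordered polymorphic terminals are treated
as the interval `[min state, max state]`; missing cells are unconstrained.
Both DPs sum over all children of a node, so consensus trees with
polytomies are scored exactly rather than arbitrarily resolved. Equality of
weighted lengths is judged at an absolute tolerance of 1e-9 throughout.

Per-character bounds: the minimum over all trees is (number of required
states − 1) for unordered characters (polymorphic cells resolved
cheaply — computed as a minimum hitting set over the small state alphabet)
and the shortest spanning range for ordered/continuous; the maximum is the
star-tree cost, found exactly by evaluating every candidate centre state or
value. CI = Σmin/Σsteps and RI = (Σmax − Σsteps)/(Σmax − Σmin) sum over
active, parsimony-informative characters (max > min); characters that
cannot vary in cost are excluded from both indices.

## Constrained search

A `ConstraintScaffold` is a (possibly polytomous) backbone tree over the
non-floater taxa plus the set of floaters and an ordered outgroup list. A
tree is admissible iff its restriction to the non-floaters displays every
non-trivial backbone split; backbone polytomies may be resolved freely and
floaters attach anywhere. Search is multi-start: seeded random-addition
order, each taxon inserted at the admissible edge of least length increase
(ties broken by canonical edge order for determinism), followed by
hill-climbing that sweeps SPR rearrangements until no improvement and then
TBR (which subsumes SPR by re-rooting the pruned subtree); every admissible
tree encountered within epsilon of the incumbent best is pooled, and a
final closure sweep expands the pool through rearrangements that stay
within the bound, so co-optimal trees connected through the near-optimal
landscape are all collected. Pools are de-duplicated by canonical
bipartition sets and capped (default 99999, matching common practice for
suboptimal-tree collection); hitting the cap flags the ensemble truncated
rather than failing. `collect_suboptimal` repeats the closure at an
increasing epsilon schedule. TNT's "New Technology" machinery (sectorial
searches, drift, tree fusing) is deliberately out of scope: multi-start
random addition with SPR/TBR is sufficient for the problem sizes the
package targets and is fully reproducible from a single seed.

Reports are rooted by placing the first sequential outgroup as sister to
the rest; search itself is unrooted.

## Relative Bremer support

For each non-trivial clade K of a reference tree and a pool of trees:
S = number of pool trees displaying K, C = number containing a split
incompatible with K (four-point condition). Support =
`100·(S − C)/max(S, C)`. This is the unique simple ratio consistent with
the three anchor cases that define the statistic verbally: clades in every
tree score 100, clades contradicted by every tree score −100, and clades
contradicted half as often as supported score 50. Trees that neither
display nor contradict (possible for polytomous pool members) count in
neither tally; if both counts are zero the support is reported as 0. Clades
with support ≤ 0 are collapsed in the reported consensus. Note the classic
step-difference formulation of relative Bremer support differs; the
tree-count reading implemented here follows the verbal definition above.

Rogue taxa: greedily remove the taxon whose deletion most increases the
number of strict-consensus splits (ties alphabetical), up to `max_prune` or
until no removal helps; supports are then recomputed on the reduced pool.

## Templeton's test

Per active character, `d_c` = weighted steps on tree B − weighted steps on
tree A. Zero differences (|d| ≤ 1e-9) are dropped; |d| values are ranked
with mid-ranks for ties; W is the smaller signed-rank sum. For n ≤ 20 the
two-tailed p comes from the exact distribution of the rank sum over all 2^n
sign patterns (computed via the generating function of doubled ranks, so
tied mid-ranks are handled exactly); otherwise the tie-corrected normal
approximation is used, without continuity correction. Continuous characters
participate with real-valued differences. Identical topologies give n = 0
and p = 1 by construction.

## Ancestral states and synapomorphies

On a binary rooted tree (root by outgroup first), marginal MPR sets are
computed per character by a down-pass of DP cost vectors and an up-pass
that adds each node's outside-subtree cost; a state or value belongs to the
MPR set iff some minimum-cost reconstruction attains it at that node. For
linear-cost characters the optimal set is an interval and is reported by
its endpoints on the candidate grid. A character is an unambiguous
synapomorphy of a clade when the MPR sets of the clade's ancestor and of
its parent node are disjoint; overlapping but unequal sets are reported as
ambiguous changes. Polytomous inputs are rejected (reconstruct on a binary
MPT). Over an ensemble, a synapomorphy is "consistent" only if unambiguous
on every tree.

## Synthetic data

The generator evolves characters along a model tree with per-edge lengths:
unordered characters under the k-state symmetric Markov process (stay
probability `1/k + (1−1/k)·exp(−k·r·t/(k−1))`), ordered characters under a
±1 stepwise walk with Poisson(r·t) events reflected at the terminal states,
continuous characters under Brownian motion with scale `bm_sigma·√t`. Root
states are uniform (BM starts at 0; parsimony scores are
translation-invariant). Cells are masked missing independently at
`missing_rate`, optionally amplified on designated fossil-like taxa
(missingness is otherwise completely at random — real fossil missingness is
block-structured by anatomical region, which the generator does not
model). `make_scaffold` restricts the true tree to chosen non-floaters and
collapses a seeded fraction of internal edges, emulating a molecular
backbone with regions of uncertainty. The study-shaped preset mirrors a
large Paleocene placental matrix: 177 taxa; 680 characters split 480
unordered / 152 ordered / 48 continuous (the ~7% continuous fraction of
the study; the ordered/unordered split within the discrete block is not
reported anywhere and is set at roughly a quarter ordered); three
sequential outgroups; a backbone over 18 extant-like taxa; high rate and
heavy, fossil-concentrated missingness.

Because characters are i.i.d. given the tree and missingness is (at most)
taxon-correlated, passing recovery tests demonstrates the correctness and
calibration of the implementation — not that parsimony with these settings
would recover real placental relationships, where characters are
correlated, missingness is structured, and rates vary across lineages.

### The recovery benchmark

Topology-recovery experiments use a fixed eight-taxon balanced tree with
internal edges 0.45 and terminal edges 0.2, 200 characters in study-shaped
proportions (146 unordered / 40 ordered / 14 continuous, k = 3), rate 0.5
and 30% missing data. The internal edges are set longer than terminals so
that each split retains an expected number of scored supporting characters
well above the homoplasy noise floor: with equal branch lengths a few
percent of replicates yield a *genuinely* shorter wrong tree (a property of
the data, verified by exhaustive enumeration, not of the search), which
would make the benchmark measure the statistical limits of parsimony rather
than the correctness of the implementation. Under these conditions the
search recovers the true topology essentially always, and a correct
partially collapsed scaffold never lowers mean recovery.

## File formats

TNT: an `xread` block with optional interleaved `&[cont]` / `&[num]`
sub-blocks, `ccode` statements (`+` ordered, `-` unordered, `]` inactive,
`/w` weight, 0-based indices with `a.b` ranges). The writer records
declared per-character state counts inside the title comment
(`mp-nstates: ...`), which TNT ignores but the reader recovers, making
round-trips lossless even when a declared state is unobserved. NEXUS: TAXA
plus STANDARD and CONTINUOUS CHARACTERS blocks and an ASSUMPTIONS block
(TYPESET/WTSET/EXSET, 1-based indices as NEXUS requires); the same lossless
metadata travels in square-bracket comments, which conforming NEXUS readers
skip. Newick via dendropy, with `[&key=value]` node comments for support
annotations. Character indices are 0-based internally; every report prints
1-based numbers.

## Pipeline

`morphparsimony run --config run.toml` executes a grid of analysis cells
named `CU`, `DM`, `CF`, `DP`, ... — first letter selects the data set
(Continuous-as-such vs Discretised), the rest a named constraint level
(`U` = unconstrained). Each cell writes weighting, tree, consensus, score
and support artefacts plus a JSON summary; failures abort only their own
cell. Across cells the pipeline writes a run summary table (analysis,
number of MPTs, best length, trees within one step, CI, RI) and pairwise
Templeton tables of representative MPTs under each data set. Cell seeds
derive deterministically from the run seed, and reruns reproduce all
TSV/JSON outputs byte for byte.

## Known limitations

- Inapplicable states are scored as missing; no Brazeau-style
  inapplicable-aware algorithm is provided.
- Relative Bremer uses the tree-count formulation (see above), not
  step differences.
- The search is heuristic; exactness is only guaranteed where the tests
  enumerate topologies (≤ 7 taxa).
- General step-matrix (Sankoff cost-matrix) characters, implied weighting,
  likelihood/Bayesian scoring and divergence-time estimation are out of
  scope.
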