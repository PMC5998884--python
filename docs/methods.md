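# Methods notes

## Reconciliation and the episode objective

A species tree S is rooted, binary, uniquely leaf-labeled and fixed.  Gene
trees are binary, leaf-labeled by species names (repeats allowed), rooted or
unrooted (every internal node of degree 3).  The lca mapping sends a gene
leaf to its species leaf and an internal node to the lca of its children's
images; a node is a duplication iff it maps to the same species node as one
of its children, and leaves and all other nodes are speciations.

Duplications cluster into episodes subject to two rules: members of one
episode share a species-tree location, and two *comparable* duplications of
the same family never share an episode (a duplication and its ancestor are
distinct events by construction).  The resulting objective is
MES(R, S) = Σ_v max_T duppath(T, v).  Minimising it over all scenarios with
the minimal per-family duplication count — and, for unrooted inputs, over
all duplication-cost-optimal rootings — gives the ME score.

## Rooted solver

Every duplication d gets the interval I(d) = ⟨M(d), s⟩ with s the child
(towards d) of the image of the lowest speciation strictly above d, or
root(S) if none exists.  The solver is a greedy bottom-up sweep over species
nodes: at node s it force-assigns every duplication whose interval top is s
(minimal levels, so the per-node episode count λ(s) equals the longest
forced chain), then pulls any still-unassigned duplication whose interval
covers s into a free level ≤ λ(s).  A pull never increases any λ and only
relaxes the constraints on the pulled duplication's ancestors, so it is
always safe; a pull is refused while the duplication still has unassigned
descendants, which would otherwise be trapped below their ancestor's slot.
Published pseudocode for this sweep is not reproduced here; the
implementation's contract is the definitional optimum, and the test suite
holds the greedy to an exhaustive oracle (`brute_force_rme`, capped at 8
duplications) on hundreds of randomized instances.

Determinism: species nodes are processed in post-order; forced duplications
and pull candidates are ordered by (interval-bottom depth, tree index,
gene-node post-order id), so within a tree descendants always precede their
ancestors and results are reproducible.

## Unrooted machinery

Per-directed-edge lca images are computed by memoised message passing in
O(|U|); the rooting cost of an edge is the sum of its two directed
duplication counts plus one unless the edge is *empty* (roots at a
speciation).  Edge classification (empty / single / double) compares images
against the **effective top** of the family — the lca of the species present
in U — rather than root(S), so families that do not span all species behave
exactly like full-span ones.  Duplication intervals still use root(S) as the
global ceiling, so episodes may be placed above the family's span where the
model allows it.

The plateau (argmin edge set) is computed from those counts; on every tested
instance it is connected and carries exactly one empty edge or at least one
double edge, and node roles (super-speciation at plateau leaves,
super-duplication at internal nodes off the empty edge, conditional on the
empty edge) are validated against every optimal rooting in the test suite.

∼-classes are built structurally: no empty edge → one class; otherwise the
empty edge is a plain singleton and each plateau single edge of an S2 star
(star around an empty-edge endpoint) defines one complex class consisting of
that edge plus all plateau edges beyond it.  The structural partition is
checked against the definitional one (equality of speciation frontiers of
the rootings) on every randomized instance.  Note that the frontier of the
empty-edge rooting is the set of *all* plateau leaves, which includes leaf
nodes of the gene tree itself (leaves are speciations).

Decomposing a complex class X detaches the maximal subtrees hanging off the
skeleton's leaves and replaces each by a fresh species-tree copy rooted at
the subtree's lca image.  Padding nodes carry `("pad", i, node)` provenance
tags so episode reports can always tell real gene nodes from copies.  The
reduced tree may degenerate to a single edge between two padded subtrees;
the container accepts that internally while parsed input is validated
strictly.

## Solvers and their contracts

* `naive_ume`: product over all plateau rootings (default cap 10⁴
  combinations); the oracle for everything else.
* `exact_ume`: product over ∼-classes (cap 10⁵).  For each combination the
  rooted inputs, plain-class rootings and detached subtrees form a rooted
  background; each complex class contributes its best reduced-tree rooting.
  Best rootings are found per tree (gnaw = one rooted solve per class edge)
  and combined in a single final scoring run.  This separation is exact when
  every background tree has a speciation root: the reduced trees'
  duplications all carry intervals topping at root(S), so across trees they
  interact only through the shared root-level episode count, a maximum that
  is minimised coordinate-wise.  When several complex classes meet a
  duplication-rooted *rooted input* (possible only in mixed rooted/unrooted
  instances) the solver falls back to the definitional product over class
  edges within the same budget.
* `lower_bound`: multi-class trees contribute only the subtrees hanging off
  their plateau leaves (identical, with identical intervals, in every
  optimal rooting — their roots are super-speciations), so dropping the
  plateau duplications can only lower the optimum; single-class trees are
  incorporated in full.  Linear-time apart from the final scoring run.
* `upper_bound`: per tree the largest class (ties: plain first, then class
  order), rootings chosen by gnaw against the accumulated background — one
  feasible combination, hence an upper bound.
* `heuristic_ume`: bounds first (equal bounds certify the upper-bound
  combination as optimal); otherwise exact enumeration when at most
  `k_budget` (default 7) multi-class trees; otherwise a greedy that commits,
  among all remaining (tree, class) pairs, the one whose best rooting adds
  the fewest episodes to the current background capacity, and finally takes
  the better of the greedy result and the upper bound, so the reported score
  always lies in [lower, upper].

Incremental evaluations against a fixed background reuse the rooted solver
with pre-seeded per-node capacities (`base_lambdas`); only levels beyond the
base are charged.  The committed-background updates make the bounds and the
greedy linear per candidate edge; the final reported score and episodes
always come from one full joint scoring run over the chosen rootings.

## DLS scenarios

The scenario grammar has gene leaves (`a`), loss leaves (`A-`), duplications
(`(R1,R2)+`, equal child species sets) and speciations (`(R1,R2)~`, disjoint
sets); both the ASCII tilde and the typographic `∼` are accepted, and the
writer re-emits the glyph seen at parse time so round trips are bit-stable.
Loss-set tokens are concatenated single-character names by default, with an
optional delimiter for real species names.  `gt` extracts the observable
gene tree (prune losses, contract unary nodes); `mes_of_scenarios` scores
explicit scenario sets directly from the definition.

## Simulator

Families evolve top-down along S: a lineage arriving at a node duplicates
with probability `dup_prob` (each copy re-arrives and may duplicate again);
at an internal node the surviving lineage speciates, each child lost with
probability `loss_prob`; at a leaf it becomes a gene sequence.  An injected
episode (species node, participation probability) forces one duplication in
the first lineage of each participating family to reach that node.  Defaults
— `dup_prob = 0.1`, `loss_prob = 0.1`, 100 families — were chosen once as a
realistic regime: most gene trees resemble the species tree with occasional
small paralogous clades, which is where episode inference is informative.

What the simulator does *not* emulate: continuous-time birth–death rates
(events are per-branch Bernoulli draws), sequence evolution and gene-tree
estimation error, horizontal transfer, and lineage-specific rate variation.
Passing the episode-recovery tests therefore shows the solvers recover
signal that is present in correctly inferred topologies; it says nothing
about robustness to reconstruction artifacts in real data.

Families whose gene tree has fewer than three leaves are resampled (the
unrooted form needs three); irrecoverably degenerate settings (e.g. two
species with zero duplication rate) error out after `max_retries` attempts.
One `random.Random(seed)` stream drives a run, so equal seeds give equal
output.

## Numerical / degenerate-input choices

* Ties in plateau edges need no breaking (the plateau is a set); edges are
  reported as (min node id, max node id) pairs, classes plain-first then by
  defining-edge id, so all enumeration orders are reproducible.
* Rooted gene trees pass through the unrooted solvers unchanged (their root
  is data).  Empty inputs score 0 with a warning.
* Unrooted parsing accepts a top-level trifurcation or a rooted binary
  string (root dissolved); fewer than three leaves, multifurcations and
  duplicate species-tree labels are rejected at parse time.
* Gene→species resolution: exact label match by default, with a
  suffix-separator mode (`GENE_SPECIES`) and an explicit two-column mapping
  file for real datasets.

## Test and acceptance problem sizes

Randomized suites use species trees of 2–6 species and gene trees of up to
12 leaves: 300+ rooted instances against the brute-force assignment oracle
(≤ 8 duplications), 200+ unrooted instances against the naive rooting
product, 500 instances for the plateau/class structural laws, and 120 for
the bound sandwich.  These sizes keep the exhaustive oracles exact and the
default suite fast; the solvers themselves are routinely run on hundreds to
thousands of simulated families (see the CLI smoke test at 200 families).

## Known limitations

* The exact solver's enumeration is exponential in the number of multi-class
  trees (k); that is inherent to the class product, and the heuristic is the
  intended tool for large k.  The heuristic's greedy phase is quadratic.
* The episode model allows any placement inside the duplication intervals;
  alternative interval models are out of scope.
* Only the duplication cost defines the plateau; loss-aware or
  deep-coalescence plateaus are not implemented.
* Species trees must be binary; non-binary species trees are rejected rather
  than resolved.
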