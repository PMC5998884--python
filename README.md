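# ume — duplication episodes from unrooted gene trees

`ume` infers **genomic duplication episodes** — bursts of gene duplications,
up to whole-genome duplications, that hit many gene families at once — by
reconciling a collection of gene trees with a species tree.  It solves the
*minimum episodes* (ME) problem when the gene trees are **unrooted**, the
usual situation for trees built from sequence data, where the root is an
artifact of the inference rather than an observation.  It is aimed at
phylogenomics practitioners who have a species tree, a pile of per-family
gene trees in newick, and want to know where in the species tree the large
duplication events sit.

## The model

A gene-tree node maps to the species tree by the **lca mapping** M; a node
`g` is a **duplication** when M(g) equals the image of one of its children,
and the duplication cost D(T, S) counts those nodes.  Each duplication `d`
may be placed anywhere on a species-tree interval
I(d) = ⟨M(d), s⟩, where `s` is the child (towards `d`) of the image of the
lowest speciation above `d` (the root of S if there is none).  For a set of
scenarios **R** the episode count is

    MES(R, S) = Σ_{v ∈ V(S)} max_{T ∈ R} duppath(T, v),

with duppath(T, v) the longest chain of comparable duplications of T placed
at v — incomparable duplications, and duplications of different families,
placed at the same node share an episode.  The ME score minimises MES over
all scenarios that keep every family's duplication count minimal.

For an unrooted gene tree U only the cost-minimising rooting edges — the
**plateau** U\*, always a connected subtree — are allowed.  Plateau edges
fall into 1, 3 or 5 **∼-classes** (edges whose rootings share the same set of
maximal non-root speciations).  Each class can be **decomposed**: the maximal
subtrees hanging off the class skeleton are detached (their roots are
speciations in every rooting of the class) and replaced by species-tree
copies, leaving a reduced unrooted tree whose best rooting is found by a
single sweep (*gnaw*).  An instance with k multi-class trees therefore needs
at most 5^k simple rooted computations instead of a product over all plateau
rootings.

Solvers: `exact_ume` (class enumeration), `naive_ume` (exhaustive oracle),
`lower_bound` / `upper_bound` (linear-time sandwich), and `heuristic_ume`,
which certifies exactness whenever the bounds meet and otherwise commits
tree/class pairs greedily by incremental episode cost.  A rooted-input solver
(`rme_score`, with a brute-force oracle), a DLS evolutionary-scenario module
(parser, gene-tree extraction `gt`, direct MES scoring) and a duplication–
loss simulator with injectable episodes round out the package.

## Worked example

The five-species tree `S = (((a,b),(c,d)),e)` and the nine-leaf unrooted
gene tree `U = (d,e,(c,(((a,b),b),((c,d),d))))`:

```sh
printf '(((a,b),(c,d)),e);\n' > species.nwk
printf '(d,e,(c,(((a,b),b),((c,d),d))));\n' > genetrees.nwk
ume score species.nwk genetrees.nwk --method heuristic
```

prints (episodes truncated here):

```json
{
  "score": 4,
  "method": "heuristic",
  "exact": true,
  "lower_bound": 2,
  "upper_bound": 4,
  "trees": [
    {"index": 0, "kind": "plain", "class": "empty", "rooting_edge": [1, 15]}
  ],
  "episode_counts": {"ab": 1, "cd": 1, "abcd": 2},
  "episodes": [
    {"species_cluster": "ab", "level": 1, "members": [{"tree": 0, "node": 7}]},
    {"species_cluster": "cd", "level": 1, "members": [{"tree": 0, "node": 12}]}
  ]
}
```

Reading: the best rooting of U costs four duplications, and those four
duplications need **4 episodes** — one at the ancestor of {a,b}, one at the
ancestor of {c,d}, and a stack of two at the ancestor of {a,b,c,d} (two
comparable duplications of one family can never share an episode).  The
bounds bracketed the score and the class enumeration certified it
(`"exact": true`; the CLI exits 0 for certified results, 2 for bounds).
`ume plateau` shows the five optimal rooting edges of U (one *empty*, four
*single*), and `ume decompose` its three ∼-classes of sizes 1, 1 and 3.

Simulating families with an injected episode and recovering it:

```sh
ume simulate species.nwk --families 50 --dup-rate 0 --loss-rate 0 \
    --episode ab:1.0 --seed 9 -p sim
ume score species.nwk sim.unrooted.nwk --method exact
```

reports `"score": 1` with a single episode at cluster `ab` carrying all 50
families.

## Layout

| module | contents |
|---|---|
| `ume.trees` | species / rooted / unrooted tree containers, newick I/O, rooting |
| `ume.reconcile` | lca mapping, duplication cost, per-edge maps, plateau, edge types, node roles |
| `ume.decompose` | speciation frontiers, ∼-classes, Δ(U, X) and the reduced tree U^X |
| `ume.rooted_me` | duplication intervals, greedy rooted ME solver, brute-force oracle |
| `ume.unrooted_me` | gnaw, exact/naive solvers, bounds, heuristic |
| `ume.dls` | DLS scenario grammar, `gt`, direct MES scoring |
| `ume.simulate` | duplication–loss simulator with injectable episodes; random tree generators |
| `ume.cli` | `ume score / episodes / plateau / decompose / mes-scenarios / simulate` |

See `docs/methods.md` for the modelling notes, parameter defaults and known
limitations.
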