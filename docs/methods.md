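# Methods

## The model

A gene network is an undirected simple graph over gene identifiers.
Each gene carries a *candidate set* of GO terms: the union, deduplicated
and sorted, of the annotations of all its gene products, restricted to
one GO namespace per run.  The method selects exactly one term per gene
so that the network is maximally cohesive, then reports the residual
dissimilarity.

Two modelling commitments are worth stating explicitly:

* **One term per gene, not per product.**  Annotations are attached to
  gene products, and one could instead select a term per product and
  aggregate.  We select at the gene level because the result we want to
  report — and the result a user inspects — is one function per network
  node.  The per-product route would need an extra aggregation rule
  with no obvious canonical choice.
* **Unannotated genes are excluded, not penalised.**  A gene with no
  candidate terms cannot be assigned a function; its edges carry no
  information about functional cohesion either way.  Excluding them (and
  reporting them loudly in the result and the gene report) keeps the
  score a statement about the evidence present, at the cost of
  optimistically ignoring missing evidence.  The alternative — weighting
  such edges 1 — would conflate "not cohesive" with "not annotated".

## Edge dissimilarity

Term depth is the number of edges on the **longest** `is_a` path from
the namespace root; the longest-path convention guarantees every child
is strictly deeper than each parent, so depth is a monotone specificity
proxy.  Only `is_a` edges are used; `part_of` and `regulates` cross
sub-hierarchies and are deliberately ignored.

The deepest common ancestor (DCA) of two terms is the element of maximal
depth in the intersection of their reflexive ancestor sets; depth ties
break to the smallest accession so the query is deterministic.  The
default edge measure is the Wu–Palmer-style distance

    d(t1, t2) = 1 − 2·depth(DCA) / (depth(t1) + depth(t2)),

which is 0 iff the terms are identical, 1 when they meet only at the
root, symmetric, and bounded in [0, 1].  The degenerate root/root pair
(depth sum 0) is defined as 0, since with one root per namespace the
terms are then identical.  The measure sits behind a registry
(`gfdnet.ontology.MEASURES`), so an alternative pairwise distance can be
plugged in without touching the search: path-length-based distances, or
a measure that also accounts for the distance from each gene's other
annotations to the selected term, are natural candidates, and published
score values obtained with an unknown measure cannot be compared across
measures.  All depths are integers, so the default measure yields exact
rationals; the search runs on `fractions.Fraction` throughout and floats
appear only in reports.

## The search

The objective is the unweighted arithmetic mean of edge weights under an
assignment, minimised over the product of candidate sets.  Ties break
first to the larger total depth of selected terms (a more specific
shared function wins), then to the lexicographically smallest accession
tuple in sorted-gene order, making every strategy deterministic.

* **Exhaustive** enumeration is the reference; it refuses to run beyond
  a combination cap (default 10^7, matching a few minutes of work).
* **Branch and bound** fixes the gene order (sorted), accumulates the
  weight sum of fully-assigned edges, and abandons a partial assignment
  as soon as that sum strictly exceeds the best complete sum.  Weights
  are non-negative, so the pruned subtree cannot contain a better
  optimum; pruning only on *strict* excess preserves the depth and
  lexicographic tie-breaks, so the returned assignment — not just its
  objective — equals the exhaustive one.  With exact rational weights
  this equality is literal, not within float tolerance.
* **Greedy** coordinate descent initialises each gene at its deepest
  candidate and sweeps genes in sorted order, re-selecting each gene's
  term to minimise its incident edge weight sum, until a sweep changes
  nothing or `max_sweeps` (default 20) is hit.  Each re-selection only
  lowers the total, so termination is guaranteed; the result is an upper
  bound on the optimum and is used by `auto` mode past the cap.

Pairwise dissimilarities and DCA queries are memoised for the duration
of a run; candidate sets are deduplicated sorted tuples.  Both are
behavioural contracts (idempotence, determinism) as much as performance
choices.

Connected components of the scorable subgraph are scored separately
(mean of that component's edge weights) alongside the global mean, so a
network that splits into a cohesive and a divergent sub-network is
visible in the breakdown.  The global score is reported as the mean over
*all* scorable edges — equivalently the edge-count-weighted mean of the
component scores — not the mean of component means.

## Synthetic data

The generator exists so the entire pipeline is testable offline.
`random_dag` grows a rooted DAG: term *i* draws 1..`max_parents`
(default 3) parents uniformly from earlier terms, guaranteeing
acyclicity and a single root.  `cohesive_annotations` picks a focal term
of maximal depth and fills each annotation slot with it with probability
`cohesion`, otherwise with a uniform draw over all terms.  Defaults — 40
terms, 8 genes, 2 products per gene, 3 terms per product — keep the
exact searches instant while leaving room for non-trivial candidate
sets.  All draws derive from one seed through fixed-offset substreams,
so every generated object, including its file serialisation, is a pure
function of the configuration.

What the generator does *not* emulate: the real GO's size (tens of
thousands of terms), its skewed branching and depth distribution,
evidence-code structure, annotation biases toward well-studied genes,
and `part_of`/`regulates` relations.  Passing tests therefore establish
the correctness of the machinery (search optimality, normalisation,
determinism, recovery of a planted signal) — not that any particular
score value on real GO data is "right".  Scores on real data also
depend on the GO release and annotation source used, so absolute values
are comparable only within one configuration.

Problem sizes in the test-suite and the reproduction script — 120
random oracle instances of ≤6 genes with ≤4 candidates each, 200
replicates per cohesion level — were chosen so exhaustive enumeration
stays an honest oracle and the full suite completes in well under a
minute of search time.

## Numerical and degenerate cases

* Exact rational arithmetic end to end; no tolerance constants exist.
* A network with no annotated edge raises a no-scorable-edges error
  rather than returning a vacuous score; a mean over zero edges is
  undefined, not 0.
* Isolated annotated nodes survive in the scorable subgraph but join no
  component average and get no selected term (they are reported as
  `unscored`).
* Obsolete terms, cross-namespace `is_a` edges, unknown accessions in
  annotation files, duplicate edges and self-loops are dropped with
  logged counts, never errors; malformed rows (wrong column counts) are
  errors naming the file and line.

## Known limitations

* The arithmetic mean treats all edges equally; hub edges are not
  down-weighted, so a single promiscuous gene can dominate small
  networks.
* Greedy descent has no optimality guarantee; its observed mean gap on
  random instances is small (reported by `scripts/acceptance.py`) but
  adversarial instances can make it worse.
* One namespace per run; signals split across biological process and
  molecular function are invisible to a single score.
* Candidate sets are taken as given: no evidence weighting beyond the
  optional IEA exclusion, no propagation of annotations to ancestors
  before selection.
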