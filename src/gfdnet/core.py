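"""Cohesive GO-term assignment and network functional dissimilarity.

Given a gene network, an annotation store and a GO DAG, the method picks
**one** GO term per gene — out of each gene's candidate set — so that the
network as a whole is as functionally cohesive as possible: every edge is
weighted by the dissimilarity of the terms selected at its endpoints, and
the objective is the arithmetic mean of those edge weights.  The optimal
assignment minimises that mean; the minimised value is the network's
functional dissimilarity, a number in [0, 1] where 0 means all connected
genes share one specific function.

Three search strategies are provided:

* ``exhaustive`` — enumerate every combination of candidate terms
  (capped, default 10^7 combinations);
* ``branch_and_bound`` — same optimum and tie-breaks, pruning partial
  assignments whose accumulated edge-weight sum already exceeds the best
  complete sum;
* ``greedy`` — deterministic coordinate descent, an upper bound used
  when the combination space exceeds the cap.

Ties between equal-objective assignments break first to the larger total
depth of selected terms (more specific wins), then to the
lexicographically smallest accession tuple in sorted-gene order, so every
search is fully deterministic.  All edge weights are exact rationals
(:class:`~fractions.Fraction`) internally: exhaustive and
branch-and-bound agree *exactly*, never merely to float tolerance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

from .annotations import AnnotationStore
from .errors import (
    IncompleteAssignmentError,
    NoScorableEdgesError,
    SearchSpaceTooLargeError,
)
from .network import GeneNetwork
from .ontology import MEASURES, GODag

log = logging.getLogger(__name__)

DEFAULT_CAP = 10**7
DEFAULT_MAX_SWEEPS = 20


@dataclass
class Assignment:
    """One selected GO term per scorable gene."""

    selection: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> str:
        return self.selection[gene_id]

    def total_depth(self, dag: GODag) -> int:
        return sum(dag.depth[t] for t in self.selection.values())


@dataclass
class DissimilarityResult:
    """Full output of a scoring run.

    ``network_score`` is the arithmetic mean of ``edge_weights`` and
    equals the edge-count-weighted mean of the component scores; all
    values are exact rationals in [0, 1] (call :func:`float` to report).
    """

    network: GeneNetwork
    assignment: Assignment
    edge_weights: dict[tuple[str, str], Fraction]
    network_score: Fraction
    component_scores: list[tuple[frozenset[str], Fraction, int]]
    unannotated_genes: set[str]
    search_mode: str
    measure: str = "wu_palmer"


class _PairCache:
    """Memoised symmetric term-pair dissimilarity for one search run.

    Pairs met while exploring combinations recur constantly; caching them
    is the behavioural contract that keeps large searches tractable.
    """

    def __init__(self, dag: GODag, measure: str):
        self.dag = dag
        self.fn: Callable = MEASURES[measure]
        self.cache: dict[tuple[str, str], Fraction] = {}

    def __call__(self, t1: str, t2: str) -> Fraction:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self.cache.get(key)
        if hit is None:
            hit = Fraction(self.fn(self.dag, t1, t2))
            self.cache[key] = hit
        return hit


def scorable_subgraph(
    network: GeneNetwork, store: AnnotationStore
) -> tuple[GeneNetwork, set[str]]:
    """Restrict a network to genes with at least one candidate term.

    Returns the induced subgraph over annotated genes and the set of
    excluded (unannotated) genes.  Edges with an unannotated endpoint
    cannot be weighted and are excluded from scoring.
    """
    annotated = {g for g in network.nodes if store.candidates(g)}
    unannotated = network.nodes - annotated
    sub = network.subgraph(annotated)
    if sub.n_edges() == 0:
        raise NoScorableEdgesError(
            f"no scorable edges remain ({len(unannotated)} of "
            f"{network.n_nodes()} genes unannotated)"
        )
    return sub, unannotated


def objective(
    network: GeneNetwork,
    assignment: Assignment,
    dag: GODag,
    measure: str = "wu_palmer",
) -> Fraction:
    """Mean edge dissimilarity under an assignment (exact rational)."""
    weights = edge_weights(network, assignment, dag, measure)
    if not weights:
        raise NoScorableEdgesError("network has no edges to average over")
    return sum(weights.values(), Fraction(0)) / len(weights)


def edge_weights(
    network: GeneNetwork,
    assignment: Assignment,
    dag: GODag,
    measure: str = "wu_palmer",
) -> dict[tuple[str, str], Fraction]:
    """Per-edge dissimilarity of the selected endpoint terms."""
    pair = _PairCache(dag, measure)
    out: dict[tuple[str, str], Fraction] = {}
    for u, v in network.sorted_edges():
        if u not in assignment.selection or v not in assignment.selection:
            missing = u if u not in assignment.selection else v
            raise IncompleteAssignmentError(f"no selected term for gene {missing!r}")
        out[(u, v)] = pair(assignment[u], assignment[v])
    return out


def _search_genes(network: GeneNetwork, store: AnnotationStore) -> list[str]:
    """Scorable genes (incident to >=1 edge) in sorted order; validates candidates."""
    genes = sorted(g for g in network.nodes if network.graph.degree(g) > 0)
    for g in genes:
        if not store.candidates(g):
            raise IncompleteAssignmentError(
                f"gene {g!r} has an edge but no candidate terms; "
                "run scorable_subgraph first"
            )
    if not genes:
        raise NoScorableEdgesError("network has no edges")
    return genes


def search_space_size(network: GeneNetwork, store: AnnotationStore) -> int:
    """Number of candidate-term combinations the exhaustive search faces."""
    return math.prod(len(store.candidates(g)) for g in _search_genes(network, store))


def exhaustive_search(
    network: GeneNetwork,
    store: AnnotationStore,
    dag: GODag,
    measure: str = "wu_palmer",
    cap: int = DEFAULT_CAP,
    stats: dict | None = None,
) -> Assignment:
    """Enumerate all candidate combinations and return the optimum.

    Minimises the summed edge weight; ties break to larger total depth of
    the selected terms, then to the lexicographically smallest accession
    tuple in sorted-gene order.
    """
    genes = _search_genes(network, store)
    size = search_space_size(network, store)
    if size > cap:
        raise SearchSpaceTooLargeError(size, cap)
    candidates = [store.candidates(g) for g in genes]
    edges = [
        (genes.index(u), genes.index(v))
        for u, v in network.sorted_edges()
    ]
    pair = _PairCache(dag, measure)
    depths = dag.depth

    best_key = None
    best_combo = None
    visited = 0
    for combo in itertools.product(*candidates):
        visited += 1
        total = sum((pair(combo[i], combo[j]) for i, j in edges), Fraction(0))
        key = (total, -sum(depths[t] for t in combo), combo)
        if best_key is None or key < best_key:
            best_key = key
            best_combo = combo
    if stats is not None:
        stats["visited"] = visited
        stats["space"] = size
    return Assignment(dict(zip(genes, best_combo)))


def branch_and_bound_search(
    network: GeneNetwork,
    store: AnnotationStore,
    dag: GODag,
    measure: str = "wu_palmer",
    stats: dict | None = None,
) -> Assignment:
    """Depth-first search over candidate terms with cost-sum pruning.

    Genes are fixed in sorted order; a partial assignment is abandoned as
    soon as the weight sum of its fully-assigned edges strictly exceeds
    the best complete sum found.  Because edge weights are non-negative
    the pruned subtree cannot contain the optimum, and because pruning is
    strict the depth/lexicographic tie-breaks match
    :func:`exhaustive_search` exactly.
    """
    genes = _search_genes(network, store)
    index = {g: i for i, g in enumerate(genes)}
    candidates = [store.candidates(g) for g in genes]
    depths = dag.depth
    # edges grouped by their later endpoint: when gene i is assigned, the
    # edges to already-assigned genes become weighable
    back_edges: list[list[int]] = [[] for _ in genes]
    for u, v in network.sorted_edges():
        i, j = index[u], index[v]
        lo, hi = (i, j) if i < j else (j, i)
        back_edges[hi].append(lo)
    pair = _PairCache(dag, measure)

    n = len(genes)
    best_key: tuple | None = None
    best_combo: tuple | None = None
    combo: list[str] = [""] * n
    visited = 0

    def descend(i: int, partial: Fraction) -> None:
        nonlocal best_key, best_combo, visited
        if i == n:
            visited += 1
            full = tuple(combo)
            key = (partial, -sum(depths[t] for t in full), full)
            if best_key is None or key < best_key:
                best_key = key
                best_combo = full
            return
        for term in candidates[i]:
            combo[i] = term
            cost = partial
            for j in back_edges[i]:
                cost += pair(term, combo[j])
            if best_key is not None and cost > best_key[0]:
                continue  # every completion is strictly worse
            descend(i + 1, cost)

    descend(0, Fraction(0))
    if stats is not None:
        stats["visited"] = visited
        stats["space"] = math.prod(len(c) for c in candidates)
    return Assignment(dict(zip(genes, best_combo)))


def greedy_search(
    network: GeneNetwork,
    store: AnnotationStore,
    dag: GODag,
    measure: str = "wu_palmer",
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    stats: dict | None = None,
) -> Assignment:
    """Deterministic coordinate descent over per-gene term choices.

    Each gene starts at its deepest candidate (ties to the smallest
    accession).  Sweeps visit genes in sorted order and re-select the
    term minimising the summed weight of that gene's incident edges,
    with the same deeper-then-lexicographic tie-break; iteration stops
    when a full sweep changes nothing or after ``max_sweeps``.  The
    returned objective upper-bounds the optimum.
    """
    genes = _search_genes(network, store)
    pair = _PairCache(dag, measure)
    depths = dag.depth
    selection: dict[str, str] = {}
    for g in genes:
        cands = store.candidates(g)
        selection[g] = min(cands, key=lambda t: (-depths[t], t))

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed = False
        for g in genes:
            neighbors = [nb for nb in network.graph.neighbors(g) if nb in selection]

            def local_cost(term: str) -> Fraction:
                return sum((pair(term, selection[nb]) for nb in neighbors), Fraction(0))

            best = min(store.candidates(g), key=lambda t: (local_cost(t), -depths[t], t))
            if best != selection[g]:
                selection[g] = best
                changed = True
        if not changed:
            break
    if stats is not None:
        stats["sweeps"] = sweeps
    return Assignment(selection)


_SEARCHES = {
    "exhaustive": exhaustive_search,
    "branch_and_bound": branch_and_bound_search,
    "greedy": greedy_search,
}


def score(
    network: GeneNetwork,
    store: AnnotationStore,
    dag: GODag,
    mode: str = "auto",
    measure: str = "wu_palmer",
    cap: int = DEFAULT_CAP,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> DissimilarityResult:
    """Run the full pipeline and return a :class:`DissimilarityResult`.

    ``mode`` is one of ``exhaustive``, ``branch_and_bound``, ``greedy``
    or ``auto`` (branch-and-bound while the combination space is within
    ``cap``, greedy beyond it).  The network score is the mean weight
    over all scorable edges; each connected component of the scorable
    subgraph additionally gets its own mean, so heterogeneous
    sub-networks are visible in the breakdown.
    """
    if mode not in ("auto", *_SEARCHES):
        raise ValueError(f"unknown mode {mode!r}")
    scorable, unannotated = scorable_subgraph(network, store)

    if mode == "auto":
        space = search_space_size(scorable, store)
        mode = "branch_and_bound" if space <= cap else "greedy"
        log.info("auto mode: %d combinations -> %s", space, mode)

    if mode == "exhaustive":
        assignment = exhaustive_search(scorable, store, dag, measure, cap=cap)
    elif mode == "branch_and_bound":
        assignment = branch_and_bound_search(scorable, store, dag, measure)
    else:
        assignment = greedy_search(scorable, store, dag, measure, max_sweeps=max_sweeps)

    weights = edge_weights(scorable, assignment, dag, measure)
    network_score = sum(weights.values(), Fraction(0)) / len(weights)

    component_scores = []
    for comp in scorable.connected_components():
        comp_edges = [(u, v) for (u, v) in weights if u in comp]
        if not comp_edges:
            continue  # isolated annotated node: nothing to average
        comp_score = sum(
            (weights[e] for e in comp_edges), Fraction(0)
        ) / len(comp_edges)
        component_scores.append((frozenset(comp), comp_score, len(comp_edges)))

    return DissimilarityResult(
        network=network,
        assignment=assignment,
        edge_weights=weights,
        network_score=network_score,
        component_scores=component_scores,
        unannotated_genes=unannotated,
        search_mode=mode,
        measure=measure,
    )
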