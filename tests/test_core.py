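"""Cohesive-assignment searches and network scoring."""

from fractions import Fraction

import pytest

from gfdnet.core import (
    Assignment,
    branch_and_bound_search,
    exhaustive_search,
    greedy_search,
    objective,
    scorable_subgraph,
    score,
)
from gfdnet.errors import (
    IncompleteAssignmentError,
    NoScorableEdgesError,
    SearchSpaceTooLargeError,
)
from gfdnet.network import GeneNetwork
from gfdnet.synthetic import SynthConfig, cohesive_annotations, network_for, random_dag

from .conftest import A, B, C, R, make_dag, make_store


def random_instance(seed, n_genes=5, terms_per_product=3, n_terms=30):
    """A small random (network, store, dag) triple for oracle comparisons."""
    cfg = SynthConfig(n_terms=n_terms, max_parents=3, n_genes=n_genes,
                      products_per_gene=1, terms_per_product=terms_per_product,
                      cohesion=0.3, seed=seed)
    dag = random_dag(cfg)
    store, _ = cohesive_annotations(dag, cfg)
    net = network_for(cfg)
    return net, store, dag


class TestScorableSubgraph:
    def test_all_annotated_identity(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {B}})
        sub, unannotated = scorable_subgraph(net, store)
        assert sub.edges == net.edges
        assert unannotated == set()

    def test_triangle_with_unannotated_corner(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3"), ("g1", "g3")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {B}})
        sub, unannotated = scorable_subgraph(net, store)
        assert sub.edges == {frozenset({"g1", "g2"})}
        assert unannotated == {"g3"}

    def test_unannotated_hub_leaves_nothing(self, chain_dag):
        net = GeneNetwork(edges=[("hub", "g1"), ("hub", "g2"), ("hub", "g3")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {A}, "g3": {A}})
        with pytest.raises(NoScorableEdgesError):
            scorable_subgraph(net, store)


class TestObjective:
    def test_triangle_same_term_is_zero(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3"), ("g1", "g3")])
        assignment = Assignment({"g1": A, "g2": A, "g3": A})
        assert objective(net, assignment, chain_dag) == 0

    def test_chain_pair_value(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        assignment = Assignment({"g1": A, "g2": B})
        assert objective(net, assignment, chain_dag) == Fraction(1, 3)

    def test_mean_of_two_edges(self, chain_dag):
        # weights 1/3 (A,B on the chain) and 1 (R,B: dca R, 1-0/(0+2)=1)
        net = GeneNetwork(edges=[("g1", "g2"), ("g3", "g4")])
        assignment = Assignment({"g1": A, "g2": B, "g3": R, "g4": B})
        assert objective(net, assignment, chain_dag) == Fraction(2, 3)

    def test_missing_endpoint_errors(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        with pytest.raises(IncompleteAssignmentError, match="g2"):
            objective(net, Assignment({"g1": A}), chain_dag)


class TestExhaustiveSearch:
    def test_single_candidates_unique_assignment(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {B}})
        assignment = exhaustive_search(net, store, chain_dag)
        assert assignment.selection == {"g1": A, "g2": B}

    def test_shared_term_chosen_over_mismatch(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {A, B}})
        assignment = exhaustive_search(net, store, chain_dag)
        assert assignment.selection == {"g1": A, "g2": A}
        assert objective(net, assignment, chain_dag) == 0

    def test_shared_leaf_clique(self):
        # 4-clique; every gene carries the deep leaf C plus private decoys
        dag = make_dag({R: set(), A: {R}, B: {R}, C: {B},
                        "GO:0000005": {B}, "GO:0000006": {A}})
        genes = ["g1", "g2", "g3", "g4"]
        decoys = [A, "GO:0000005", "GO:0000006", B]
        net = GeneNetwork(edges=[(u, v) for i, u in enumerate(genes)
                                 for v in genes[i + 1:]])
        store = make_store(dag, {g: {C, d} for g, d in zip(genes, decoys)})
        assignment = exhaustive_search(net, store, dag)
        assert set(assignment.selection.values()) == {C}
        assert objective(net, assignment, dag) == 0

    def test_tie_breaks_prefer_deeper_terms(self, chain_dag):
        # R/R and B/B both give weight 0; B is deeper so must win
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {R, B}, "g2": {R, B}})
        assignment = exhaustive_search(net, store, chain_dag)
        assert assignment.selection == {"g1": B, "g2": B}

    def test_cap_enforced(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {R, A, B}, "g2": {R, A, B}})
        with pytest.raises(SearchSpaceTooLargeError):
            exhaustive_search(net, store, chain_dag, cap=8)


class TestBranchAndBound:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_on_random_instances(self, seed):
        net, store, dag = random_instance(seed)
        exh = exhaustive_search(net, store, dag)
        bnb = branch_and_bound_search(net, store, dag)
        assert objective(net, bnb, dag) == objective(net, exh, dag)
        # identical tie-breaks: the whole assignment matches, not just the value
        assert bnb.selection == exh.selection

    def test_single_candidates_identical(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {B}})
        assert (branch_and_bound_search(net, store, chain_dag).selection
                == exhaustive_search(net, store, chain_dag).selection)

    def test_pruning_skips_combinations(self):
        # first branch (lexicographic) is optimal; later branches get pruned
        dag = make_dag({R: set(), A: {R}, B: {R}, C: {A}})
        genes = ["g1", "g2", "g3", "g4"]
        net = GeneNetwork(edges=[(u, v) for i, u in enumerate(genes)
                                 for v in genes[i + 1:]])
        store = make_store(dag, {g: {A, B, C} for g in genes})
        stats = {}
        branch_and_bound_search(net, store, dag, stats=stats)
        assert stats["visited"] < stats["space"] == 3 ** 4


class TestGreedySearch:
    def test_single_candidates_identical(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2")])
        store = make_store(chain_dag, {"g1": {A}, "g2": {B}})
        assert (greedy_search(net, store, chain_dag).selection
                == exhaustive_search(net, store, chain_dag).selection)

    def test_shared_leaf_clique_reaches_optimum(self):
        dag = make_dag({R: set(), A: {R}, B: {R}, C: {B},
                        "GO:0000005": {B}, "GO:0000006": {A}})
        genes = ["g1", "g2", "g3", "g4"]
        decoys = [A, "GO:0000005", "GO:0000006", B]
        net = GeneNetwork(edges=[(u, v) for i, u in enumerate(genes)
                                 for v in genes[i + 1:]])
        store = make_store(dag, {g: {C, d} for g, d in zip(genes, decoys)})
        assignment = greedy_search(net, store, dag)
        assert objective(net, assignment, dag) == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_never_beats_exhaustive(self, seed):
        net, store, dag = random_instance(seed)
        greedy = objective(net, greedy_search(net, store, dag), dag)
        exact = objective(net, exhaustive_search(net, store, dag), dag)
        assert greedy >= exact


class TestScore:
    def test_shared_candidate_clique_scores_zero(self, chain_dag):
        genes = ["g1", "g2", "g3"]
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3"), ("g1", "g3")])
        store = make_store(chain_dag, {g: {B} for g in genes})
        result = score(net, store, chain_dag)
        assert result.network_score == 0

    def test_two_component_breakdown(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2"), ("g3", "g4")])
        store = make_store(chain_dag, {"g1": {B}, "g2": {B},
                                       "g3": {A}, "g4": {B}})
        # g3-g4 candidates force the chain pair: weight 1/3
        result = score(net, store, chain_dag, mode="exhaustive")
        assert result.network_score == Fraction(1, 6)
        scores = sorted(s for _, s, _ in result.component_scores)
        assert scores == [0, Fraction(1, 3)]

    def test_auto_mode_uses_greedy_beyond_cap(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3")])
        store = make_store(chain_dag, {g: {R, A, B} for g in ("g1", "g2", "g3")})
        result = score(net, store, chain_dag, mode="auto", cap=8)
        assert result.search_mode == "greedy"
        result2 = score(net, store, chain_dag, mode="auto", cap=100)
        assert result2.search_mode == "branch_and_bound"

    @pytest.mark.parametrize("seed", range(10))
    def test_three_way_score_consistency(self, seed):
        net, store, dag = random_instance(seed, n_genes=6)
        result = score(net, store, dag)
        weights = list(result.edge_weights.values())
        assert all(0 <= w <= 1 for w in weights)
        assert 0 <= result.network_score <= 1
        assert result.network_score == sum(weights) / len(weights)
        total_edges = sum(n for _, _, n in result.component_scores)
        weighted = sum(s * n for _, s, n in result.component_scores)
        assert total_edges == len(weights)
        assert result.network_score == weighted / total_edges

    @pytest.mark.parametrize("seed", range(5))
    def test_node_relabeling_invariance(self, seed):
        net, store, dag = random_instance(seed)
        base = score(net, store, dag).network_score

        mapping = {g: f"zz_{g}" for g in net.nodes}
        relabeled = GeneNetwork(
            nodes=[mapping[n] for n in net.nodes],
            edges=[(mapping[u], mapping[v]) for u, v in net.sorted_edges()],
        )
        relabeled_store = make_store(dag, {
            mapping[g]: {p.product_id: set(p.terms) for p in gene.products}
            for g, gene in store.genes.items()
        })
        assert score(relabeled, relabeled_store, dag).network_score == base

    def test_common_deepest_term_gives_zero(self):
        # every gene's candidates include the deepest term C -> optimum is 0
        dag = make_dag({R: set(), A: {R}, B: {A}, C: {B}})
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3")])
        store = make_store(dag, {"g1": {C, A}, "g2": {C, R}, "g3": {C, B}})
        result = score(net, store, dag)
        assert result.network_score == 0
        assert set(result.assignment.selection.values()) == {C}

    def test_extra_zero_weight_edge_cannot_raise_score(self, chain_dag):
        net = GeneNetwork(edges=[("g1", "g2"), ("g2", "g3")])
        store = make_store(chain_dag, {"g1": {B}, "g2": {A}, "g3": {B}})
        base = score(net, store, chain_dag)
        # add an edge between two genes assigned the identical term
        sel = base.assignment.selection
        assert sel["g1"] == sel["g3"]
        bigger = GeneNetwork(edges=net.sorted_edges() + [("g1", "g3")])
        with_edge = objective(bigger, base.assignment, chain_dag)
        assert with_edge <= base.network_score

    def test_memoized_pairs_match_direct_evaluation(self, seed=0):
        from gfdnet.ontology import term_dissimilarity
        net, store, dag = random_instance(seed)
        result = score(net, store, dag)
        for (u, v), w in result.edge_weights.items():
            direct = term_dissimilarity(
                dag, result.assignment[u], result.assignment[v])
            assert float(w) == direct
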