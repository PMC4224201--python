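"""Shared fixtures: tiny hand-built ontologies and annotation helpers."""

import pytest

from gfdnet.annotations import AnnotationStore
from gfdnet.ontology import GODag, GOTerm

R, A, B, C = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"


def make_dag(parent_map, namespace="biological_process"):
    """Build a GODag from {accession: set of parent accessions}."""
    terms = {
        acc: GOTerm(acc, f"term {acc[-2:]}", namespace, frozenset(parents))
        for acc, parents in parent_map.items()
    }
    return GODag(terms)


def make_store(dag, gene_terms):
    """Build a store from {gene: terms} or {gene: {product: terms}}."""
    store = AnnotationStore(dag)
    for gene, val in gene_terms.items():
        if isinstance(val, dict):
            for product, terms in val.items():
                for t in terms:
                    store.add(gene, product, t)
        else:
            for t in val:
                store.add(gene, f"{gene}.p1", t)
    return store


@pytest.fixture
def chain_dag():
    """Root R <- A <- B: depths 0, 1, 2."""
    return make_dag({R: set(), A: {R}, B: {A}})


@pytest.fixture
def sibling_dag():
    """A and B are leaves directly under the root."""
    return make_dag({R: set(), A: {R}, B: {R}})


@pytest.fixture
def diamond_dag():
    """R <- A, R <- B, A <- C, B <- C: two root paths to C."""
    return make_dag({R: set(), A: {R}, B: {R}, C: {A, B}})
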