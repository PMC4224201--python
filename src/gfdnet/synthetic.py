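"""Seeded synthetic ontologies, annotation stores and fixture networks.

Everything here exists so that the whole pipeline is testable offline:
random rooted DAGs standing in for a GO namespace, annotation stores
whose *cohesion* parameter tunes how often gene products share one focal
deep term, and small named networks echoing the topologies the method is
meant to discriminate (a cohesive clique, a path, a two-component
network with one cohesive and one divergent part).

With cohesion 1 every product carries only the focal term, so the
optimal assignment selects it everywhere and the network scores exactly
0 — the ground-truth recovery case.  As cohesion falls, annotations
drift toward uniform noise over all terms and the expected score rises.

All generators are pure functions of their :class:`SynthConfig`: the
same seed reproduces the same ontology, store and files byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .annotations import AnnotationStore, write_tsv
from .network import GeneNetwork, write_sif
from .ontology import GODag, GOTerm, write_obo

# fixed offsets deriving independent sub-streams from one seed
_DAG_STREAM = 0
_ANNOTATION_STREAM = 1


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic generators.

    ``cohesion`` is the probability that any single annotation slot is
    the focal (deep, shared) term rather than a uniform draw over all
    terms; 1 makes the network perfectly cohesive, 0 is pure noise.
    """

    n_terms: int = 40
    max_parents: int = 3
    n_genes: int = 8
    products_per_gene: int = 2
    terms_per_product: int = 3
    cohesion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_terms", "max_parents", "n_genes", "products_per_gene",
                     "terms_per_product"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.cohesion <= 1.0:
            raise ValueError(f"cohesion must be in [0, 1], got {self.cohesion}")


def _accession(i: int) -> str:
    return f"GO:{i + 1:07d}"


def _gene_id(i: int) -> str:
    return f"g{i + 1:03d}"


def random_dag(config: SynthConfig) -> GODag:
    """A random rooted DAG in the biological_process namespace.

    Term 0 is the root; term *i* (i > 0) draws 1..max_parents distinct
    parents uniformly from terms 0..i-1, which guarantees acyclicity and
    a single root.
    """
    rng = np.random.default_rng([_DAG_STREAM, config.seed])
    terms: dict[str, GOTerm] = {}
    root = _accession(0)
    terms[root] = GOTerm(root, "synthetic root", "biological_process")
    for i in range(1, config.n_terms):
        k = int(rng.integers(1, min(config.max_parents, i) + 1))
        parent_idx = rng.choice(i, size=k, replace=False)
        parents = frozenset(_accession(int(j)) for j in parent_idx)
        acc = _accession(i)
        terms[acc] = GOTerm(acc, f"synthetic term {i}", "biological_process", parents)
    return GODag(terms)


def cohesive_annotations(
    dag: GODag, config: SynthConfig
) -> tuple[AnnotationStore, str]:
    """An annotation store with tunable cohesion, plus its focal term.

    The focal term is a term of maximal depth (ties to the smallest
    accession) so that a perfectly cohesive network provably scores 0.
    Each of the ``terms_per_product`` slots of each product is the focal
    term with probability ``cohesion``, otherwise a uniform draw over
    all terms.
    """
    if config.cohesion > 0:
        if max(dag.depth.values()) < 2:
            raise ValueError("cohesion > 0 needs a DAG with a term of depth >= 2")
    rng = np.random.default_rng([_ANNOTATION_STREAM, config.seed])
    focal = min(dag.terms, key=lambda t: (-dag.depth[t], t))
    all_terms = sorted(dag.terms)
    store = AnnotationStore(dag)
    for gi in range(config.n_genes):
        gene = _gene_id(gi)
        for pi in range(config.products_per_gene):
            product = f"{gene}.p{pi + 1}"
            for _ in range(config.terms_per_product):
                if rng.random() < config.cohesion:
                    term = focal
                else:
                    term = all_terms[int(rng.integers(len(all_terms)))]
                store.add(gene, product, term)
    return store, focal


def fixture_networks() -> dict[str, GeneNetwork]:
    """Named fixture topologies used throughout the test-suite.

    ``two_component`` mirrors the shape of a signalling network split
    into a cohesive 5-gene clique and a looser 7-gene part, the
    situation where per-component score breakdowns are informative.
    """
    clique5 = GeneNetwork()
    members = [_gene_id(i) for i in range(5)]
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            clique5.add_edge(u, v)

    path7 = GeneNetwork()
    chain = [_gene_id(i) for i in range(7)]
    for u, v in zip(chain, chain[1:]):
        path7.add_edge(u, v)

    two_component = GeneNetwork()
    for u, v in clique5.sorted_edges():
        two_component.add_edge(u, v)
    second = [_gene_id(i) for i in range(5, 12)]
    for u, v in zip(second, second[1:]):
        two_component.add_edge(u, v)

    return {"clique5": clique5, "path7": path7, "two_component": two_component}


def network_for(config: SynthConfig) -> GeneNetwork:
    """A connected random network over the configured genes.

    Built as a random spanning tree plus extra random edges (about half
    the gene count), seeded from the config; matches the gene ids the
    annotation generator uses.
    """
    rng = np.random.default_rng([2, config.seed])
    net = GeneNetwork()
    genes = [_gene_id(i) for i in range(config.n_genes)]
    if len(genes) == 1:
        net.add_node(genes[0])
        return net
    for i in range(1, len(genes)):
        j = int(rng.integers(i))
        net.add_edge(genes[i], genes[j])
    extra = max(1, config.n_genes // 2)
    for _ in range(extra):
        i, j = rng.integers(len(genes), size=2)
        if i != j:
            net.add_edge(genes[int(i)], genes[int(j)])
    return net


def write_bundle(config: SynthConfig, out_dir) -> dict[str, Path]:
    """Persist a synthetic ontology/annotations/network bundle as files.

    Writes ``ontology.obo``, ``annotations.tsv`` and ``network.sif`` to
    ``out_dir`` so the file-based pipeline can be exercised end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dag = random_dag(config)
    store, focal = cohesive_annotations(dag, config)
    net = network_for(config)
    paths = {
        "obo": out_dir / "ontology.obo",
        "tsv": out_dir / "annotations.tsv",
        "sif": out_dir / "network.sif",
    }
    write_obo(dag, paths["obo"], header_comment=f"synthetic ontology, seed={config.seed}")
    write_tsv(store, paths["tsv"])
    write_sif(net, paths["sif"])
    return paths


def perturbed(config: SynthConfig, **changes) -> SynthConfig:
    """A copy of ``config`` with the given fields replaced."""
    return replace(config, **changes)
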