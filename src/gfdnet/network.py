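"""Gene network I/O: SIF / edge-list readers and result report writers."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx

from .errors import EmptyNetworkError, FormatError
from .ontology import _open_maybe_gzip

if TYPE_CHECKING:  # pragma: no cover
    from .core import DissimilarityResult
    from .ontology import GODag

log = logging.getLogger(__name__)


class GeneNetwork:
    """An undirected simple graph over verbatim gene identifier strings.

    Self-loops and duplicate edges are rejected at construction; node
    identity is the exact string from the input file (no case folding —
    gene symbols are case-sensitive in some organisms).
    """

    def __init__(self, nodes=(), edges=()):
        self.graph = nx.Graph()
        self.graph.add_nodes_from(nodes)
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, u: str, v: str) -> bool:
        """Add an undirected edge; returns False for self-loops/duplicates."""
        if u == v or self.graph.has_edge(u, v):
            return False
        self.graph.add_edge(u, v)
        return True

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (min, max) pairs in deterministic order."""
        return sorted((min(u, v), max(u, v)) for u, v in self.graph.edges)

    def subgraph(self, nodes) -> "GeneNetwork":
        sub = GeneNetwork()
        sub.graph = self.graph.subgraph(nodes).copy()
        return sub

    def connected_components(self) -> list[set[str]]:
        """Components sorted by their smallest member for stable reporting."""
        return sorted(nx.connected_components(self.graph), key=min)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __repr__(self) -> str:
        return f"GeneNetwork({self.n_nodes()} nodes, {self.n_edges()} edges)"


def read_network(path, format: str = "sif") -> GeneNetwork:
    """Read a gene network from a SIF or 2-column edge-list file.

    SIF rows ``A rel B [C ...]`` fan out to edges A–B, A–C, …; one-column
    rows declare isolated nodes.  Edge direction is discarded, duplicate
    edges and self-loops are dropped with logged counts.
    """
    if format not in ("sif", "edgelist"):
        raise ValueError(f"format must be 'sif' or 'edgelist', got {format!r}")
    net = GeneNetwork()
    dropped = 0
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            cols = [c.strip() for c in cols if c.strip()]
            if format == "sif":
                if len(cols) == 1:
                    net.add_node(cols[0])
                    continue
                if len(cols) == 2:
                    raise FormatError(
                        path, line_no, "SIF row needs 1 column (node) or >=3 (src rel tgt...)"
                    )
                src, targets = cols[0], cols[2:]
                net.add_node(src)
                for tgt in targets:
                    net.add_node(tgt)
                    if not net.add_edge(src, tgt):
                        dropped += 1
            else:
                if len(cols) != 2:
                    raise FormatError(path, line_no, f"expected 2 columns, got {len(cols)}")
                u, v = cols
                net.add_node(u)
                net.add_node(v)
                if not net.add_edge(u, v):
                    dropped += 1
    if net.n_nodes() == 0:
        raise EmptyNetworkError(f"{path}: no nodes found")
    if dropped:
        log.info("read_network(%s): dropped %d duplicate/self-loop edges", path, dropped)
    return net


def write_sif(network: GeneNetwork, path, relation: str = "pp") -> None:
    """Write a network as SIF; isolated nodes get one-column rows."""
    with open(path, "w", encoding="utf-8") as fh:
        linked = set()
        for u, v in network.sorted_edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
            linked.update((u, v))
        for node in sorted(network.nodes - linked):
            fh.write(f"{node}\n")


def write_graphml(result: "DissimilarityResult", path) -> None:
    """Export the scored network as GraphML with a ``weight`` edge attribute."""
    g = nx.Graph()
    g.add_nodes_from(result.network.graph.nodes)
    for (u, v), w in result.edge_weights.items():
        g.add_edge(u, v, weight=float(w))
    for gene, term in result.assignment.selection.items():
        g.nodes[gene]["selected_go_id"] = term
    nx.write_graphml(g, path)


def write_result(result: "DissimilarityResult", out_dir, dag: "GODag | None" = None) -> dict:
    """Write the three report files and return their paths.

    * ``edge_weights.tsv`` — ``gene1  gene2  weight`` per scorable edge;
    * ``gene_selection.tsv`` — ``gene  selected_go_id  go_name  status``,
      with empty term and status ``unannotated`` for excluded genes;
    * ``summary.json`` — network score, per-component scores,
      unannotated genes and run settings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    edge_path = out_dir / "edge_weights.tsv"
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for u, v in sorted(result.edge_weights):
            fh.write(f"{u}\t{v}\t{float(result.edge_weights[(u, v)]):.6g}\n")

    gene_path = out_dir / "gene_selection.tsv"
    with open(gene_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tselected_go_id\tgo_name\tstatus\n")
        for gene in sorted(result.network.nodes):
            term = result.assignment.selection.get(gene)
            if term is None:
                status = "unannotated" if gene in result.unannotated_genes else "unscored"
                fh.write(f"{gene}\t\t\t{status}\n")
            else:
                name = dag.terms[term].name if dag is not None and term in dag else ""
                fh.write(f"{gene}\t{term}\t{name}\tselected\n")

    summary_path = out_dir / "summary.json"
    summary = {
        "network_score": float(result.network_score),
        "component_scores": [
            {
                "genes": sorted(comp),
                "score": float(score),
                "n_edges": n_edges,
            }
            for comp, score, n_edges in result.component_scores
        ],
        "unannotated_genes": sorted(result.unannotated_genes),
        "settings": {"search_mode": result.search_mode, "measure": result.measure},
    }
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"edges": edge_path, "genes": gene_path, "summary": summary_path}
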