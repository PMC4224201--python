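"""Gene Ontology DAG: parsing, depth, common ancestors and term dissimilarity.

One :class:`GODag` holds a single GO namespace (biological_process,
molecular_function or cellular_component) as a rooted DAG over ``is_a``
edges.  Term *depth* is the number of edges on the **longest** path from
the namespace root, so specificity is monotone: every child is strictly
deeper than each of its parents.

The pairwise dissimilarity between two terms is a Wu–Palmer-style
distance built on the deepest common ancestor (DCA)::

    d(t1, t2) = 1 - 2 * depth(DCA) / (depth(t1) + depth(t2))

It is 0 for identical terms, 1 for terms whose only shared ancestor is
the root, and rewards deep (specific) shared ancestry.  The measure is
pluggable: any callable ``f(dag, t1, t2) -> float`` registered in
:data:`MEASURES` can replace the default.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import EmptyOntologyError, FormatError, UnknownTermError

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: Maps GAF aspect letters to namespace names.
ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

_GO_ACCESSION = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GOTerm:
    """A single non-obsolete ontology term."""

    id: str
    name: str
    namespace: str
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False

    def __post_init__(self):
        if not _GO_ACCESSION.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")
        if self.obsolete and self.parents:
            raise ValueError(f"obsolete term {self.id} must carry no parents")


class GODag:
    """A single-namespace GO DAG with depth and ancestor queries.

    Parameters
    ----------
    terms
        Mapping accession -> :class:`GOTerm`; all of one namespace, all
        non-obsolete, parent references closed within the mapping.
    """

    def __init__(self, terms: Mapping[str, GOTerm]):
        if not terms:
            raise EmptyOntologyError("no terms supplied")
        self.terms: dict[str, GOTerm] = dict(terms)
        namespaces = {t.namespace for t in self.terms.values()}
        if len(namespaces) != 1:
            raise ValueError(f"terms span multiple namespaces: {sorted(namespaces)}")
        self.namespace = namespaces.pop()
        for term in self.terms.values():
            missing = term.parents - self.terms.keys()
            if missing:
                raise ValueError(f"{term.id} has parents outside the DAG: {sorted(missing)}")

        roots = sorted(t.id for t in self.terms.values() if not t.parents)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}: {roots[:5]}")
        self.root: str = roots[0]

        self._graph = nx.DiGraph()  # edges parent -> child
        self._graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                self._graph.add_edge(parent, term.id)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise ValueError("is_a graph contains a cycle")

        # Longest-path depth and reflexive ancestor closure, one topological pass.
        self.depth: dict[str, int] = {}
        self.ancestor_sets: dict[str, frozenset[str]] = {}
        for acc in nx.topological_sort(self._graph):
            parents = self.terms[acc].parents
            if not parents:
                self.depth[acc] = 0
                self.ancestor_sets[acc] = frozenset({acc})
            else:
                self.depth[acc] = 1 + max(self.depth[p] for p in parents)
                anc = {acc}
                for p in parents:
                    anc.update(self.ancestor_sets[p])
                self.ancestor_sets[acc] = frozenset(anc)

        self._dca_cache: dict[tuple[str, str], str] = {}

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:
        return f"GODag({self.namespace!r}, {len(self)} terms, root={self.root!r})"

    def _require(self, accession: str) -> None:
        if accession not in self.terms:
            raise UnknownTermError(accession)

    def deepest_common_ancestor(self, t1: str, t2: str) -> str:
        """Return the deepest shared ancestor of ``t1`` and ``t2``.

        Ancestor sets are reflexive, so the DCA of a term with itself is
        the term.  Depth ties break to the lexicographically smallest
        accession, making the query deterministic.
        """
        self._require(t1)
        self._require(t2)
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self._dca_cache.get(key)
        if hit is not None:
            return hit
        common = self.ancestor_sets[t1] & self.ancestor_sets[t2]
        # root is always common, so `common` is never empty
        dca = min(common, key=lambda a: (-self.depth[a], a))
        self._dca_cache[key] = dca
        return dca


def wu_palmer_distance(dag: GODag, t1: str, t2: str) -> Fraction:
    """Wu–Palmer-style dissimilarity ``1 - 2*depth(DCA)/(depth(t1)+depth(t2))``.

    Returns an exact :class:`~fractions.Fraction` in [0, 1].  The
    degenerate root/root pair (depth sum 0) is defined as 0: with one
    root per namespace both terms are then identical.
    """
    dca = dag.deepest_common_ancestor(t1, t2)
    denom = dag.depth[t1] + dag.depth[t2]
    if denom == 0:
        return Fraction(0)
    return 1 - Fraction(2 * dag.depth[dca], denom)


#: Registry of pluggable edge dissimilarity measures.
MEASURES = {"wu_palmer": wu_palmer_distance}


def term_dissimilarity(dag: GODag, t1: str, t2: str, measure: str = "wu_palmer") -> float:
    """Pairwise term dissimilarity in [0, 1] under the named measure."""
    return float(MEASURES[measure](dag, t1, t2))


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_obo(path, namespace: str) -> GODag:
    """Parse an OBO 1.2/1.4 file into a single-namespace :class:`GODag`.

    Obsolete terms are dropped, as are terms of other namespaces and
    ``is_a`` edges crossing out of the requested namespace (counts are
    logged).  Only ``is_a`` edges are used; ``part_of``/``regulates``
    relationships are ignored.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
    try:
        with _open_maybe_gzip(path) as handle:
            graph = obonet.read_obo(handle, ignore_obsolete=True)
    except (OSError, UnicodeDecodeError):
        raise
    except Exception as exc:  # obonet raises assorted errors on garbled input
        raise FormatError(path, 0, f"not a readable OBO file ({exc})") from exc

    default_ns = graph.graph.get("default-namespace", [None])
    default_ns = default_ns[0] if default_ns else None

    in_namespace = {
        acc
        for acc, data in graph.nodes(data=True)
        if data.get("namespace", default_ns) == namespace
    }
    if not in_namespace:
        raise EmptyOntologyError(f"{path}: no terms in namespace {namespace!r}")
    dropped_terms = graph.number_of_nodes() - len(in_namespace)

    terms = {}
    dropped_edges = 0
    for acc in in_namespace:
        data = graph.nodes[acc]
        parents = set()
        for parent in data.get("is_a", []):
            parent = parent.split("!")[0].strip()
            if parent in in_namespace:
                parents.add(parent)
            else:
                dropped_edges += 1
        terms[acc] = GOTerm(
            id=acc,
            name=data.get("name", ""),
            namespace=namespace,
            parents=frozenset(parents),
        )
    if dropped_terms or dropped_edges:
        log.info(
            "parse_obo(%s): kept %d %s terms; dropped %d other-namespace/obsolete "
            "terms and %d cross-namespace is_a edges",
            path, len(terms), namespace, dropped_terms, dropped_edges,
        )
    return GODag(terms)


def brute_force_depths(terms: Mapping[str, GOTerm]) -> dict[str, int]:
    """Independent longest-path depth by enumerating all root-to-term paths.

    Exponential; intended as a test oracle on DAGs of <= ~50 terms.
    """
    roots = [t.id for t in terms.values() if not t.parents]
    assert len(roots) == 1
    root = roots[0]

    def longest(acc: str) -> int:
        if acc == root:
            return 0
        return max(1 + longest(p) for p in terms[acc].parents)

    return {acc: longest(acc) for acc in terms}


def write_obo(dag: GODag, path, header_comment: str | None = None) -> None:
    """Serialise a DAG back to a minimal OBO 1.2 flat file.

    Terms are written in sorted accession order so equal DAGs serialise
    byte-identically.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: gfdnet-synthetic-{dag.namespace}\n")
        if header_comment:
            fh.write(f"remark: {header_comment}\n")
        fh.write("\n")
        for acc in sorted(dag.terms):
            term = dag.terms[acc]
            fh.write("[Term]\n")
            fh.write(f"id: {term.id}\n")
            fh.write(f"name: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for parent in sorted(term.parents):
                fh.write(f"is_a: {parent} ! {dag.terms[parent].name}\n")
            fh.write("\n")
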