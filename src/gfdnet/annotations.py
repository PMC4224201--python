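"""Gene -> gene-product -> GO-term annotation stores.

A gene product (protein/RNA) carries a set of GO terms; a gene carries one
or more products.  The *candidate set* of a gene — the terms the cohesive
search may select from — is the union over its products, deduplicated and
sorted for deterministic iteration.

Readers accept GAF 2.1/2.2 or a bespoke 3-column TSV (``gene  product
go_id``), both optionally gzipped.  Terms absent from the loaded DAG
(other namespaces, obsolete, typos) are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import FormatError
from .ontology import ASPECT_TO_NAMESPACE, GODag, _open_maybe_gzip

log = logging.getLogger(__name__)

_GAF_COLUMNS = 17


@dataclass
class GeneProduct:
    product_id: str
    terms: set[str] = field(default_factory=set)


@dataclass
class Gene:
    gene_id: str
    products: list[GeneProduct] = field(default_factory=list)

    def candidate_terms(self) -> tuple[str, ...]:
        """Sorted union of all products' terms."""
        union: set[str] = set()
        for product in self.products:
            union |= product.terms
        return tuple(sorted(union))


class AnnotationStore:
    """Per-gene annotation sets restricted to one DAG's namespace."""

    def __init__(self, dag: GODag):
        self.dag = dag
        self.genes: dict[str, Gene] = {}
        #: rows whose GO term was absent from the DAG
        self.dropped_terms: int = 0
        #: rows skipped for NOT qualifiers or mismatched aspect (GAF only)
        self.skipped_rows: int = 0

    def add(self, gene_id: str, product_id: str, go_id: str) -> None:
        """Record one annotation; silently drops terms not in the DAG."""
        if go_id not in self.dag:
            self.dropped_terms += 1
            return
        gene = self.genes.setdefault(gene_id, Gene(gene_id))
        for product in gene.products:
            if product.product_id == product_id:
                product.terms.add(go_id)
                return
        gene.products.append(GeneProduct(product_id, {go_id}))

    def candidates(self, gene_id: str) -> tuple[str, ...]:
        """Sorted candidate term accessions; empty tuple for unknown genes."""
        gene = self.genes.get(gene_id)
        if gene is None:
            return ()
        return gene.candidate_terms()

    def annotated_genes(self) -> set[str]:
        return {g for g, gene in self.genes.items() if gene.candidate_terms()}

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:
        return f"AnnotationStore({len(self.genes)} genes, namespace={self.dag.namespace!r})"


def load_gaf(
    path,
    dag: GODag,
    *,
    gene_key: str = "symbol",
    exclude_iea: bool = False,
) -> AnnotationStore:
    """Load a GAF 2.1/2.2 file.

    Rows are skipped when the qualifier contains ``NOT`` or the aspect
    letter does not match the DAG's namespace.  ``gene_key`` chooses the
    gene identifier: ``"symbol"`` (DB Object Symbol, default) or ``"id"``
    (DB Object ID).  ``exclude_iea`` drops electronically inferred
    annotations; by default every evidence code is accepted.
    """
    if gene_key not in ("symbol", "id"):
        raise ValueError(f"gene_key must be 'symbol' or 'id', got {gene_key!r}")
    store = AnnotationStore(dag)
    want_aspect = {a for a, ns in ASPECT_TO_NAMESPACE.items() if ns == dag.namespace}
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) != _GAF_COLUMNS:
                raise FormatError(
                    path, line_no, f"expected {_GAF_COLUMNS} tab-separated columns, got {len(cols)}"
                )
            db_id, symbol, qualifier, go_id = cols[1], cols[2], cols[3], cols[4]
            aspect, evidence = cols[8], cols[6]
            if "NOT" in qualifier.split("|"):
                store.skipped_rows += 1
                continue
            if aspect not in want_aspect:
                store.skipped_rows += 1
                continue
            if exclude_iea and evidence == "IEA":
                store.skipped_rows += 1
                continue
            gene_id = symbol if gene_key == "symbol" else db_id
            store.add(gene_id, db_id, go_id)
    log.info(
        "load_gaf(%s): %d genes; skipped %d rows, dropped %d unknown terms",
        path, len(store), store.skipped_rows, store.dropped_terms,
    )
    return store


def load_tsv(path, dag: GODag) -> AnnotationStore:
    """Load a 3-column ``gene<TAB>product<TAB>go_id`` file (header optional).

    Same semantics as :func:`load_gaf` minus qualifier/aspect filtering.
    Lines starting with ``#`` or a ``gene`` header are ignored.
    """
    store = AnnotationStore(dag)
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(path, line_no, f"expected 3 columns, got {len(cols)}")
            gene_id, product_id, go_id = cols[0], cols[1], cols[2]
            if line_no == 1 and go_id.lower() in ("go_id", "term", "go"):
                continue  # header row
            store.add(gene_id, product_id, go_id)
    log.info(
        "load_tsv(%s): %d genes; dropped %d unknown terms",
        path, len(store), store.dropped_terms,
    )
    return store


def write_tsv(store: AnnotationStore, path) -> None:
    """Write a store back to the 3-column TSV format, sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tproduct\tgo_id\n")
        for gene_id in sorted(store.genes):
            gene = store.genes[gene_id]
            for product in sorted(gene.products, key=lambda p: p.product_id):
                for go_id in sorted(product.terms):
                    fh.write(f"{gene_id}\t{product.product_id}\t{go_id}\n")
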