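"""Pairwise GO-term dissimilarity on a hand-built five-term ontology.

Shows how the deepest common ancestor (DCA) drives the Wu–Palmer-style
distance 1 - 2*depth(DCA) / (depth(t1) + depth(t2)).
"""

from gfdnet import GODag, GOTerm, term_dissimilarity

ns = "biological_process"
R, A, B, C, D = (f"GO:000000{i}" for i in range(1, 6))
dag = GODag({
    R: GOTerm(R, "root process", ns),
    A: GOTerm(A, "signal transduction", ns, frozenset({R})),
    B: GOTerm(B, "kinase cascade", ns, frozenset({A})),
    C: GOTerm(C, "MAPK cascade", ns, frozenset({B})),
    D: GOTerm(D, "cell adhesion", ns, frozenset({R})),
})

for t1, t2 in [(C, C), (B, C), (A, C), (C, D)]:
    dca = dag.deepest_common_ancestor(t1, t2)
    w = term_dissimilarity(dag, t1, t2)
    print(f"d({dag.terms[t1].name!r}, {dag.terms[t2].name!r}) = {w:.3f}"
          f"   [DCA: {dag.terms[dca].name!r}, depth {dag.depth[dca]}]")

# Identical terms weigh 0; terms meeting only at the root weigh 1; a
# deep shared ancestor (here the kinase cascade) keeps the weight low.
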