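# gfdnet

**Functional dissimilarity of gene networks via cohesive GO-term selection.**

Inferred gene networks (co-expression, protein–protein interaction,
pathway extractions) need validation: do the connected genes actually
share function?  Classical semantic-similarity measures score a *set* of
genes and ignore how they are wired.  `gfdnet` scores the network
*through its topology*: it selects, for every gene, one Gene Ontology
annotation — out of everything its gene products are annotated with — so
that the network as a whole is as functionally cohesive as possible,
then reports how far from cohesive even that best selection is.

## The measure

Let `G = (V, E)` be an undirected gene network and let each gene `v`
carry a candidate set `C(v)` of GO terms (the union over its gene
products, one namespace per run).  For an assignment `a(v) ∈ C(v)`
define each edge weight by a Wu–Palmer-style distance on the GO `is_a`
DAG,

```
d(t1, t2) = 1 − 2·depth(DCA(t1, t2)) / (depth(t1) + depth(t2))
```

where `depth` is the longest `is_a` path from the namespace root and
`DCA` is the deepest common ancestor.  The network's functional
dissimilarity is the minimum over assignments of the mean edge weight:

```
GFD(G) = min over a  of  (1/|E|) · Σ_{(u,v) ∈ E} d(a(u), a(v))
```

Scores live in [0, 1]: 0 means every connected gene can be read as
performing one shared, specific function; 1 means no functional
cohesion at all.  Ties between equally good assignments resolve to the
more specific (deeper) terms, then lexicographically, so results are
fully deterministic.  The optimum is found exactly by exhaustive or
branch-and-bound search (identical answers, the latter pruned), with a
deterministic greedy fallback for very large candidate spaces.

## Worked example

```python
from gfdnet import SynthConfig, cohesive_annotations, network_for, random_dag, score

cfg = SynthConfig(n_terms=40, n_genes=8, cohesion=0.2, seed=42)
dag = random_dag(cfg)                       # seeded random GO-like DAG
store, focal = cohesive_annotations(dag, cfg)
result = score(network_for(cfg), store, dag)
print(float(result.network_score))
```

Running `python examples/01_score_synthetic_network.py` (the same
computation, with reporting) prints:

```
network: 8 genes, 9 edges
functional dissimilarity: 0.1629
search mode: branch_and_bound
planted focal term: GO:0000031 (depth 9)
  g001 -> GO:0000037 (depth 8)
  g002 -> GO:0000008 (depth 5)
  ...
```

At cohesion 0.2 only a fifth of the annotation slots carry the planted
focal term, so the best assignment mixes related deep terms and the
score lands at 0.16 — low but clearly above the 0.0 a fully cohesive
network achieves.  The per-gene lines show which annotation the search
judged most compatible with each gene's neighbourhood.

The other scripts in `examples/` each demonstrate one capability:
pairwise term dissimilarity and deepest common ancestors, the three
search strategies, the score's response to annotation cohesion, and the
file-based OBO + annotations + SIF pipeline.

## Command line

```bash
# score a network from files (GO OBO, GAF or 3-column TSV, SIF or edge list)
gfdnet score --obo go.obo --annotations ann.gaf --ann-format gaf \
             --network net.sif --namespace BP --out results/

# generate a self-contained synthetic OBO/TSV/SIF bundle
gfdnet synth --n-genes 10 --cohesion 0.8 --seed 1 --out bundle/
```

`score` prints the network dissimilarity alone on stdout (logs go to
stderr) and writes three reports: per-edge weights, the selected term
per gene, and a JSON summary with per-component scores — a network that
splits into a cohesive and a divergent sub-network shows it there.
Exit codes: 0 success, 2 input errors, 3 if no scorable edge remains.

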