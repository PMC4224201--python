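"""The file-based pipeline: OBO + TSV + SIF in, three reports out.

Equivalent to `gfdnet synth ... && gfdnet score ...` but driven from
Python.  Useful when the inputs come from real files (a GO release, a
GAF from the GO Consortium, a Cytoscape SIF export).
"""

import tempfile
from pathlib import Path

from gfdnet import (
    SynthConfig, load_tsv, parse_obo, read_network, score, write_bundle,
    write_result,
)

workdir = Path(tempfile.mkdtemp(prefix="gfdnet_example_"))
paths = write_bundle(SynthConfig(cohesion=0.8, seed=11), workdir)

dag = parse_obo(paths["obo"], "biological_process")
store = load_tsv(paths["tsv"], dag)
net = read_network(paths["sif"], format="sif")

result = score(net, store, dag)
reports = write_result(result, workdir / "out", dag=dag)

print(f"network score: {float(result.network_score):.4f}")
for comp, comp_score, n_edges in result.component_scores:
    print(f"  component ({len(comp)} genes, {n_edges} edges): "
          f"score {float(comp_score):.4f}")
print("reports written:")
for name, path in reports.items():
    print(f"  {name}: {path}")

# edge_weights.tsv gives the per-edge dissimilarities, gene_selection.tsv
# the chosen GO term per gene, summary.json the network and per-component
# scores plus any genes excluded for lack of annotations.
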