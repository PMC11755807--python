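"""Extract the PIWIL2-seeded correlation module from a mixed panel.

A complete Pearson correlation graph is built over log2(x+1) normalized
values of PCGs, TEs and piRNAs (here the most variable molecules to keep
the complete graph small); the module is the seed, its top-k neighbors by
|r| and their top-k neighbors, and edges are kept only above the third
quartile of |r| over all member pairs.
"""

import tempfile

import numpy as np
import pandas as pd

from piwiflow import (
    CohortConfig, generate_cohort, size_factors, normalize,
    build_graph, extract_module, filter_edges, export_graph,
)

cohort = generate_cohort(CohortConfig(seed=1))
sf_rna = size_factors(cohort.rna_library())
sf_small = size_factors(cohort.small_library())
panel = pd.concat([
    normalize(cohort.pcg_counts, sf_rna),
    normalize(cohort.te_counts, sf_rna),
    normalize(cohort.pirna_counts, sf_small),
])
kinds = pd.concat([cm.annotations["kind"] for cm in
                   (cohort.pcg_counts, cohort.te_counts, cohort.pirna_counts)])

var = np.log2(panel + 1).var(axis=1)
keep = var.nlargest(150).index.union(pd.Index(["PIWIL2"]))
graph = build_graph(panel.loc[keep], kinds=kinds)

module = filter_edges(extract_module(graph, "PIWIL2", k=10), graph)
by_kind = pd.Series([graph.nodes[m].get("kind", "?") for m in module.members]).value_counts()
print(f"PIWIL2 module: {len(module.members)} members "
      f"({dict(by_kind)}), {len(module.edges)} edges retained")
print(f"Q3 |r| threshold over all member pairs: {module.q3_threshold:.3f}")

strongest = module.edges.reindex(module.edges["r"].abs().nlargest(5).index)
print("\nstrongest retained edges:")
print(strongest.round(3).to_string(index=False))

files = export_graph(module, graph, tempfile.mkdtemp())
print(f"\nexported for Cytoscape: {files['graphml']}")
print("(piRNAs co-vary with PIWIL2 here because the generator couples "
      "PIWIL2 to the latent piRNA factor)")
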