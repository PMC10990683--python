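# cytonet

Tools for two coupled questions in systems biology: *what does a
bioregulatory network model actually contain*, and *which cell lineage does
an RNA expression profile belong to?*

The first half of the package works on Reactome-style SBML pathway models.
It parses them into a bipartite species–reaction network, classifies each
molecular species as a system **input** (only ever consumed), **output**
(only ever produced), **mediator** (both) or **isolated**, prunes the
network to a reaction-centred subgraph at a chosen reaction distance, and
exports GraphViz DOT or SIF for visualization. Because curated pathway
databases are fragments, it also cross-indexes a whole corpus of models by
the external identifiers (UniProt accessions, gene symbols via an HGNC
table) harvested from species annotations: this supports species-overlap /
orthogonality analysis (Jaccard index over identifier sets) and flags
**knowledge gaps** — species a model only produces whose identifiers appear
in no other model, i.e. molecules whose downstream actions are missing from
the database. Since these models ship without kinetics, uniform rate laws
can be injected (mass action `v = k_f·∏[Rᵢ]^sᵢ`, or Michaelis–Menten
`v = v_max·[S]/(k_m+[S])` on the first listed reactant) and sanity-checked
with a fixed-step RK4 integrator.

The second half is an expression profiler for the Human Protein Atlas
single-cell long format (gene × tissue × cluster × cell type, in nTPM —
normalized transcripts per million). Rows are keyed by cell lineage
(`Tissue + " " + Cell.type`), cluster replicates are summarized (sample
standard deviation with the n−1 denominator, coefficient of variation) and
collapsed by the **median**, the lineage × gene matrix is **Min–Max
normalized** per gene to [0, 1], and lineages are compared by **Manhattan
(L1) distance**:

    d(i, j) = Σ_g | x'_ig − x'_jg |,   x' = (x − min_g) / (max_g − min_g)

A query expression vector is classified to its nearest lineage under this
metric. Per-gene differential profiles use z-scores across lineages,
`z = (x − x̄)/s`, tiered at |z| ≥ 2 (significant) and |z| ≥ 3 (very
significant) by default.

A deterministic synthetic-data module generates both input kinds with
ground-truth manifests — expression tables with planted lineage markers and
SBML corpora with planted roles, shared identifiers and gap species — so
the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from cytonet import (ExpressionGroundTruth, make_expression_table,
                     load_expression_table, aggregate_median, build_matrix,
                     minmax_normalize, classify_lineage, gene_zscores)

# synthetic HPA-style table: 8 lineages x 3 clusters x 300 genes
tsv, manifest = make_expression_table(ExpressionGroundTruth(seed=0))
records = load_expression_table(tsv)
matrix = build_matrix(aggregate_median(records, "merge"))
normalized = minmax_normalize(matrix)

# perturb a smooth-muscle profile and classify it
rng = np.random.default_rng(42)
source = "Adipose tissue smooth muscle cells"
raw = matrix.values.loc[source].to_numpy()
query = dict(zip(matrix.col_genes, raw * np.exp(rng.normal(0, 0.2, raw.size))))
for key, dist in classify_lineage(query, normalized, top_k=3):
    print(f"{key:45s} {dist:8.3f}")
```

prints

```
Adipose tissue smooth muscle cells              56.773
Placenta smooth muscle cells                   106.359
Heart muscle cardiomyocytes                    112.071
```

The noisy query is recovered as its source lineage (rank 1), and the next
nearest lineage is the *other* smooth-muscle lineage — the two share a
planted marker-gene block, so their feature vectors sit close under the L1
metric, exactly the behaviour expected of related lineages in real data.
A follow-up differential query,

```python
profile = gene_zscores(matrix, manifest["markers"][source][0])
```

shows the planted marker peaking in its home lineage (z = 2.47 across the
8 lineages, tier `significant`).

Every operation is also reachable from the command line (`cytonet
search|roles|prune|dot|sif|gaps|overlap|kinetics|simulate|gep-build|
gep-classify|gep-gene|synth-expr|synth-sbml`); run `cytonet --help`.

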