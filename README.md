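# radgrn

Network analysis of radiation-response gene expression, built as a tested,
reusable pipeline:

1. **Synthetic data** (`radgrn.simulate`) — expression matrices with planted
   block-correlated modules, star-shaped hub neighborhoods, labeled
   radiation-induced genes, and linear-Gaussian Bayesian-network samples, so
   every downstream stage is testable offline.
2. **I/O** (`radgrn.io`) — TSV/CSV expression tables with AGI gene
   identifiers (`ATnGnnnnn`), GMT gene sets, JSON gene catalogs, GraphML and
   edge-list network export.
3. **GRN inference** (`radgrn.grn`) — Pearson-correlation networks with
   exact t-test significance filtering (default p ≤ 0.0005; optional
   Bonferroni/Benjamini–Hochberg correction), edge weight = r.
4. **Subnetwork extraction** (`radgrn.subnetworks`) — hypergeometric
   overrepresentation of gene sets on the network's node list with BH
   control, induced process subnetworks, and hub detection by degree
   thresholding (with optional promotion of annotated radiation-induced
   genes).
5. **Network measures** (`radgrn.measures`) — degree distributions, subgraph
   centrality (diagonal of the adjacency matrix exponential), adjacency and
   normalized (random-walk) spectral gaps, girth by traces of adjacency
   powers, diameter / average shortest path / connected components, density,
   Jaccard neighborhood similarity, closeness, PageRank, and eigenvector
   centrality.
6. **Causal discovery** (`radgrn.causal`) — incremental association Markov
   blanket (IAMB) recovery with Fisher-z partial-correlation tests, spouse /
   child role tagging via d-separation and collider checks, AND-rule
   symmetry correction.
7. **Gene ranking** (`radgrn.ranking`) — logistic regression of a binary
   gene category on standardized centrality features (IRLS with Wald
   inference, ridge fallback under separation), ranking by fitted log-odds.
8. **Pipeline + CLI** (`radgrn.pipeline`, `radgrn.cli`) — the full flow with
   a YAML config, a single seed, and a manifest that makes runs
   byte-for-byte reproducible.

## CLI

```sh
radgrn simulate --n-genes 60 --n-samples 30 --module-sizes 4 \
    --hub-leaves 12 --corr 0.8 --seed 1 --out-dir data
radgrn infer --expr data/expression.tsv --p-threshold 1e-5 --out net.graphml
radgrn extract --net net.graphml --sets data/gene_sets.gmt \
    --universe data/genes.txt --alpha 0.05 --hub-threshold 5 --out-dir sub
radgrn measure --net sub/subnet_module_0.graphml --out summary.json
radgrn jaccard --net-a a.graphml --gene-a AT1G00001 --net-b b.graphml --gene-b AT1G00001
radgrn causal --expr data/expression.tsv --targets targets.txt --out mb.json
radgrn rank --net sub/subnet_module_0.graphml --catalog data/catalog.json \
    --by score --top 50 --out ranking.tsv
radgrn run --config config.yaml          # full pipeline from YAML
radgrn report <run-dir>                  # hub / summary / Jaccard tables
```

A pipeline config holds either an `expression_path` (plus optional
`gene_sets_path` / `catalog_path`) or a `simulation:` block, together with
the stage thresholds and one `seed`; see `radgrn.pipeline.PipelineConfig`.

## Conventions worth knowing

- Subgraph centrality and the normalized spectral gap operate on the
  binarized undirected adjacency; the adjacency spectral gap also supports
  weighted mode.
- Girth (smallest `r` with `trace(A^r) > 0`) is only informative on a
  directed view; any undirected edge yields a length-2 closed walk.
- Jaccard similarity uses open neighborhoods (the gene itself excluded).
- Markov-blanket role tags are honest: directions that collider logic
  cannot settle are reported as `undetermined`.
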