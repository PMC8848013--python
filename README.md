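# grnimpact

Does imputing single-cell RNA-seq data help or hurt gene-regulatory-network
(GRN) reconstruction?  `grnimpact` is a self-contained evaluation pipeline
for that question: it simulates single-cell count data with a known
TF → gene ground-truth network, applies imputation operators (or imports
matrices from external tools), reconstructs networks with four inference
families, and scores everything with the early-precision metric suite —
EPR, log2 performance ratios, network-structure similarity, correlation
inflation diagnostics, and chain/feed-forward-loop motif classification.

It is aimed at computational biologists benchmarking preprocessing choices
for single-cell network inference, and at method developers who need a
controlled testbed where the true network is known.

## The evaluation in brief

Given a ranked list of predicted TF → gene edges and a reference network
with k positive edges:

- the **top-k network** keeps every prediction whose competition rank is
  ≤ k (tied weights share a rank, so more than k edges may be reported);
- **early precision** EP = |TP| / (reported edges);
- the reference **density** is numEdges / ((numGenes × numTFs) − numTFs),
  the fraction of the TF-sourced edge universe that is truly positive;
- **EPR = EP / density**, so a uniformly random predictor scores 1 and a
  perfect ranking scores 1/density;
- imputation effects are summarized as **log2(EPR_imputed / EPR_unimputed)**:
  0 means no change, −1 a 50% performance decline.

Evaluation conventions: undirected predictions are expanded into two
opposing directed edges, only edges leaving a TF are counted, and a
bidirectional pair collapses to one edge unless both endpoints are TFs.

Beyond precision, the pipeline asks *how* imputation changes networks:
Jaccard similarity of top-500 edge sets with hierarchical clustering and
adjusted-Rand purity against imputation/method labels, a two-way ANOVA
decomposing log2-ratio variance into its two experimental factors, rank
shifts of baseline true positives, per-class (TP/FP/FN) regressions of
gene-gene |correlation| before vs after imputation, and chain-vs-loop
motif confusion rates (TPR, FDR).

## Worked example

```python
from grnimpact import (SimulationConfig, evaluate_model,
                       infer_tree_importance, normalize,
                       sample_ground_truth, simulate_counts)

cfg = SimulationConfig(n_tfs=10, n_genes=60, n_cells=150,
                       effect_size=2.0, seed=3)
net = sample_ground_truth(cfg)
norm = normalize(simulate_counts(net, cfg))
ranked = infer_tree_importance(norm, n_trees=50, seed=3)
m = evaluate_model(ranked, net)
print(m.n_tp, m.n_reported, round(m.ep, 3), round(m.epr, 2))
```

prints

```
45 125 0.36 1.7
```

meaning: of the 125 top-ranked edges (k = 125 true edges in the
reference), 45 are correct, an early precision of 0.36; divided by the
reference density 0.212 that is an EPR of 1.70 — the random-forest ranking
recovers true regulation 1.7× better than chance.

The `examples/` directory holds one short script per capability
(simulation, gene selection, correlation inflation, scoring, motifs, the
full factorial experiment); each prints its numbers with a line on what
they mean.  The full grid is also available from the shell:

```bash
grnimpact run --config experiment.yaml --outdir results/
grnimpact report --artifacts results/
```

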