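"""Top-k network evaluation: harmonization, early precision, EPR.

Evaluation follows the TF-centric conventions of early-precision
benchmarking: undirected edges are expanded into two opposing directed
records, only edges leaving a TF are considered, a bidirectional pair is
counted once unless both endpoints are TFs, and both networks are
restricted to the gene universe of the expression matrix.  The top-k
network keeps every predicted edge whose competition rank is at most k,
where k is the number of positive edges in the (harmonized) reference —
ties can push the reported edge count above k.  Early precision EP is the
TP fraction among reported edges, and EPR = EP / reference density, so a
random predictor scores EPR = 1 regardless of the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    EdgeClassification,
    GeneSelection,
    GroundTruthNetwork,
    ModelMetrics,
    RankedEdgeList,
    TopKNetwork,
)

__all__ = [
    "harmonize_networks",
    "network_density",
    "top_k",
    "classify_edges",
    "compute_epr",
    "log2_ratio",
    "degree_distribution",
    "candidate_edges",
    "random_ranking",
    "evaluate_model",
]


def network_density(num_edges: int, num_genes: int, num_tfs: int) -> float:
    """Density of a TF-sourced directed network.

    The edge universe excludes self-loops, giving the denominator
    ``num_genes * num_tfs - num_tfs``.
    """
    if num_tfs < 1 or num_genes < num_tfs:
        raise ValueError("need num_genes >= num_tfs >= 1")
    denom = num_genes * num_tfs - num_tfs
    if denom <= 0:
        raise ValueError("degenerate universe: no TF-sourced edges possible")
    if num_edges < 0:
        raise ValueError("num_edges must be >= 0")
    return num_edges / denom


def harmonize_networks(
    pred: RankedEdgeList,
    ref: GroundTruthNetwork,
    selection: GeneSelection | None = None,
) -> tuple[RankedEdgeList, GroundTruthNetwork]:
    """Bring a prediction and a reference onto one comparable edge universe.

    Both networks are restricted to the selection's gene universe (or the
    reference's genes when no selection is given); undirected edges are
    expanded to two directed records; edges not sourced at a TF and
    self-loops are dropped.  Because only TF-sourced edges survive, a
    bidirectional TF <-> non-TF pair collapses to the single TF -> gene
    record (keeping the better weight if duplicates arise), while TF <-> TF
    pairs remain as two distinct edges.  Raises if the reference retains no
    positive edge (EPR would be undefined).
    """
    universe = set(selection.universe) if selection is not None else set(ref.genes)
    tf_set = {t for t in ref.tfs if t in universe}

    # reference side
    ref_edges = set()
    for s, t in ref.edges:
        pairs = [(s, t)] if ref.directed else [(s, t), (t, s)]
        for a, b in pairs:
            if a == b or a not in tf_set or b not in universe:
                continue
            ref_edges.add((a, b))
    if not ref_edges:
        raise ValueError("no positive edges after harmonization; EPR undefined")
    ref_h = GroundTruthNetwork(
        tfs=frozenset(tf_set),
        genes=frozenset(g for g in universe),
        edges=frozenset(ref_edges),
    )

    # prediction side
    df = pred.edges
    keep = (
        df["source"].isin(tf_set)
        & df["target"].isin(universe)
        & (df["source"] != df["target"])
    )
    kept = df.loc[keep, ["source", "target", "weight"]]
    # duplicate (source, target) records cannot normally occur, but if a
    # collapse produces one, the better (larger) weight wins
    kept = (
        kept.sort_values("weight", ascending=False)
        .drop_duplicates(subset=["source", "target"], keep="first")
    )
    pred_h = RankedEdgeList(
        kept, method_tag=pred.method_tag,
        imputation_tag=pred.imputation_tag, directed=True,
    )
    return pred_h, ref_h


def top_k(pred: RankedEdgeList, k: int) -> TopKNetwork:
    """Every predicted edge with rank <= k; ties may report more than k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = pred.edges[pred.edges["rank"] <= k].reset_index(drop=True)
    return TopKNetwork(edges=edges, k=k)


def classify_edges(topk: TopKNetwork, ref: GroundTruthNetwork) -> EdgeClassification:
    """TP/FP partition of the top-k edges and FN reference edges."""
    pred_set = topk.edge_set()
    ref_set = set(ref.edges)
    return EdgeClassification(
        tp=frozenset(pred_set & ref_set),
        fp=frozenset(pred_set - ref_set),
        fn=frozenset(ref_set - pred_set),
        n_reported=topk.n_reported,
    )


def compute_epr(cls: EdgeClassification, ref_density: float) -> ModelMetrics:
    """Early precision and its density-normalized ratio.

    EP = |TP| / n_reported (the reported top-k size, which may exceed k via
    ties); EPR = EP / reference density, 1 being chance level.
    """
    if ref_density <= 0:
        raise ValueError("reference density must be positive")
    if cls.n_reported == 0:
        raise ValueError("no reported edges; EP undefined")
    ep = cls.n_tp / cls.n_reported
    return ModelMetrics(
        ep=ep,
        epr=ep / ref_density,
        density=ref_density,
        n_tp=cls.n_tp,
        n_reported=cls.n_reported,
        k=cls.n_tp + cls.n_fn,
    )


def log2_ratio(metric_imputed: float, metric_unimputed: float) -> float:
    """log2(imputed / unimputed); 0 means no change, sign flips under swap."""
    if metric_imputed <= 0 or metric_unimputed <= 0:
        raise ValueError("log2 ratio requires strictly positive metrics")
    return float(np.log2(metric_imputed / metric_unimputed))


def degree_distribution(topk: TopKNetwork) -> dict:
    """Per node: in-degree + out-degree within the top-k network."""
    degree: dict = {}
    for s, t in topk.edge_set():
        degree[s] = degree.get(s, 0) + 1
        degree[t] = degree.get(t, 0) + 1
    return degree


def candidate_edges(tfs, genes) -> list:
    """The full TF-sourced edge universe (no self-loops), in sorted order."""
    tfs = sorted(tfs)
    genes = sorted(genes)
    return [(s, t) for s in tfs for t in genes if s != t]


def random_ranking(tfs, genes, rng: np.random.Generator) -> RankedEdgeList:
    """Uniform-random weights over the whole candidate edge universe."""
    cand = candidate_edges(tfs, genes)
    weights = rng.random(len(cand))
    df = pd.DataFrame(cand, columns=["source", "target"])
    df["weight"] = weights
    return RankedEdgeList(df, method_tag="random", imputation_tag="none")


def evaluate_model(
    pred: RankedEdgeList,
    ref: GroundTruthNetwork,
    selection: GeneSelection | None = None,
    k: int | None = None,
    baseline_epr: float | None = None,
    baseline_density: float | None = None,
) -> ModelMetrics:
    """Harmonize, cut at top-k, classify and score one model.

    ``k`` defaults to the number of positive edges of the harmonized
    reference.  When a matched unimputed baseline EPR (and optionally its
    top-k predicted density) is supplied, the log2 ratios are filled in.
    """
    pred_h, ref_h = harmonize_networks(pred, ref, selection)
    if len(pred_h) == 0:
        raise ValueError("prediction is empty after harmonization")
    k_eff = k if k is not None else ref_h.n_edges
    tk = top_k(pred_h, k_eff)
    cls = classify_edges(tk, ref_h)
    density = network_density(ref_h.n_edges, len(ref_h.genes), len(ref_h.tfs))
    metrics = compute_epr(cls, density)
    metrics.k = k_eff
    metrics.degree_per_node = degree_distribution(tk)
    if baseline_epr is not None:
        metrics.log2_epr_ratio = log2_ratio(metrics.epr, baseline_epr)
    if baseline_density is not None:
        pred_density = network_density(
            tk.n_reported, len(ref_h.genes), len(ref_h.tfs)
        )
        if pred_density > 0 and baseline_density > 0:
            metrics.log2_density_ratio = log2_ratio(pred_density, baseline_density)
    return metrics
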