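"""Score TF -> gene candidate edges from an expression matrix.

Four scoring families are provided, mirroring the method classes most used
for single-cell network reconstruction: random-forest importance and
gradient-boosted importance (directed, regression-based), mutual information
with per-gene context normalization (undirected, information-based; a
surrogate for partial-information-decomposition scoring), and regularized
Gaussian partial correlation (undirected).  All emit a
:class:`~grnimpact.core.RankedEdgeList` with competition ranks over edge
weights; undirected families emit each kept pair as two directed records
sharing one rank.  Externally produced ranked edge lists (tab-separated
``Gene1  Gene2  EdgeWeight``) are imported via
:func:`load_external_ranked_edges`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics import mutual_info_score

from .core import ExpressionDataset, GeneSelection, RankedEdgeList

__all__ = [
    "infer_tree_importance",
    "infer_boosted",
    "infer_mi_context",
    "infer_partial_correlation",
    "load_external_ranked_edges",
    "mi_bits",
]


def _subset(data: ExpressionDataset, selection: GeneSelection | None):
    """Expression restricted to the selection universe; returns
    (matrix genes x cells, gene ids, tf ids)."""
    if selection is None:
        genes = list(data.gene_ids)
    else:
        universe = set(selection.universe)
        genes = [g for g in data.gene_ids if g in universe]
    idx = [data.gene_index(g) for g in genes]
    expr = data.counts[idx].astype(float)
    tf_set = set(data.tf_ids)
    tfs = [g for g in genes if g in tf_set]
    return expr, genes, tfs


def _tree_edges(data, selection, fit_model, imputation_tag, method_tag):
    expr, genes, tfs = _subset(data, selection)
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs in the selection")
    tf_idx = {g: i for i, g in enumerate(genes) if g in set(tfs)}
    records = []
    for j, target in enumerate(genes):
        predictors = [t for t in tfs if t != target]
        if not predictors:
            continue
        X = expr[[tf_idx[t] for t in predictors]].T
        y = expr[j]
        var_y = float(y.var())
        if var_y == 0:
            importances = np.zeros(len(predictors))
        else:
            model = fit_model(j)
            model.fit(X, y)
            importances = model.feature_importances_ * var_y
        records.extend((t, target, float(w)) for t, w in zip(predictors, importances))
    return RankedEdgeList.from_records(
        records, method_tag=method_tag,
        imputation_tag=imputation_tag, directed=True,
    )


def infer_tree_importance(data: ExpressionDataset, selection: GeneSelection | None = None,
                          n_trees: int = 100, seed: int = 0) -> RankedEdgeList:
    """Random-forest edge importances.

    For each target gene a random-forest regression on all TF expressions
    (the target excluded from its own predictors) is fit; the edge weight of
    TF -> target is the forest's impurity importance scaled by the target's
    variance, so per-target importances are comparable when pooled into one
    global ranking.  A constant target contributes zero-weight edges.
    """
    def make(j):
        return RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt",
            random_state=seed + 7919 * j, n_jobs=1,
        )
    return _tree_edges(data, selection, make, data.layer_tag, "tree")


def infer_boosted(data: ExpressionDataset, selection: GeneSelection | None = None,
                  learning_rate: float = 0.1, n_rounds: int = 100,
                  seed: int = 0) -> RankedEdgeList:
    """Gradient-boosted-tree edge importances with early stopping.

    Same contract as :func:`infer_tree_importance` but each per-target model
    is a gradient-boosted regression stopped early on a held-out validation
    fold.
    """
    def make(j):
        return GradientBoostingRegressor(
            learning_rate=learning_rate, n_estimators=n_rounds,
            validation_fraction=0.1, n_iter_no_change=5,
            random_state=seed + 7919 * j,
        )
    return _tree_edges(data, selection, make, data.layer_tag, "boost")


def mi_bits(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Mutual information in bits between two gene profiles after
    equal-frequency discretization into ``n_bins`` bins.

    A constant gene collapses to one bin and scores 0 by convention.
    Invariant under monotone maps of either argument.
    """
    bx, by = _discretize(np.asarray(x, float), n_bins), _discretize(np.asarray(y, float), n_bins)
    return float(mutual_info_score(bx, by) / np.log(2))


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; a (near-)constant gene collapses to one bin."""
    try:
        binned = pd.qcut(x, n_bins, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(x.size, dtype=int)
    return np.nan_to_num(np.asarray(binned, dtype=float)).astype(int)


def infer_mi_context(data: ExpressionDataset, selection: GeneSelection | None = None,
                     n_bins: int = 8) -> RankedEdgeList:
    """Mutual information with per-gene context normalization.

    Each gene is discretized into equal-frequency bins, mutual information
    (in bits) is computed for every TF-gene pair, and each pair's weight is
    the mean of the two endpoint z-scores of that MI within each endpoint's
    own MI distribution.  Scoring is undirected: each kept pair becomes two
    opposing directed records sharing one rank.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    expr, genes, tfs = _subset(data, selection)
    if len(tfs) < 1:
        raise ValueError("selection contains no TFs")
    binned = np.vstack([_discretize(expr[i], n_bins) for i in range(len(genes))])
    tf_set = set(tfs)

    pairs = [(i, j) for i in range(len(genes)) for j in range(i + 1, len(genes))
             if genes[i] in tf_set or genes[j] in tf_set]
    mi = np.array([
        mutual_info_score(binned[i], binned[j]) / np.log(2) for i, j in pairs
    ])

    per_gene: dict[int, list] = {}
    for (pair_idx, (i, j)) in enumerate(pairs):
        per_gene.setdefault(i, []).append(pair_idx)
        per_gene.setdefault(j, []).append(pair_idx)
    mean_g = {g: float(mi[ix].mean()) for g, ix in per_gene.items()}
    std_g = {g: float(mi[ix].std()) or 1.0 for g, ix in per_gene.items()}

    records = []
    for pair_idx, (i, j) in enumerate(pairs):
        zi = (mi[pair_idx] - mean_g[i]) / std_g[i]
        zj = (mi[pair_idx] - mean_g[j]) / std_g[j]
        w = 0.5 * (zi + zj)
        records.append((genes[i], genes[j], w))
        records.append((genes[j], genes[i], w))
    return RankedEdgeList.from_records(
        records, method_tag="mi", imputation_tag=data.layer_tag, directed=False,
    )


def infer_partial_correlation(data: ExpressionDataset,
                              selection: GeneSelection | None = None,
                              threshold: float = 0.1,
                              shrink: bool = True) -> RankedEdgeList:
    """Gaussian partial correlations above an absolute threshold.

    The precision matrix is estimated by Ledoit-Wolf shrinkage (``shrink=True``,
    the default) or a plain inverse of the sample covariance; partial
    correlations are ``-P_ij / sqrt(P_ii P_jj)``.  Pairs involving at least
    one TF with ``|pcor|`` strictly above ``threshold`` are kept with weight
    ``|pcor|`` and expanded to two directed records.
    """
    expr, genes, tfs = _subset(data, selection)
    if len(tfs) < 1:
        raise ValueError("selection contains no TFs")
    X = expr.T  # cells x genes
    keep = X.std(axis=0) > 0
    if shrink:
        cov = LedoitWolf(assume_centered=False).fit(X[:, keep]).covariance_
    else:
        cov = np.cov(X[:, keep], rowvar=False)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                "sample covariance is singular; enable shrink=True "
                "(Ledoit-Wolf regularization)"
            )
    P = np.linalg.pinv(cov) if shrink else np.linalg.inv(cov)
    d = np.sqrt(np.diag(P))
    pcor_sub = -P / np.outer(d, d)

    kept_idx = np.flatnonzero(keep)
    pcor = np.zeros((len(genes), len(genes)))
    pcor[np.ix_(kept_idx, kept_idx)] = pcor_sub

    tf_set = set(tfs)
    records = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if genes[i] not in tf_set and genes[j] not in tf_set:
                continue
            w = abs(pcor[i, j])
            if w > threshold:  # strictly above, by convention
                records.append((genes[i], genes[j], w))
                records.append((genes[j], genes[i], w))
    return RankedEdgeList.from_records(
        records, method_tag="pcor", imputation_tag=data.layer_tag, directed=False,
    )


def load_external_ranked_edges(path, method_tag: str = "external",
                               imputation_tag: str = "unknown") -> RankedEdgeList:
    """Load an external ranked edge list (``Gene1\\tGene2\\tEdgeWeight`` TSV).

    Ranks are recomputed by competition ranking of the weights in descending
    order; malformed rows, missing weights and duplicate edges are rejected
    with the offending line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["Gene1", "Gene2", "EdgeWeight"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected header {required}, found {list(df.columns[:3])}"
        )
    if df.empty:
        warnings.warn(f"{path}: empty ranked edge list", UserWarning)
        empty = pd.DataFrame(columns=["source", "target", "weight"])
        return RankedEdgeList(empty, method_tag=method_tag,
                              imputation_tag=imputation_tag)
    bad = df.index[pd.to_numeric(df["EdgeWeight"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric or missing EdgeWeight at lines {lines}")
    dup = df.duplicated(subset=["Gene1", "Gene2"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(f"{path}: duplicate (Gene1, Gene2) rows at lines {lines}")
    out = df.rename(columns={"Gene1": "source", "Gene2": "target",
                             "EdgeWeight": "weight"})
    out["weight"] = out["weight"].astype(float)
    return RankedEdgeList(out[["source", "target", "weight"]],
                          method_tag=method_tag, imputation_tag=imputation_tag)
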