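"""Light-weight imputation operators plus an import path for external tools.

Three mechanism families are provided — neighbor aggregation on raw counts,
graph diffusion on normalized data, and empirical-Bayes shrinkage of
gamma-Poisson rates — alongside an identity baseline.  They are deliberately
named by mechanism, not after any published tool: they reproduce the
qualitative behaviour of each family (variance reduction, correlation
smoothing, conservative shrinkage) without claiming numerical equivalence
to any release.  Genuinely imputed matrices from external tools enter the
pipeline through :func:`load_external_imputed`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from .core import ExpressionDataset, ImputationResult

__all__ = [
    "impute_identity",
    "impute_knn_aggregate",
    "impute_diffusion",
    "impute_shrinkage",
    "load_external_imputed",
]


def impute_identity(data: ExpressionDataset) -> ImputationResult:
    """No-op baseline: returns the input matrix unchanged, tagged ``noimp``."""
    return ImputationResult(data.counts.copy().astype(float), "noimp", {})


def _size_factors(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero total count cannot be imputed")
    return lib / np.median(lib)


def impute_knn_aggregate(data: ExpressionDataset, k_neighbors: int = 15) -> ImputationResult:
    """Stepwise nearest-neighbor aggregation of raw counts.

    Follows a doubling schedule: at step s the raw counts of each cell are
    pooled with its ``min(2**s, k_neighbors)`` nearest neighbors (plus
    itself), where distances are Euclidean on median-depth-scaled,
    square-root-transformed partial aggregates — the variance-stabilizing
    transform appropriate for (near-)Poisson counts.  Aggregates from the
    previous step define the distances of the next, so neighborhoods sharpen
    as smoothing proceeds.  The result is rescaled to each cell's original
    depth.  ``k_neighbors=0`` is the identity.
    """
    if data.layer_tag != "raw":
        raise ValueError("neighbor aggregation operates on raw counts")
    if k_neighbors < 0:
        raise ValueError("k_neighbors must be >= 0")
    if k_neighbors >= data.n_cells:
        raise ValueError("k_neighbors must be smaller than the number of cells")

    X = data.counts.astype(float)
    params = {"k_neighbors": k_neighbors}
    if k_neighbors == 0:
        return ImputationResult(X, "knn_aggregate", params)

    agg = X.copy()
    s = 1
    while True:
        k_s = min(2 ** s, k_neighbors)
        lib = agg.sum(axis=0)
        med = np.median(lib)
        scaled = np.sqrt(agg * (med / lib)[None, :])
        # pairwise Euclidean distances between cells on the stabilized scale
        sq = (scaled ** 2).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2.0 * scaled.T @ scaled
        np.fill_diagonal(d2, -np.inf)  # self excluded, re-added below
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors = order[:, 1:k_s + 1]  # first entry is self (-inf)
        agg = X.copy()
        for j in range(data.n_cells):
            agg[:, j] += X[:, neighbors[j]].sum(axis=1)
        if k_s == k_neighbors:
            break
        s += 1

    # aggregated profile, renormalized to each cell's original median-scaled depth
    lib_orig = X.sum(axis=0)
    med_orig = np.median(lib_orig)
    lib_agg = agg.sum(axis=0)
    out = agg * (med_orig / lib_agg)[None, :]
    return ImputationResult(out, "knn_aggregate", params)


def diffusion_operator(data: ExpressionDataset, knn: int = 15,
                       n_components: int = 20) -> np.ndarray:
    """Row-stochastic Markov matrix over cells from an adaptive Gaussian
    kernel on the top principal components.

    The kernel bandwidth of each cell is its distance to its ``knn``-th
    neighbor; the kernel is symmetrized (K + K.T) so disconnected kNN
    components still communicate, then row-normalized.
    """
    if knn >= data.n_cells:
        raise ValueError("knn must be smaller than the number of cells")
    n_components = min(n_components, data.n_genes, data.n_cells - 1)
    pcs = PCA(n_components=n_components, random_state=0).fit_transform(data.counts.T)
    sq = (pcs ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * pcs @ pcs.T, 0.0)
    d = np.sqrt(d2)
    sigma = np.sort(d, axis=1)[:, knn]
    sigma[sigma == 0] = np.finfo(float).eps
    K = np.exp(-(d / sigma[:, None]) ** 2)
    K = K + K.T
    M = K / K.sum(axis=1, keepdims=True)
    return M


def impute_diffusion(data: ExpressionDataset, knn: int = 15, t: int = 3,
                     n_components: int = 20) -> ImputationResult:
    """Graph-diffusion smoothing of normalized expression.

    Expression is propagated ``t`` steps along the cell-cell Markov matrix
    of :func:`diffusion_operator`; ``t=0`` is the identity and large ``t``
    drives every gene toward its stationary-weighted mean across cells.
    """
    if data.layer_tag != "normalized":
        raise ValueError("diffusion operates on the normalized layer")
    if t < 0:
        raise ValueError("t must be >= 0")
    params = {"knn": knn, "t": t, "n_components": n_components}
    if t == 0:
        return ImputationResult(data.counts.copy(), "diffusion", params)
    M = diffusion_operator(data, knn=knn, n_components=n_components)
    Mt = np.linalg.matrix_power(M, t)
    out = np.clip(data.counts @ Mt.T, 0.0, None)
    return ImputationResult(out, "diffusion", params)


def impute_shrinkage(data: ExpressionDataset, prior_strength: float = 1.0,
                     ridge_alpha: float = 1.0) -> ImputationResult:
    """Gamma-Poisson posterior-mean shrinkage of per-gene rates.

    Models each raw count as Poisson(size_factor x rate) with a gamma prior
    on the rate centered on a cross-gene prediction: each gene's normalized
    profile is ridge-regressed on all other genes, and the fit (back on the
    rate scale) serves as the prior mean.  The posterior mean rate is

        (count + prior_strength * predicted_rate) / (size_factor + prior_strength)

    so ``prior_strength -> 0`` recovers the normalized raw counts and
    ``prior_strength -> inf`` returns the predictions.  Output is on the
    normalized (log1p, median-depth) scale.
    """
    if data.layer_tag != "raw":
        raise ValueError("shrinkage operates on raw counts with size factors")
    if prior_strength < 0:
        raise ValueError("prior_strength must be >= 0")
    s = _size_factors(data.counts)
    rate = data.counts / s[None, :]
    Y = np.log1p(rate)  # genes x cells, normalized scale
    params = {"prior_strength": prior_strength, "ridge_alpha": ridge_alpha}

    if prior_strength == 0:
        return ImputationResult(Y, "shrinkage", params)

    n_genes = data.n_genes
    pred = np.empty_like(Y)
    for g in range(n_genes):
        mask = np.arange(n_genes) != g
        model = Ridge(alpha=ridge_alpha)
        model.fit(Y[mask].T, Y[g])
        pred[g] = model.predict(Y[mask].T)
    mu = np.clip(np.expm1(pred), 0.0, None)

    post_rate = (data.counts + prior_strength * mu) / (s + prior_strength)[None, :]
    return ImputationResult(np.log1p(post_rate), "shrinkage", params)


def load_external_imputed(path, method_name: str,
                          data: ExpressionDataset) -> ImputationResult:
    """Load a genes x cells CSV produced by an external imputation tool.

    The file must cover exactly the dataset's genes and cells (any order);
    mismatches are reported by name, and negative or non-finite entries are
    rejected.
    """
    df = pd.read_csv(path, index_col=0)
    missing_genes = [g for g in data.gene_ids if g not in df.index]
    extra_genes = [g for g in df.index if g not in set(data.gene_ids)]
    if missing_genes or extra_genes:
        raise ValueError(
            f"gene mismatch in {path}: missing {missing_genes[:10]}, "
            f"unexpected {extra_genes[:10]}"
        )
    missing_cells = [c for c in data.cell_ids if c not in df.columns]
    extra_cells = [c for c in df.columns if c not in set(data.cell_ids)]
    if missing_cells or extra_cells:
        raise ValueError(
            f"cell mismatch in {path}: missing {missing_cells[:10]}, "
            f"unexpected {extra_cells[:10]}"
        )
    matrix = df.loc[data.gene_ids, data.cell_ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError(f"non-finite entries in {path}")
    if matrix.min() < 0:
        raise ValueError(f"negative entries in {path}")
    return ImputationResult(matrix, f"external:{method_name}", {"path": str(path)})
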