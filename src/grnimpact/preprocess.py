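"""Normalization and gene selection.

The gene universe for network inference is the union of the top-N genes
most variable across pseudotime — ranked by the deviance explained by a
smooth additive (regression-spline) fit of expression on pseudotime — and
the TFs whose pseudotime trend is significant after Bonferroni correction
across TFs (family-wise alpha 0.01 by default).  The identical universe is
applied to every imputation layer of a dataset, so imputed and unimputed
networks are always compared over the same genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .core import ExpressionDataset, GeneSelection

__all__ = ["normalize", "fit_pseudotime_trend", "select_genes"]


def normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Depth-normalize raw counts: scale each cell to the median library
    size, then log1p.

    Cells with zero total count cannot be scaled and are rejected with a
    diagnostic naming the offending cells.
    """
    if data.layer_tag != "raw":
        raise ValueError("normalize expects the raw integer layer")
    lib = data.counts.sum(axis=0).astype(float)
    zero_cells = [c for c, s in zip(data.cell_ids, lib) if s == 0]
    if zero_cells:
        raise ValueError(
            "cannot normalize cells with zero total count: "
            + ", ".join(map(str, zero_cells[:10]))
            + ("..." if len(zero_cells) > 10 else "")
        )
    median_lib = float(np.median(lib))
    scaled = data.counts * (median_lib / lib)[None, :]
    return data.with_matrix(np.log1p(scaled), layer_tag="normalized")


def _spline_basis(pseudotime: np.ndarray, n_knots: int = 6, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix (with intercept column) on pseudotime.

    Interior knots at quantiles of the observed pseudotime; boundary knots
    replicated per the usual B-spline convention.
    """
    t = np.asarray(pseudotime, dtype=float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        return np.ones((t.size, 1))
    interior = np.quantile(t, np.linspace(0, 1, n_knots)[1:-1])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    design = np.empty((t.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        design[:, j] = BSpline(knots, coef, degree, extrapolate=False)(t)
    design = np.nan_to_num(design)
    return np.column_stack([np.ones(t.size), design[:, 1:]])  # drop one for identifiability


def _trend_stats(Y: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized spline fit of many genes (rows of Y) on one shared basis.

    Returns per-gene (deviance explained, F-test p against intercept-only).
    Constant genes yield (0, 1); an exact fit yields p = 0.
    """
    n = basis.shape[0]
    coef, _, rank, _ = np.linalg.lstsq(basis, Y.T, rcond=None)
    resid = Y.T - basis @ coef
    rss = (resid ** 2).sum(axis=0)
    centered = Y.T - Y.T.mean(axis=0)
    tss = (centered ** 2).sum(axis=0)

    safe_tss = np.where(tss > 0, tss, 1.0)
    dev = np.where(tss > 0, np.clip(1.0 - rss / safe_tss, 0.0, 1.0), 0.0)

    df_model = rank - 1
    df_resid = n - rank
    p = np.ones_like(rss)
    if df_model > 0 and df_resid > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((tss - rss) / df_model) / (rss / df_resid)
        ok = (tss > 0) & (rss > 0)
        p = np.where(ok, stats.f.sf(np.where(ok, f_stat, 0.0), df_model, df_resid), p)
        p = np.where((tss > 0) & (rss <= 0), 0.0, p)  # exact fit
    return dev, p


def fit_pseudotime_trend(expr: np.ndarray, pseudotime: np.ndarray,
                         basis: np.ndarray | None = None) -> tuple[float, float]:
    """Smooth additive fit of one gene's expression on pseudotime.

    Regresses expression on a cubic B-spline basis (6 knots) plus intercept
    and compares against the intercept-only null with an F test.  Returns
    ``(deviance_explained, p_value)``; a constant gene yields ``(0.0, 1.0)``.
    """
    y = np.asarray(expr, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if y.size != t.size:
        raise ValueError("expression and pseudotime lengths differ")
    if y.size < 10:
        raise ValueError("need at least 10 cells to fit a pseudotime trend")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValueError("expression and pseudotime must be finite")
    X = _spline_basis(t) if basis is None else basis
    dev, p = _trend_stats(y[None, :], X)
    return float(dev[0]), float(p[0])


def select_genes(data: ExpressionDataset, n_top: int = 500,
                 alpha: float = 0.01) -> GeneSelection:
    """Select the inference gene universe from a normalized dataset.

    Highly variable genes (HVGs) are the ``n_top`` genes with the largest
    deviance explained by the pseudotime-trend fit; significantly varying
    TFs are those with Bonferroni-corrected trend p-value below ``alpha``
    (correction over the TF family only).  The returned universe is the
    union of the two lists.
    """
    if data.layer_tag != "normalized":
        raise ValueError("select_genes expects a normalized layer")
    basis = _spline_basis(data.pseudotime)
    dev, p = _trend_stats(np.asarray(data.counts, dtype=float), basis)
    stats_df = pd.DataFrame({
        "gene": data.gene_ids,
        "is_tf": data.tf_flags,
        "deviance_explained": dev,
        "p_value": p,
    })

    n_tf = int(stats_df["is_tf"].sum())
    stats_df["p_bonferroni"] = np.where(
        stats_df["is_tf"], np.minimum(1.0, stats_df["p_value"] * max(n_tf, 1)), np.nan
    )

    if n_top > len(stats_df):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(stats_df)} available genes; "
            "selecting all genes", UserWarning,
        )
    ordered = stats_df.sort_values(
        ["deviance_explained", "gene"], ascending=[False, True], kind="mergesort"
    )
    hvg_ids = ordered["gene"].head(n_top).tolist()

    sig = stats_df[stats_df["is_tf"] & (stats_df["p_bonferroni"] < alpha)]
    sig_tf_ids = sorted(sig["gene"].tolist())

    return GeneSelection(hvg_ids=hvg_ids, sig_tf_ids=sig_tf_ids,
                         n_top=n_top, alpha=alpha, stats=stats_df)
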