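"""Cross-model structure comparisons.

Beyond per-model precision, the pipeline compares the *structure* of the
networks produced by each (imputation x inference-method) model: Jaccard
overlap of top-ranked edge sets with hierarchical clustering and
adjusted-Rand purity against annotation labels, a variance decomposition of
EPR log2 ratios across the two experimental factors, rank shifts of
true-positive edges after imputation, and per-class (TP/FP/FN) regressions
of gene-gene correlation before vs after imputation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core import EdgeClassification, ExpressionDataset, RankedEdgeList

__all__ = [
    "jaccard_similarity",
    "similarity_matrix",
    "cluster_models",
    "cluster_purity_ari",
    "variance_by_factor",
    "VarianceDecomposition",
    "rank_shift",
    "correlation_class_regression",
    "CorrelationClassTable",
]


def jaccard_similarity(edges_a, edges_b) -> float:
    """Intersection over union of two edge sets; 1 (with a warning) when
    both are empty."""
    a, b = set(edges_a), set(edges_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty edge sets defined as 1", UserWarning)
        return 1.0
    return len(a & b) / len(union)


def similarity_matrix(edge_sets: dict, top_n: int | None = None) -> pd.DataFrame:
    """Pairwise Jaccard matrix over models.

    ``edge_sets`` maps a model label to either a set of directed edges or a
    :class:`RankedEdgeList` (cut to its ``top_n`` best-ranked edges when
    ``top_n`` is given).
    """
    def as_set(v):
        if isinstance(v, RankedEdgeList):
            df = v.edges
            if top_n is not None:
                df = df[df["rank"] <= top_n]
            return set(zip(df["source"], df["target"]))
        return set(v)

    labels = list(edge_sets)
    sets = {m: as_set(v) for m, v in edge_sets.items()}
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        j = jaccard_similarity(sets[a], sets[b])
        mat.loc[a, b] = mat.loc[b, a] = j
    return mat


def cluster_models(sim: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Agglomerative (average-linkage) clustering of models on 1 - Jaccard.

    Returns integer labels indexed by model; invariant to model order.
    """
    if len(sim) < 2:
        raise ValueError("need at least 2 models to cluster")
    if n_clusters > len(sim):
        raise ValueError("n_clusters exceeds the number of models")
    order = sorted(sim.index)
    sim = sim.loc[order, order]
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=order, name="cluster")


def cluster_purity_ari(labels_found, labels_annotation) -> float:
    """Adjusted Rand index between a clustering and an annotation label.

    Standard pair-counting ARI with expected-index correction: 1 for
    identical partitions (up to relabeling), ~0 at chance.
    """
    a = list(labels_found)
    b = list(labels_annotation)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) < 2:
        raise ValueError("ARI needs at least 2 elements")
    return float(adjusted_rand_score(b, a))


@dataclass
class VarianceDecomposition:
    """Which factor — imputation or inference method — drives EPR changes.

    ``var_across_imputation`` holds, per (dataset, fixed GRN method), the
    variance of log2 EPR ratios across imputations; ``var_across_grn`` the
    converse.  A two-sided Wilcoxon rank-sum test compares the two variance
    collections, and a per-dataset two-way ANOVA (sequential sums of
    squares, factor order GRN then imputation) attributes the variance.
    """

    var_across_imputation: pd.DataFrame
    var_across_grn: pd.DataFrame
    ranksum_statistic: float
    ranksum_p: float
    anova_tables: dict = field(default_factory=dict)


def variance_by_factor(metrics: pd.DataFrame) -> VarianceDecomposition:
    """Variance decomposition of log2 EPR ratios over a factorial grid.

    ``metrics`` must be tidy with columns ``dataset``, ``imputation``,
    ``grn_method`` and ``log2_epr_ratio``, and must contain every
    (imputation x GRN) combination for every dataset; missing cells are an
    error listing the offenders.
    """
    required = {"dataset", "imputation", "grn_method", "log2_epr_ratio"}
    missing_cols = required - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table missing columns: {sorted(missing_cols)}")

    datasets = sorted(metrics["dataset"].unique())
    imps = sorted(metrics["imputation"].unique())
    grns = sorted(metrics["grn_method"].unique())
    have = set(zip(metrics["dataset"], metrics["imputation"], metrics["grn_method"]))
    missing = [c for c in itertools.product(datasets, imps, grns) if c not in have]
    if missing:
        raise ValueError(f"incomplete factorial grid; missing cells: {missing[:10]}")

    var_imp = (
        metrics.groupby(["dataset", "grn_method"])["log2_epr_ratio"]
        .var(ddof=1).rename("variance").reset_index()
    )
    var_grn = (
        metrics.groupby(["dataset", "imputation"])["log2_epr_ratio"]
        .var(ddof=1).rename("variance").reset_index()
    )
    stat, p = stats.ranksums(var_imp["variance"], var_grn["variance"])

    anova_tables = {}
    for ds, sub in metrics.groupby("dataset"):
        model = smf.ols(
            "log2_epr_ratio ~ C(grn_method) + C(imputation)", data=sub
        ).fit()
        anova_tables[ds] = sm.stats.anova_lm(model, typ=1)

    return VarianceDecomposition(
        var_across_imputation=var_imp,
        var_across_grn=var_grn,
        ranksum_statistic=float(stat),
        ranksum_p=float(p),
        anova_tables=anova_tables,
    )


def rank_shift(tp_edges_unimputed, ranking_imputed: RankedEdgeList,
               ranking_unimputed: RankedEdgeList | None = None,
               universe_size: int | None = None) -> pd.DataFrame:
    """Where do the baseline's true-positive edges land after imputation?

    For each TP edge of the unimputed top-k network, reports its rank in the
    imputed full ranking (``rank_after``) and, when the unimputed ranking is
    supplied, its original rank and the shift ``rank_after - rank_before``.
    Edges absent from the imputed ranking get rank ``universe_size + 1``
    (default: the imputed list length + 1) and are flagged.
    """
    rank_after = ranking_imputed.rank_of()
    rank_before = ranking_unimputed.rank_of() if ranking_unimputed else {}
    sentinel = (universe_size if universe_size is not None
                else len(ranking_imputed)) + 1
    rows = []
    for edge in sorted(tp_edges_unimputed):
        after = rank_after.get(edge)
        row = {
            "source": edge[0],
            "target": edge[1],
            "rank_after": after if after is not None else sentinel,
            "missing_after": after is None,
        }
        if ranking_unimputed is not None:
            before = rank_before.get(edge)
            row["rank_before"] = before
            row["shift"] = (row["rank_after"] - before
                            if before is not None else np.nan)
        rows.append(row)
    cols = ["source", "target", "rank_after", "missing_after"]
    if ranking_unimputed is not None:
        cols += ["rank_before", "shift"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CorrelationClassTable:
    """Per-edge |correlation| before/after imputation and per-class OLS lines.

    Each classified edge (TP/FP/FN) contributes one point; the fitted
    ``|corr_after| ~ |corr_before|`` line summarizes how imputation moved
    each class.  Classes with fewer than 2 usable edges get no line and are
    flagged, as are edges whose correlation is undefined (constant gene).
    """

    table: pd.DataFrame
    lines: pd.DataFrame  # per class: slope, intercept, n
    excluded: list = field(default_factory=list)


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlation_class_regression(
    data_before: ExpressionDataset,
    data_after: ExpressionDataset,
    cls: EdgeClassification,
) -> CorrelationClassTable:
    """Gene-gene correlation before vs after imputation, by prediction class.

    For every TP/FP/FN edge, the absolute Pearson correlation of its two
    genes is computed on the pre- and post-imputation layers, and an
    ordinary-least-squares line is fit per class on (|before|, |after|).
    Edges touching a constant gene have undefined correlation and are
    excluded from the regression (reported in ``excluded``).
    """
    rows, excluded = [], []
    classes = [("TP", cls.tp), ("FP", cls.fp), ("FN", cls.fn)]
    for label, edges in classes:
        for s, t in sorted(edges):
            try:
                i, j = data_before.gene_index(s), data_before.gene_index(t)
            except ValueError:
                excluded.append((s, t, "gene not in expression matrix"))
                continue
            c_before = _pearson(data_before.counts[i], data_before.counts[j])
            c_after = _pearson(data_after.counts[i], data_after.counts[j])
            if c_before is None or c_after is None:
                excluded.append((s, t, "constant gene; correlation undefined"))
                continue
            rows.append({
                "source": s, "target": t, "class": label,
                "corr_before": abs(c_before), "corr_after": abs(c_after),
            })
    table = pd.DataFrame(rows, columns=["source", "target", "class",
                                        "corr_before", "corr_after"])

    line_rows = []
    for label, _ in classes:
        sub = table[table["class"] == label]
        if len(sub) < 2 or sub["corr_before"].std() == 0:
            line_rows.append({"class": label, "slope": np.nan,
                              "intercept": np.nan, "n": len(sub)})
            continue
        res = stats.linregress(sub["corr_before"], sub["corr_after"])
        line_rows.append({"class": label, "slope": float(res.slope),
                          "intercept": float(res.intercept), "n": len(sub)})
    lines = pd.DataFrame(line_rows).set_index("class")
    return CorrelationClassTable(table=table, lines=lines, excluded=excluded)
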