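"""Plain-text readers and writers for the pipeline's interchange formats.

Counts travel as genes x cells CSV (header = cell ids, first column = gene
ids) with optional MatrixMarket output; networks as two-column TSV edge
lists (``Gene1\\tGene2``, optional ``Type`` column marking undirected
references); ranked edges in the ``Gene1\\tGene2\\tEdgeWeight`` dialect;
pseudotime as a two-column CSV; gene/TF lists as one identifier per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .core import ExpressionDataset, GroundTruthNetwork, RankedEdgeList

__all__ = [
    "write_counts_csv", "read_counts_csv",
    "write_counts_mtx",
    "write_pseudotime_csv", "read_pseudotime_csv",
    "write_gene_list", "read_gene_list",
    "write_network_tsv", "read_network_tsv",
    "write_ranked_edges_tsv",
    "write_dataset",
]


def write_counts_csv(data: ExpressionDataset, path) -> None:
    data.to_frame().to_csv(path, index_label="gene")


def read_counts_csv(path, tf_ids=None, pseudotime=None,
                    layer_tag: str = "raw") -> ExpressionDataset:
    """Load a genes x cells CSV; TF flags and pseudotime are attached from
    the given TF id list and per-cell pseudotime (defaults: no TFs, uniform
    pseudotime grid)."""
    df = pd.read_csv(path, index_col=0)
    gene_ids = list(df.index.astype(str))
    cell_ids = list(df.columns.astype(str))
    tf_set = set(tf_ids) if tf_ids is not None else set()
    tf_flags = np.array([g in tf_set for g in gene_ids])
    if pseudotime is None:
        pseudotime = np.linspace(0.0, 1.0, len(cell_ids))
    return ExpressionDataset(df.to_numpy(), gene_ids, tf_flags,
                             np.asarray(pseudotime, dtype=float),
                             layer_tag=layer_tag, cell_ids=cell_ids)


def write_counts_mtx(data: ExpressionDataset, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx plus gene/cell TSVs."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(data.counts))
    prefix.with_name(prefix.name + "_genes.tsv").write_text(
        "\n".join(map(str, data.gene_ids)) + "\n")
    prefix.with_name(prefix.name + "_cells.tsv").write_text(
        "\n".join(map(str, data.cell_ids)) + "\n")


def write_pseudotime_csv(data: ExpressionDataset, path) -> None:
    pd.DataFrame({"cell": data.cell_ids, "pseudotime": data.pseudotime}
                 ).to_csv(path, index=False)


def read_pseudotime_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="pseudotime")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + ("\n" if len(genes) else ""))


def read_gene_list(path) -> list:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_network_tsv(net: GroundTruthNetwork, path) -> None:
    df = pd.DataFrame(sorted(net.edges), columns=["Gene1", "Gene2"])
    df["Type"] = "directed" if net.directed else "undirected"
    df.to_csv(path, sep="\t", index=False)


def read_network_tsv(path, tfs=None) -> GroundTruthNetwork:
    """Edge-list TSV -> reference network.

    The TF set defaults to the set of edge sources; an optional ``Type``
    column with any ``undirected`` entry marks the whole network undirected.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"Gene1", "Gene2"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns Gene1 and Gene2")
    edges = frozenset(zip(df["Gene1"].astype(str), df["Gene2"].astype(str)))
    directed = True
    if "Type" in df.columns and (df["Type"].astype(str) == "undirected").any():
        directed = False
    sources = {s for s, _ in edges}
    tf_set = frozenset(map(str, tfs)) if tfs is not None else frozenset(sources)
    genes = frozenset(g for e in edges for g in e) | tf_set
    return GroundTruthNetwork(tfs=tf_set, genes=genes, edges=edges,
                              directed=directed)


def write_ranked_edges_tsv(ranked: RankedEdgeList, path) -> None:
    """BEELINE-compatible ``Gene1\\tGene2\\tEdgeWeight``, sorted by rank."""
    out = ranked.edges.rename(columns={"source": "Gene1", "target": "Gene2",
                                       "weight": "EdgeWeight"})
    out[["Gene1", "Gene2", "EdgeWeight"]].to_csv(path, sep="\t", index=False)


def write_dataset(data: ExpressionDataset, net: GroundTruthNetwork,
                  outdir, mtx: bool = False) -> None:
    """Persist a simulated dataset: counts, pseudotime, TF list, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_csv(data, outdir / "counts.csv")
    write_pseudotime_csv(data, outdir / "pseudotime.csv")
    write_gene_list(data.tf_ids, outdir / "tfs.txt")
    write_network_tsv(net, outdir / "ground_truth.tsv")
    if mtx:
        write_counts_mtx(data, outdir / "counts")
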