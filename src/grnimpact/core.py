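"""Core domain types shared across the pipeline.

The pipeline's substrate is a genes x cells expression matrix with per-gene
transcription-factor (TF) annotation and a per-cell pseudotime, evaluated
against a directed TF -> gene reference network.  Candidate networks are
scored, rank-annotated edge lists; all evaluation happens on "top-k"
subnetworks, where k is the number of positive edges in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SimulationConfig",
    "GroundTruthNetwork",
    "ExpressionDataset",
    "GeneSelection",
    "ImputationResult",
    "RankedEdgeList",
    "TopKNetwork",
    "EdgeClassification",
    "ModelMetrics",
    "MotifInstance",
    "MotifClassification",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic single-cell experiment.

    Parameters
    ----------
    n_tfs, n_genes, n_cells
        Grid dimensions; ``n_genes`` counts all genes including TFs.
    edges_per_gene
        Mean in-degree of the ground-truth network (regulators per gene).
    effect_size
        Scale of regulatory weights; 0 disconnects targets from their
        regulators (a pure null model).
    dispersion
        Negative-binomial overdispersion (gamma-Poisson shape = 1/dispersion);
        0 degenerates to Poisson.
    dropout_strength
        Rate of mean-dependent extra zeros: each entry is zeroed with
        probability exp(-dropout_strength * mean).  0 disables dropout.
    library_sigma
        Log-normal sigma of per-cell library-size factors.
    seed
        Base seed for the generator; the whole simulation is reproducible.
    """

    n_tfs: int = 10
    n_genes: int = 100
    n_cells: int = 300
    edges_per_gene: float = 2.0
    effect_size: float = 2.0
    dispersion: float = 0.3
    dropout_strength: float = 0.3
    library_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs < 1:
            raise ValueError("n_tfs must be >= 1 (an empty TF set cannot emit edges)")
        if self.n_genes <= self.n_tfs:
            raise ValueError("n_genes must exceed n_tfs")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        for name in ("edges_per_gene", "effect_size", "dispersion",
                     "dropout_strength", "library_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.edges_per_gene <= 0:
            raise ValueError("edges_per_gene must be positive")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Directed TF -> gene reference network used as evaluation truth.

    Every edge source is a TF, there are no self-loops, and the edge set is
    duplicate-free.  ``k`` (the number of positive edges) is what the top-k
    evaluation keys on.
    """

    tfs: frozenset
    genes: frozenset
    edges: frozenset  # of (source, target) ordered pairs
    directed: bool = True

    def __post_init__(self):
        if not self.tfs <= self.genes:
            raise ValueError("TF set must be a subset of the gene set")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-loop {s}->{t} not allowed")
            if s not in self.tfs:
                raise ValueError(f"edge source {s} is not a TF")
            if t not in self.genes:
                raise ValueError(f"edge target {t} is not a known gene")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        from .evaluate import network_density

        return network_density(len(self.edges), len(self.genes), len(self.tfs))


class ExpressionDataset:
    """Genes x cells expression matrix with TF flags and pseudotime.

    ``layer_tag`` records provenance: ``raw`` (integer counts), ``normalized``
    (depth-scaled log1p) or ``imputed:<method>``.  The simulator additionally
    attaches the latent (noise-free) rate matrix under ``latent`` so that
    tests can interrogate the signal before the count noise model.
    """

    def __init__(
        self,
        counts: np.ndarray,
        gene_ids: Sequence[str],
        tf_flags: np.ndarray,
        pseudotime: np.ndarray,
        layer_tag: str = "raw",
        cell_ids: Sequence[str] | None = None,
        latent: np.ndarray | None = None,
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = counts.shape
        if len(gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        tf_flags = np.asarray(tf_flags, dtype=bool)
        if tf_flags.shape != (n_genes,):
            raise ValueError("tf_flags length does not match matrix rows")
        pseudotime = np.asarray(pseudotime, dtype=float)
        if pseudotime.shape != (n_cells,):
            raise ValueError("pseudotime length does not match matrix columns")
        if not np.all(np.isfinite(pseudotime)):
            raise ValueError("pseudotime must be finite")
        if not np.all(np.isfinite(counts)):
            raise ValueError("expression values must be finite")
        if counts.min() < 0:
            raise ValueError("expression values must be non-negative")
        if layer_tag == "raw" and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("raw layer must hold integer counts")
            counts = counts.astype(np.int64)
        self.counts = counts
        self.gene_ids = list(gene_ids)
        self.tf_flags = tf_flags
        self.pseudotime = pseudotime
        self.layer_tag = layer_tag
        self.cell_ids = (
            list(cell_ids) if cell_ids is not None
            else [f"cell{i}" for i in range(n_cells)]
        )
        self.latent = latent

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def tf_ids(self) -> list:
        return [g for g, f in zip(self.gene_ids, self.tf_flags) if f]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def with_matrix(self, matrix: np.ndarray, layer_tag: str) -> "ExpressionDataset":
        """Same annotation, new expression layer."""
        return ExpressionDataset(
            matrix, self.gene_ids, self.tf_flags, self.pseudotime,
            layer_tag=layer_tag, cell_ids=self.cell_ids, latent=self.latent,
        )


@dataclass
class GeneSelection:
    """Gene universe used for network inference and evaluation.

    The union of the top ``n_top`` most pseudotime-variable genes and the TFs
    whose pseudotime trend survives Bonferroni correction at level ``alpha``.
    The same selection is applied to every imputation layer of a dataset so
    that imputed and unimputed models are compared on equal footing.
    """

    hvg_ids: list
    sig_tf_ids: list
    n_top: int
    alpha: float
    stats: pd.DataFrame  # per gene: deviance_explained, p_value, p_bonferroni

    @property
    def universe(self) -> list:
        seen, out = set(), []
        for g in list(self.hvg_ids) + list(self.sig_tf_ids):
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out


@dataclass
class ImputationResult:
    """Output of one imputation operator: same shape, tagged by mechanism."""

    matrix: np.ndarray
    method_tag: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("imputed matrix must be finite")
        if self.matrix.min() < 0:
            raise ValueError("imputed matrix must be non-negative")


def competition_ranks(weights: np.ndarray) -> np.ndarray:
    """Competition ("min") ranks of weights in descending order.

    The best (largest) weight gets rank 1; equal weights share the smallest
    rank of their block, and the following rank is skipped accordingly
    (weights [5, 4, 4, 3] -> ranks [1, 2, 2, 4]).
    """
    w = np.asarray(weights, dtype=float)
    if w.size and not np.all(np.isfinite(w)):
        raise ValueError("edge weights must be finite")
    return rankdata(-w, method="min").astype(int)


class RankedEdgeList:
    """Scored, rank-annotated candidate edges from one model.

    Ranks follow competition ranking of weights in descending order; tied
    weights share a rank.  Undirected methods emit each kept pair as two
    directed records sharing one weight and rank.
    """

    COLUMNS = ("source", "target", "weight", "rank")

    def __init__(
        self,
        edges: pd.DataFrame,
        method_tag: str = "unknown",
        imputation_tag: str = "unknown",
        directed: bool = True,
    ):
        edges = edges.reset_index(drop=True)
        missing = [c for c in ("source", "target", "weight") if c not in edges.columns]
        if missing:
            raise ValueError(f"edge table is missing columns: {missing}")
        if (edges["source"] == edges["target"]).any():
            raise ValueError("self-loops are not allowed in a ranked edge list")
        if edges.duplicated(subset=["source", "target"]).any():
            dupes = edges[edges.duplicated(subset=["source", "target"], keep=False)]
            raise ValueError(
                "duplicate (source, target) records: "
                + ", ".join(f"{s}->{t}" for s, t in
                            dupes[["source", "target"]].drop_duplicates().itertuples(index=False))
            )
        edges = edges.copy()
        edges["rank"] = competition_ranks(edges["weight"].to_numpy())
        self.edges = edges.sort_values(["rank", "source", "target"]).reset_index(drop=True)
        self.method_tag = method_tag
        self.imputation_tag = imputation_tag
        self.directed = directed

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(zip(self.edges["source"], self.edges["target"]))

    def rank_of(self) -> Mapping[tuple, int]:
        return dict(zip(zip(self.edges["source"], self.edges["target"]),
                        self.edges["rank"]))

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
        **kwargs,
    ) -> "RankedEdgeList":
        """Build from (source, target, weight) triples."""
        df = pd.DataFrame(records, columns=["source", "target", "weight"])
        return cls(df, **kwargs)


@dataclass
class TopKNetwork:
    """All predicted edges with rank <= k.

    Because tied weights share a rank, the number of reported edges
    ``n_reported`` may exceed k.
    """

    edges: pd.DataFrame
    k: int

    @property
    def n_reported(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(zip(self.edges["source"], self.edges["target"]))


@dataclass
class EdgeClassification:
    """TP/FP partition of a top-k network plus the missed reference edges."""

    tp: frozenset
    fp: frozenset
    fn: frozenset
    n_reported: int

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


@dataclass
class ModelMetrics:
    """Early-precision metrics of one model on one dataset.

    ``ep`` is the fraction of true positives among the reported top-k edges;
    ``epr = ep / density`` of the reference, so 1 is chance level.  Log2
    ratios compare an imputed model to its matched unimputed baseline.
    """

    ep: float
    epr: float
    density: float
    n_tp: int
    n_reported: int
    k: int
    log2_epr_ratio: float | None = None
    log2_density_ratio: float | None = None
    degree_per_node: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MotifInstance:
    """Ordered triple X -> Y -> Z; a chain lacks the shortcut X -> Z, a
    feed-forward loop (ffl) has it."""

    x: str
    y: str
    z: str
    kind: str  # "chain" | "ffl"

    def __post_init__(self):
        if len({self.x, self.y, self.z}) != 3:
            raise ValueError("motif genes must be distinct")
        if self.kind not in ("chain", "ffl"):
            raise ValueError(f"unknown motif kind {self.kind!r}")


@dataclass
class MotifClassification:
    """Chain-motif confusion counts of a predicted network vs the reference.

    TP: chain in both.  FP: predicted chain that is a loop in the reference.
    FN: predicted loop that is a chain in the reference.  Motifs whose
    backbone (X->Y, Y->Z) is absent from the reference are unclassifiable and
    excluded from the rates; rates with zero denominator are ``None``.
    """

    tp_chains: list
    fp_chains: list
    fn_chains: list
    tp_loops: list
    unclassifiable: list

    @property
    def n_tp(self) -> int:
        return len(self.tp_chains)

    @property
    def n_fp(self) -> int:
        return len(self.fp_chains)

    @property
    def n_fn(self) -> int:
        return len(self.fn_chains)

    @property
    def tpr(self) -> float | None:
        denom = self.n_tp + self.n_fn
        return self.n_tp / denom if denom else None

    @property
    def fdr(self) -> float | None:
        denom = self.n_tp + self.n_fp
        return self.n_fp / denom if denom else None
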