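"""Full factorial experiment: datasets x imputations x inference methods.

``run_experiment`` simulates (or loads) each dataset, fixes one gene
selection per dataset, produces every imputation layer, scores every
(imputation, method) cell into ranked edge lists and early-precision
metrics, and then runs the cross-model structure and motif analyses.
Every intermediate is persisted as plain text under the output directory,
and ``report`` regenerates the summary tables from those artifacts alone,
so every reported number is recomputable.  Per-cell seeds are derived by
hashing (master seed, dataset, imputation, method), so adding a grid cell
never perturbs the others.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import ExpressionDataset, GroundTruthNetwork, SimulationConfig
from .evaluate import evaluate_model, harmonize_networks, network_density, top_k
from .impute import (impute_diffusion, impute_identity, impute_knn_aggregate,
                     impute_shrinkage, load_external_imputed)
from .infer import (infer_boosted, infer_mi_context,
                    infer_partial_correlation, infer_tree_importance,
                    load_external_ranked_edges)
from .motifs import classify_motifs
from .preprocess import normalize, select_genes
from .simulate import downsample_counts, sample_ground_truth, simulate_counts
from .structure import (correlation_class_regression, cluster_models,
                        cluster_purity_ari, rank_shift, similarity_matrix,
                        variance_by_factor)

__all__ = ["ExperimentConfig", "run_experiment", "report", "derive_seed"]

KNOWN_IMPUTATIONS = {"noimp", "knn_aggregate", "diffusion", "shrinkage", "external"}
KNOWN_GRN = {"tree", "boost", "mi", "pcor", "external"}


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed from the master seed and string labels."""
    key = "|".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """Configuration of one factorial run.

    ``datasets`` entries are either simulator specs
    (``{"name": ..., "sim": {<SimulationConfig overrides>}}``) or file specs
    (``{"name", "counts", "pseudotime", "tfs", "reference"}``).  The
    ``noimp`` baseline is mandatory: all log2 ratios are taken against it.
    """

    datasets: list = field(default_factory=lambda: [{"name": "sim0", "sim": {}}])
    imputations: list = field(default_factory=lambda: [
        {"tag": "noimp"},
        {"tag": "knn_aggregate", "params": {"k_neighbors": 15}},
        {"tag": "diffusion", "params": {"knn": 15, "t": 3}},
        {"tag": "shrinkage", "params": {"prior_strength": 1.0}},
    ])
    grn_methods: list = field(default_factory=lambda: [
        {"tag": "tree", "params": {"n_trees": 50}},
        {"tag": "boost", "params": {"n_rounds": 50}},
        {"tag": "mi", "params": {"n_bins": 8}},
        {"tag": "pcor", "params": {"threshold": 0.1}},
    ])
    n_top: int = 500
    alpha: float = 0.01
    top_n_similarity: int = 500
    downsample_fraction: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        imp_tags = [i["tag"] for i in self.imputations]
        if "noimp" not in imp_tags:
            raise ValueError("the noimp baseline imputation is mandatory")
        for tag in imp_tags:
            if tag.split(":")[0] not in KNOWN_IMPUTATIONS:
                raise ValueError(f"unknown imputation tag {tag!r}")
        for m in self.grn_methods:
            if m["tag"].split(":")[0] not in KNOWN_GRN:
                raise ValueError(f"unknown GRN method tag {m['tag']!r}")
        if self.downsample_fraction is not None and not (
                0 < self.downsample_fraction <= 1):
            raise ValueError("downsample_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.validate()
        return cfg


def _load_dataset(spec: dict, config: ExperimentConfig
                  ) -> tuple[ExpressionDataset, GroundTruthNetwork]:
    name = spec["name"]
    if "sim" in spec or "counts" not in spec:
        overrides = dict(spec.get("sim", {}))
        overrides.setdefault("seed", derive_seed(config.seed, name, "sim"))
        sim_cfg = SimulationConfig(**overrides)
        net = sample_ground_truth(sim_cfg)
        data = simulate_counts(net, sim_cfg)
    else:
        tfs = io.read_gene_list(spec["tfs"])
        pt = io.read_pseudotime_csv(spec["pseudotime"]).to_numpy()
        data = io.read_counts_csv(spec["counts"], tf_ids=tfs, pseudotime=pt)
        net = io.read_network_tsv(spec["reference"], tfs=tfs)
    if config.downsample_fraction is not None and config.downsample_fraction < 1:
        data = downsample_counts(data, config.downsample_fraction,
                                 seed=derive_seed(config.seed, name, "downsample"))
    return data, net


def _impute_layer(tag: str, params: dict, raw: ExpressionDataset,
                  norm: ExpressionDataset) -> ExpressionDataset:
    """One imputed expression layer on the normalized (log) scale.

    Each family runs on its native substrate — aggregation and shrinkage on
    raw counts, diffusion on the normalized layer — and the result is
    brought back onto the log1p scale so all layers feed the same inference
    methods.
    """
    base = tag.split(":")[0]
    if base == "noimp":
        res = impute_identity(norm)
        matrix = res.matrix
    elif base == "knn_aggregate":
        res = impute_knn_aggregate(raw, **params)
        matrix = np.log1p(res.matrix)
    elif base == "diffusion":
        res = impute_diffusion(norm, **params)
        matrix = res.matrix
    elif base == "shrinkage":
        res = impute_shrinkage(raw, **params)
        matrix = res.matrix
    elif base == "external":
        res = load_external_imputed(params["path"], tag.split(":", 1)[1], raw)
        matrix = res.matrix
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown imputation tag {tag!r}")
    return norm.with_matrix(matrix, layer_tag=f"imputed:{tag}")


def _infer(tag: str, params: dict, data: ExpressionDataset, selection,
           seed: int):
    base = tag.split(":")[0]
    if base == "tree":
        return infer_tree_importance(data, selection, seed=seed, **params)
    if base == "boost":
        return infer_boosted(data, selection, seed=seed, **params)
    if base == "mi":
        return infer_mi_context(data, selection, **params)
    if base == "pcor":
        return infer_partial_correlation(data, selection, **params)
    if base == "external":
        return load_external_ranked_edges(params["path"], method_tag=tag)
    raise ValueError(f"unknown GRN method tag {tag!r}")  # pragma: no cover


def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Execute the full grid and persist every intermediate.

    Layout: ``<outdir>/<dataset>/`` holds the raw dataset, the gene
    selection, one imputed matrix per tag, one ranked edge list per grid
    cell, motif tables, rank shifts and class-regression lines;
    ``<outdir>/metrics.csv`` is the tidy per-cell metrics table and
    ``<outdir>/failures.csv`` enumerates any failed cells.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    metric_rows, failures, motif_rows = [], [], []
    for spec in config.datasets:
        name = spec["name"]
        ds_dir = outdir / name
        try:
            raw, net = _load_dataset(spec, config)
            io.write_dataset(raw, net, ds_dir / "input")
            norm = normalize(raw)
            selection = select_genes(norm, n_top=config.n_top, alpha=config.alpha)
            io.write_gene_list(selection.universe, ds_dir / "gene_universe.txt")
            selection.stats.to_csv(ds_dir / "gene_stats.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - failures are data, not crashes
            failures.append({"dataset": name, "imputation": "*", "grn_method": "*",
                             "stage": "dataset", "error": str(exc)})
            continue

        layers: dict[str, ExpressionDataset] = {}
        for imp in config.imputations:
            tag = imp["tag"]
            try:
                layer = _impute_layer(tag, imp.get("params", {}), raw, norm)
                layers[tag] = layer
                io.write_counts_csv(layer, ds_dir / f"imputed_{tag.replace(':', '_')}.csv")
            except Exception as exc:  # noqa: BLE001
                failures.append({"dataset": name, "imputation": tag,
                                 "grn_method": "*", "stage": "imputation",
                                 "error": str(exc)})

        rankings: dict[tuple, object] = {}
        for imp in config.imputations:
            tag = imp["tag"]
            if tag not in layers:
                continue
            for method in config.grn_methods:
                mtag = method["tag"]
                cell_seed = derive_seed(config.seed, name, tag, mtag)
                try:
                    ranked = _infer(mtag, method.get("params", {}),
                                    layers[tag], selection, cell_seed)
                    ranked.imputation_tag = tag
                    rankings[(tag, mtag)] = ranked
                    io.write_ranked_edges_tsv(
                        ranked,
                        ds_dir / f"ranked_{tag.replace(':', '_')}_{mtag}.tsv")
                except Exception as exc:  # noqa: BLE001
                    failures.append({"dataset": name, "imputation": tag,
                                     "grn_method": mtag, "stage": "inference",
                                     "error": str(exc)})

        # evaluation: noimp first to anchor the log2 ratios
        baselines: dict[str, dict] = {}
        grn_tags = [m["tag"] for m in config.grn_methods]
        for mtag in grn_tags:
            ordered = ["noimp"] + [i["tag"] for i in config.imputations
                                   if i["tag"] != "noimp"]
            for tag in ordered:
                if (tag, mtag) not in rankings:
                    continue
                try:
                    base = baselines.get(mtag)
                    metrics = evaluate_model(
                        rankings[(tag, mtag)], net, selection,
                        baseline_epr=base["epr"] if base else None,
                        baseline_density=base["density"] if base else None,
                    )
                    if tag == "noimp":
                        pred_h, ref_h = harmonize_networks(
                            rankings[(tag, mtag)], net, selection)
                        tk = top_k(pred_h, ref_h.n_edges)
                        baselines[mtag] = {
                            "epr": metrics.epr,
                            "density": network_density(
                                tk.n_reported, len(ref_h.genes), len(ref_h.tfs)),
                            "tp": classify_edges_tp(tk, ref_h),
                            "pred": pred_h,
                        }
                        metrics.log2_epr_ratio = 0.0
                        metrics.log2_density_ratio = 0.0
                    metric_rows.append({
                        "dataset": name, "imputation": tag, "grn_method": mtag,
                        "ep": metrics.ep, "epr": metrics.epr,
                        "density": metrics.density, "k": metrics.k,
                        "n_tp": metrics.n_tp, "n_reported": metrics.n_reported,
                        "log2_epr_ratio": metrics.log2_epr_ratio,
                        "log2_density_ratio": metrics.log2_density_ratio,
                    })
                    # motif classification of this cell's top-k network
                    pred_h, ref_h = harmonize_networks(
                        rankings[(tag, mtag)], net, selection)
                    tk = top_k(pred_h, ref_h.n_edges)
                    mc = classify_motifs(tk.edge_set(), set(ref_h.edges))
                    motif_rows.append({
                        "dataset": name, "imputation": tag, "grn_method": mtag,
                        "tp_chains": mc.n_tp, "fp_chains": mc.n_fp,
                        "fn_chains": mc.n_fn, "tp_loops": len(mc.tp_loops),
                        "unclassifiable": len(mc.unclassifiable),
                        "tpr": mc.tpr, "fdr": mc.fdr,
                    })
                except Exception as exc:  # noqa: BLE001
                    failures.append({"dataset": name, "imputation": tag,
                                     "grn_method": mtag, "stage": "evaluation",
                                     "error": str(exc)})

        # structure analyses per dataset
        try:
            _structure_outputs(ds_dir, rankings, baselines, layers, net,
                               selection, config)
        except Exception as exc:  # noqa: BLE001
            failures.append({"dataset": name, "imputation": "*",
                             "grn_method": "*", "stage": "structure",
                             "error": str(exc)})

    metrics_df = pd.DataFrame(metric_rows, columns=[
        "dataset", "imputation", "grn_method", "ep", "epr", "density", "k",
        "n_tp", "n_reported", "log2_epr_ratio", "log2_density_ratio"])
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame(motif_rows).to_csv(outdir / "motifs.csv", index=False)
    pd.DataFrame(failures, columns=["dataset", "imputation", "grn_method",
                                    "stage", "error"]
                 ).to_csv(outdir / "failures.csv", index=False)
    manifest = {
        "seed": config.seed,
        "n_top": config.n_top,
        "alpha": config.alpha,
        "top_n_similarity": config.top_n_similarity,
        "downsample_fraction": config.downsample_fraction,
        "datasets": [d["name"] for d in config.datasets],
        "imputations": [i["tag"] for i in config.imputations],
        "grn_methods": [m["tag"] for m in config.grn_methods],
        "n_cells_completed": len(metric_rows),
        "n_failures": len(failures),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report(outdir)
    return outdir


def classify_edges_tp(tk, ref) -> frozenset:
    """TP edge set of one top-k network (helper for rank-shift baselines)."""
    return frozenset(tk.edge_set() & set(ref.edges))


def _structure_outputs(ds_dir, rankings, baselines, layers, net, selection,
                       config) -> None:
    """Similarity/clustering, rank shifts and class regressions for one
    dataset."""
    if len(rankings) >= 2:
        labeled = {f"{imp}+{m}": rel for (imp, m), rel in rankings.items()}
        sim = similarity_matrix(labeled, top_n=config.top_n_similarity)
        sim.to_csv(ds_dir / "similarity.csv")
        imp_levels = sorted({imp for imp, _ in rankings})
        grn_levels = sorted({m for _, m in rankings})
        ari_rows = []
        for label_name, levels, labeler in (
                ("imputation", imp_levels, lambda key: key.split("+")[0]),
                ("grn_method", grn_levels, lambda key: key.split("+")[1])):
            if len(levels) < 2 or len(sim) <= len(levels):
                continue
            found = cluster_models(sim, n_clusters=len(levels))
            annotation = [labeler(k) for k in found.index]
            ari_rows.append({"label": label_name,
                             "ari": cluster_purity_ari(found.tolist(), annotation)})
        pd.DataFrame(ari_rows, columns=["label", "ari"]
                     ).to_csv(ds_dir / "ari.csv", index=False)

    shift_rows = []
    for (imp, mtag), ranked in rankings.items():
        if imp == "noimp" or mtag not in baselines:
            continue
        pred_h, ref_h = harmonize_networks(ranked, net, selection)
        shifts = rank_shift(baselines[mtag]["tp"], pred_h,
                            ranking_unimputed=baselines[mtag]["pred"])
        shifts.insert(0, "grn_method", mtag)
        shifts.insert(0, "imputation", imp)
        shift_rows.append(shifts)
    if shift_rows:
        pd.concat(shift_rows).to_csv(ds_dir / "rank_shifts.csv", index=False)

    reg_rows = []
    norm_layer = layers.get("noimp")
    for (imp, mtag), ranked in rankings.items():
        if imp == "noimp" or norm_layer is None or imp not in layers:
            continue
        pred_h, ref_h = harmonize_networks(ranked, net, selection)
        tk = top_k(pred_h, ref_h.n_edges)
        from .evaluate import classify_edges
        cls = classify_edges(tk, ref_h)
        table = correlation_class_regression(norm_layer, layers[imp], cls)
        lines = table.lines.reset_index()
        lines.insert(0, "grn_method", mtag)
        lines.insert(0, "imputation", imp)
        reg_rows.append(lines)
    if reg_rows:
        pd.concat(reg_rows).to_csv(ds_dir / "class_regression.csv", index=False)


def report(artifact_dir) -> dict:
    """Summary tables regenerated from persisted artifacts.

    Returns (and writes under ``<artifact_dir>/report/``) the EPR table,
    the log2-ratio table, the variance decomposition with per-dataset ANOVA
    (when the grid allows it), and the motif summary.  Running it twice is
    idempotent.
    """
    artifact_dir = Path(artifact_dir)
    metrics_path = artifact_dir / "metrics.csv"
    if not metrics_path.exists():
        raise FileNotFoundError(f"no metrics.csv under {artifact_dir}; "
                                "not a completed experiment directory")
    metrics = pd.read_csv(metrics_path)
    rep_dir = artifact_dir / "report"
    rep_dir.mkdir(exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    if metrics.empty:
        raise ValueError("metrics table is empty; nothing to report")
    tables["epr"] = metrics.pivot_table(
        index=["dataset", "imputation"], columns="grn_method", values="epr")
    tables["log2_epr_ratio"] = metrics.pivot_table(
        index=["dataset", "imputation"], columns="grn_method",
        values="log2_epr_ratio")

    ratios = metrics[metrics["imputation"] != "noimp"].dropna(
        subset=["log2_epr_ratio"])
    if (ratios["imputation"].nunique() >= 2
            and ratios["grn_method"].nunique() >= 2):
        try:
            vd = variance_by_factor(ratios)
            tables["variance_across_imputation"] = vd.var_across_imputation
            tables["variance_across_grn"] = vd.var_across_grn
            anova = pd.concat(
                {ds: tbl for ds, tbl in vd.anova_tables.items()},
                names=["dataset", "term"])
            tables["anova"] = anova.reset_index()
            tables["wilcoxon"] = pd.DataFrame([{
                "statistic": vd.ranksum_statistic, "p_value": vd.ranksum_p}])
        except ValueError as exc:
            warnings.warn(f"variance decomposition skipped: {exc}", UserWarning)

    motifs_path = artifact_dir / "motifs.csv"
    if motifs_path.exists():
        try:
            tables["motifs"] = pd.read_csv(motifs_path)
        except pd.errors.EmptyDataError:
            pass

    for name, tbl in tables.items():
        tbl.to_csv(rep_dir / f"{name}.csv")
    return tables
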