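"""Synthetic single-cell data with a known regulatory ground truth.

The generator produces what the downstream evaluation needs and nothing
more: a sparse directed TF -> gene network with hub TFs, smooth TF
expression programs along pseudotime, target genes driven by a monotone
link of their regulators' programs, and counts drawn from an overdispersed
(gamma-Poisson) law with mean-dependent extra zeros emulating dropout.
Library sizes vary log-normally across cells so that depth normalization
is non-trivial.  Binomial thinning provides the in-silico "lower sequencing
depth" stress test.
"""

from __future__ import annotations

import numpy as np

from .core import ExpressionDataset, GroundTruthNetwork, SimulationConfig

__all__ = ["sample_ground_truth", "simulate_counts", "downsample_counts"]


def _gene_ids(config: SimulationConfig) -> tuple[list, list]:
    tfs = [f"TF{i}" for i in range(config.n_tfs)]
    targets = [f"G{i}" for i in range(config.n_genes - config.n_tfs)]
    return tfs, targets


def sample_ground_truth(config: SimulationConfig) -> GroundTruthNetwork:
    """Draw a sparse directed TF -> gene network.

    Each gene receives a Poisson(edges_per_gene) number of regulators
    (capped by the number of eligible TFs), drawn without replacement with
    probabilities proportional to a heavy-tailed per-TF propensity, which
    yields hub TFs.  TFs themselves can be regulated by other TFs, so the
    network contains TF->TF as well as TF->target edges.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tfs, targets = _gene_ids(config)
    genes = tfs + targets

    # heavy-tailed out-degree propensity: Pareto-like weights create hub TFs
    propensity = rng.pareto(1.5, size=config.n_tfs) + 1.0

    edges: set[tuple] = set()
    for gene in genes:
        eligible = [t for t in tfs if t != gene]
        if not eligible:
            continue
        m = int(min(rng.poisson(config.edges_per_gene), len(eligible)))
        if m == 0:
            continue
        p = np.array([propensity[tfs.index(t)] for t in eligible])
        chosen = rng.choice(eligible, size=m, replace=False, p=p / p.sum())
        edges.update((t, gene) for t in chosen)

    # the evaluation layer needs both edge flavours present
    has_tf_edge = any(t in tfs for _, t in edges)
    has_target_edge = any(t not in tfs for _, t in edges)
    if not has_tf_edge and config.n_tfs >= 2:
        src, dst = rng.choice(config.n_tfs, size=2, replace=False)
        edges.add((tfs[src], tfs[dst]))
    if not has_target_edge and targets:
        edges.add((tfs[int(rng.integers(config.n_tfs))], targets[int(rng.integers(len(targets)))]))

    return GroundTruthNetwork(
        tfs=frozenset(tfs), genes=frozenset(genes), edges=frozenset(edges)
    )


def _tf_programs(config: SimulationConfig, rng: np.random.Generator,
                 pseudotime: np.ndarray) -> np.ndarray:
    """Smooth per-TF expression programs over pseudotime.

    Half the TFs follow sigmoid switches, half Gaussian pulses, with random
    midpoints/widths; both shapes are what smooth additive fits should
    detect as pseudotime-variable.
    """
    n_tfs = config.n_tfs
    programs = np.empty((n_tfs, pseudotime.size))
    for i in range(n_tfs):
        t0 = rng.uniform(0.2, 0.8)
        if rng.random() < 0.5:
            steep = rng.uniform(6, 14) * rng.choice([-1.0, 1.0])
            shape = 1.0 / (1.0 + np.exp(-steep * (pseudotime - t0)))
        else:
            width = rng.uniform(0.08, 0.25)
            shape = np.exp(-0.5 * ((pseudotime - t0) / width) ** 2)
        programs[i] = shape
    return programs


def simulate_counts(net: GroundTruthNetwork,
                    config: SimulationConfig) -> ExpressionDataset:
    """Generate raw counts consistent with a ground-truth network.

    Latent rates: TFs follow smooth pseudotime programs; each target's
    log-rate is a weighted sum of its (standardized) regulator programs with
    weight scale ``effect_size`` and random activating/repressing signs, so
    regulated pairs are more strongly correlated (on the latent layer) than
    random non-edges.  Counts: gamma-Poisson around rate x library size with
    shape 1/dispersion, then mean-dependent extra zeros with probability
    exp(-dropout_strength * mean).  The latent rate matrix is attached to the
    returned dataset for downstream diagnostics.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    tfs, targets = _gene_ids(config)
    genes = tfs + targets
    if not net.genes <= set(genes):
        raise ValueError("network genes exceed the configured gene budget")

    n_cells = config.n_cells
    pseudotime = np.sort(rng.uniform(0.0, 1.0, size=n_cells))

    programs = _tf_programs(config, rng, pseudotime)  # n_tfs x n_cells
    std = programs.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    z_programs = (programs - programs.mean(axis=1, keepdims=True)) / std

    base_log_rate = rng.normal(1.0, 0.4, size=len(genes))
    log_rate = np.tile(base_log_rate[:, None], (1, n_cells)).astype(float)

    tf_index = {t: i for i, t in enumerate(tfs)}
    gene_index = {g: i for i, g in enumerate(genes)}

    # TFs: own smooth program (amplitude ~ effect scale, floor at 1 so TFs
    # vary along pseudotime even in the null effect_size=0 model)
    tf_amplitude = max(config.effect_size, 1.0)
    for t, i in tf_index.items():
        log_rate[gene_index[t]] += tf_amplitude * z_programs[i]

    # targets: monotone (exp) link of the weighted regulator sum
    regulators: dict = {g: [] for g in genes}
    for s, t in net.edges:
        regulators[t].append(s)
    for g, regs in regulators.items():
        if not regs or g in tf_index:
            continue
        signs = rng.choice([-1.0, 1.0], size=len(regs))
        weights = signs * rng.uniform(0.7, 1.3, size=len(regs))
        combo = np.zeros(n_cells)
        for w, r in zip(weights, regs):
            combo += w * z_programs[tf_index[r]]
        if len(regs):
            combo /= np.sqrt(len(regs))
        log_rate[gene_index[g]] += config.effect_size * combo

    rate = np.exp(log_rate)

    lib = np.exp(rng.normal(0.0, config.library_sigma, size=n_cells))
    mean = rate * lib[None, :]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    if config.dropout_strength > 0:
        keep = rng.random(mean.shape) >= np.exp(-config.dropout_strength * mean)
        # exp(-s*mean) is the probability of an *extra* technical zero
        counts = np.where(keep, counts, 0)

    tf_flags = np.array([g in tf_index for g in genes])
    return ExpressionDataset(
        counts, genes, tf_flags, pseudotime, layer_tag="raw",
        cell_ids=[f"cell{i}" for i in range(n_cells)], latent=rate,
    )


def downsample_counts(data: ExpressionDataset, fraction: float,
                      seed: int = 0) -> ExpressionDataset:
    """Binomial thinning of raw counts to a fraction of sequencing depth.

    Every entry is replaced by Binomial(count, fraction), so the output is
    elementwise dominated by the input and the expected total depth is
    ``fraction`` times the original.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if data.layer_tag != "raw":
        raise ValueError("downsampling requires the raw integer layer")
    if fraction == 1.0:
        return data.with_matrix(data.counts.copy(), layer_tag="raw")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(data.counts, fraction)
    return data.with_matrix(thinned.astype(np.int64), layer_tag="raw")
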