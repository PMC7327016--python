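"""Benchmark-shaped synthetic fixtures: a planted TF->target network plus an
expression matrix in which targets depend statistically on their regulators.

This is a minimal dependence-planting generator, NOT a replica of the
kinetic simulators behind the public network-inference challenges; AUCs
measured on these fixtures validate the pipeline's ability to recover
planted structure, not benchmark performance on real compendia.

Generative model, per sample: unregulated TFs are drawn iid standard
normal; a regulated gene responds to the observed expression of its
regulators as tanh(sum_j beta_j x_j) + Gaussian noise, with effect sizes
|beta| uniform in ``effect_range`` and negative (repression) with
probability 1 - ``activation_fraction``. Unregulated non-TF genes are pure
noise. TF->TF edges are restricted to run down the TF index order (an
acyclic regulatory cascade), so expression propagates in a single
topological pass and every planted edge leaves an observable statistical
footprint. The matrix is shifted to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import DataValidationError, ExpressionMatrix, GoldStandard

__all__ = [
    "SyntheticDataset",
    "generate_network",
    "simulate_expression",
    "make_benchmark_fixture",
    "hold_out_edges",
    "PROFILES",
]

# Fixture shapes mirror the public challenge datasets: five 100-gene
# networks observed over 210 samples (TF counts in the mid-30s to mid-40s),
# and an in-silico compendium of 1643 genes x 805 samples with 178 TFs and
# 4012 interactions. `tiny` is a fast unit-test shape.
PROFILES: dict[str, dict] = {
    "dream4_like": dict(n_genes=100, n_tfs=40, n_edges=150, n_samples=210, max_in_degree=3),
    "dream5_like": dict(n_genes=1643, n_tfs=178, n_edges=4012, n_samples=805, max_in_degree=10),
    "tiny": dict(n_genes=20, n_tfs=6, n_edges=15, n_samples=30, max_in_degree=3),
}

NOISE_SD = 0.3
EFFECT_RANGE = (0.5, 2.0)
ACTIVATION_FRACTION = 0.7


@dataclass
class SyntheticDataset:
    """A planted network with matching expression; the gold standard is the
    complete truth (every non-edge is a true negative)."""

    expr: ExpressionMatrix
    gold: GoldStandard
    params: dict

    @property
    def true_edges(self) -> set[tuple[str, str]]:
        return set(self.gold.positives)


def _gene_ids(n_genes: int, n_tfs: int) -> tuple[list[str], list[str]]:
    width = max(3, len(str(n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    return genes, genes[:n_tfs]


def generate_network(
    n_genes: int,
    n_tfs: int,
    n_edges: int,
    max_in_degree: int | None = None,
    seed: int = 0,
) -> GoldStandard:
    """Uniform random directed TF->gene network without self-loops.

    The first ``n_tfs`` gene ids are the regulators; ``max_in_degree`` caps
    how many regulators any single gene may have. Edges between two TFs only
    run from a lower to a higher TF index, so the regulatory cascade is
    acyclic and expression can be simulated in one topological pass.
    """
    if n_tfs >= n_genes:
        raise DataValidationError("n_tfs must be smaller than n_genes")
    max_edges = n_tfs * (n_genes - n_tfs) + n_tfs * (n_tfs - 1) // 2
    if n_edges > max_edges:
        raise DataValidationError(
            f"n_edges={n_edges} exceeds the {max_edges} feasible acyclic TF->gene pairs"
        )
    if max_in_degree is not None and n_edges > max_in_degree * n_genes:
        raise DataValidationError("n_edges infeasible under the in-degree cap")

    genes, tfs = _gene_ids(n_genes, n_tfs)
    tf_rank = {tf: i for i, tf in enumerate(tfs)}
    rng = np.random.default_rng(seed)
    candidates = [
        (tf, g) for tf in tfs for g in genes
        if g != tf and (g not in tf_rank or tf_rank[tf] < tf_rank[g])
    ]
    order = rng.permutation(len(candidates))
    edges: set[tuple[str, str]] = set()
    in_degree: dict[str, int] = {}
    for idx in order:
        tf, g = candidates[idx]
        if max_in_degree is not None and in_degree.get(g, 0) >= max_in_degree:
            continue
        edges.add((tf, g))
        in_degree[g] = in_degree.get(g, 0) + 1
        if len(edges) == n_edges:
            break
    if len(edges) < n_edges:
        raise DataValidationError("could not place all edges under the in-degree cap")
    return GoldStandard(set(tfs), edges)


def simulate_expression(
    gold: GoldStandard,
    n_samples: int,
    noise_sd: float = NOISE_SD,
    effect_range: tuple[float, float] = EFFECT_RANGE,
    activation_fraction: float = ACTIVATION_FRACTION,
    seed: int = 0,
    gene_ids: Iterable[str] | None = None,
) -> ExpressionMatrix:
    """Simulate expression in which planted targets depend on their regulators.

    With ``noise_sd=0`` a regulated gene is an exact deterministic function
    of its regulators' observed expression; as ``noise_sd`` grows the
    TF-target correlation decays toward zero.
    """
    if noise_sd < 0:
        raise DataValidationError("noise_sd must be non-negative")
    lo, hi = effect_range
    if not (0 < lo <= hi):
        raise DataValidationError("effect_range must satisfy 0 < low <= high")
    if not 0 <= activation_fraction <= 1:
        raise DataValidationError("activation_fraction must lie in [0, 1]")

    if gene_ids is None:
        gene_set = set(gold.tf_ids) | {g for _, g in gold.positives}
        gene_ids = sorted(gene_set)
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tf_ids = sorted(gold.tf_ids)

    rng = np.random.default_rng(seed)
    # per-edge effect sizes, deterministic order
    edges = sorted(gold.positives)
    beta = rng.uniform(lo, hi, size=len(edges))
    sign = np.where(rng.random(len(edges)) < activation_fraction, 1.0, -1.0)
    beta *= sign

    tf_set = set(tf_ids)
    values = np.empty((n_genes, n_samples))
    regulated: dict[str, list[tuple[str, float]]] = {}
    for (tf, g), b in zip(edges, beta):
        regulated.setdefault(g, []).append((tf, b))
    for g, regs in regulated.items():
        if g in tf_set:
            for tf, _ in regs:
                if tf_ids.index(tf) >= tf_ids.index(g):
                    raise DataValidationError(
                        f"TF->TF edge ({tf}, {g}) against the TF ordering; the "
                        "regulatory cascade must be acyclic"
                    )

    # one topological pass: TFs in index order first, then non-TF genes
    for g in tf_ids + [g for g in gene_ids if g not in tf_set]:
        i = gidx[g]
        if g in regulated:
            drive = np.zeros(n_samples)
            for tf, b in regulated[g]:
                drive += b * values[gidx[tf]]
            values[i] = np.tanh(drive) + rng.standard_normal(n_samples) * noise_sd
        else:
            # unregulated TFs (cascade roots) and unregulated non-TF genes
            values[i] = rng.standard_normal(n_samples)

    values -= values.min()  # shift to non-negative, like abundance data
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def make_benchmark_fixture(profile: str = "dream4_like", seed: int = 0, **overrides) -> SyntheticDataset:
    """Generate a named-shape dataset (network + expression + params).

    Profiles: 'dream4_like' (100 genes x 210 samples, 40 TFs, 150 edges),
    'dream5_like' (1643 x 805, 178 TFs, 4012 edges), 'tiny' (20 x 30).
    """
    if profile not in PROFILES:
        raise DataValidationError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    params = {**PROFILES[profile],
              "noise_sd": NOISE_SD, "effect_range": EFFECT_RANGE,
              "activation_fraction": ACTIVATION_FRACTION, "seed": int(seed),
              **overrides}
    gold = generate_network(params["n_genes"], params["n_tfs"], params["n_edges"],
                            params["max_in_degree"], seed=seed)
    genes, _ = _gene_ids(params["n_genes"], params["n_tfs"])
    expr = simulate_expression(
        gold, params["n_samples"], noise_sd=params["noise_sd"],
        effect_range=params["effect_range"],
        activation_fraction=params["activation_fraction"],
        seed=seed + 1, gene_ids=genes,
    )
    return SyntheticDataset(expr, gold, params)


def hold_out_edges(
    gold: GoldStandard, fraction_observed: float, seed: int = 0
) -> tuple[GoldStandard, set[tuple[str, str]]]:
    """Split planted edges into an observed gold standard and hidden truth.

    Emulates the real-world situation where the gold standard is incomplete:
    the returned GoldStandard carries ``fraction_observed`` of the edges as
    positives while the remaining true edges stay uncharacterized — the
    synthetic analogue of cross-checking high-scoring pairs against an
    external interaction database.
    """
    if not 0 < fraction_observed < 1:
        raise DataValidationError("fraction_observed must lie strictly between 0 and 1")
    edges = sorted(gold.positives)
    rng = np.random.default_rng(seed)
    n_obs = max(1, int(round(fraction_observed * len(edges))))
    perm = rng.permutation(len(edges))
    observed = {edges[i] for i in perm[:n_obs]}
    hidden = {edges[i] for i in perm[n_obs:]}
    return GoldStandard(set(gold.tf_ids), observed), hidden
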