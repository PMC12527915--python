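"""Synthetic perturb-seq generator with a known ground-truth gene graph.

Counts follow a negative-binomial (Gamma-Poisson) model: gene g in a cell
of state c has mean s_n * mu_{c,g}, where s_n is a log-normal library-size
factor and mu_{c,g} multiplies a shared log-normal baseline by a
state-program factor on a random subset of genes.  Perturbing a driver
gene multiplies the means of the driver and of its directed-graph
descendants by alpha^(beta^depth) up to a propagation depth P, so
perturbation footprints are consistent with the known graph — the property
that makes graph-ablation experiments on this data meaningful.

Driver genes are drawn among genes that are both expressed (baseline mean
at or above the median) and regulatory hubs (out-degree >= 6 by default),
mirroring the fact that CRISPR screens target expressed regulators whose
perturbation has a broad transcriptomic footprint.  With the default
density the footprints of different drivers overlap little, so a single
(control, perturbed) cell pair carries enough evidence to identify the
driver — a negative-binomial likelihood-ratio oracle on these defaults
tops out near 0.9 top-1 accuracy, bounding what any classifier can reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .data_core import CountMatrix, ValidationError
from .dgp import Pair, PairedDataset
from .gene_graph import DirectedGeneGraph

__all__ = [
    "SimConfig",
    "PerturbationSpec",
    "SimulatedCells",
    "PairedSimData",
    "generate_graph",
    "simulate_cells",
    "apply_perturbation",
    "build_pair_dataset",
]


@dataclass
class SimConfig:
    """Generator parameters (desk-scale defaults)."""

    n_genes: int = 200
    n_states: int = 4
    n_drivers: int = 20
    cells_per_pert: int = 50  # per (state, driver)
    controls_per_state: int = 500
    lib_log_mu: float = 0.0
    lib_log_sigma: float = 0.3
    theta: float = 10.0  # NB dispersion; variance = m + m^2/theta
    alpha: float = 3.0  # driver effect multiplier
    beta: float = 0.6  # propagation decay, in (0, 1)
    depth: int = 2  # propagation depth P
    graph_density: float = 0.03
    driver_min_outdegree: int = 6
    driver_expr_quantile: float = 0.5
    gene_log_mu: float = -0.7
    gene_log_sigma: float = 1.2
    program_frac: float = 0.15
    program_log_sigma: float = 0.8
    holdout_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValidationError("beta must be in (0, 1)")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        for name in ("n_genes", "n_states", "n_drivers", "cells_per_pert",
                     "controls_per_state", "depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class PerturbationSpec:
    """Multiplicative mean effect of perturbing one driver gene."""

    driver: int
    effect: np.ndarray  # per-gene multiplier, 1 for unaffected genes

    @classmethod
    def from_driver(
        cls, graph: DirectedGeneGraph, driver: int, config: SimConfig
    ) -> "PerturbationSpec":
        if not 0 <= driver < graph.n_nodes:
            raise ValidationError(f"driver index {driver} not in graph")
        d = dijkstra(
            graph.adjacency, directed=True, unweighted=True,
            indices=driver, limit=config.depth,
        )
        effect = np.ones(graph.n_nodes)
        reach = np.isfinite(d)
        effect[reach] = config.alpha ** (config.beta ** d[reach])
        effect[driver] = config.alpha
        return cls(driver, effect)


@dataclass
class SimulatedCells:
    counts: CountMatrix
    states: np.ndarray  # per-cell state index
    state_means: np.ndarray  # [C, G] mu_{c,g}
    library_sizes: np.ndarray


@dataclass
class PairedSimData:
    counts: CountMatrix
    dataset: PairedDataset
    graph: DirectedGeneGraph
    states: dict[str, int]  # cell id -> state
    drivers: list[str]
    config: SimConfig

    def source_pools(self) -> dict[str, list[str]]:
        """Eligible source cells (same-state controls) per target cell;
        used for control-resampling augmentation during fine-tuning."""
        ctrls: dict[int, list[str]] = {}
        for cid, st in self.states.items():
            if cid.startswith("ctrl_"):
                ctrls.setdefault(st, []).append(cid)
        return {
            p.target_id: ctrls[self.states[p.target_id]]
            for p in self.dataset.pairs
        }

    def ground_truth(self) -> dict:
        return {
            "config": asdict(self.config),
            "drivers": self.drivers,
            "edges": sorted(
                [self.graph.gene_ids[s], self.graph.gene_ids[t]]
                for s, t in self.graph.edges
            ),
        }


def generate_graph(
    n_genes: int, density: float, seed: int | np.random.Generator
) -> DirectedGeneGraph:
    """Directed graph with heavy-tailed out-degree (preferential
    attachment on sources), ~density * G^2 edges, no self-loops."""
    if not 0 < density < 1:
        raise ValidationError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    target = int(round(density * n_genes * n_genes))
    out_deg = np.ones(n_genes)
    edges: set[tuple[int, int]] = set()
    while len(edges) < target:
        p = out_deg / out_deg.sum()
        s = int(rng.choice(n_genes, p=p))
        t = int(rng.integers(n_genes))
        if s == t or (s, t) in edges:
            continue
        edges.add((s, t))
        out_deg[s] += 1
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    return DirectedGeneGraph.from_edges(gene_ids, edges)


def _state_means(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    base = np.exp(
        config.gene_log_mu + config.gene_log_sigma * rng.standard_normal(config.n_genes)
    )
    means = np.tile(base, (config.n_states, 1))
    n_prog = max(1, int(round(config.program_frac * config.n_genes)))
    for c in range(config.n_states):
        prog = rng.choice(config.n_genes, size=n_prog, replace=False)
        means[c, prog] *= np.exp(
            config.program_log_sigma * rng.standard_normal(n_prog)
        )
    return means


def _draw_counts(
    means: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-Poisson draws; means [n_cells, G]. Returns (counts, lib sizes)."""
    n = means.shape[0]
    s = np.exp(
        config.lib_log_mu + config.lib_log_sigma * rng.standard_normal(n)
    )
    lam = rng.gamma(config.theta, (s[:, None] * means) / config.theta)
    counts = rng.poisson(lam).astype(np.int64)
    # a cell must have at least one count; force the most expressed gene
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    if empty.size:
        counts[empty, np.argmax(means[empty], axis=1)] = 1
    return counts, s


def simulate_cells(
    config: SimConfig,
    graph: DirectedGeneGraph | None = None,
    seed: int | np.random.Generator | None = None,
    n_cells_per_state: int | None = None,
) -> SimulatedCells:
    """Unperturbed cells for every state (``controls_per_state`` each)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means = _state_means(config, rng)
    per = n_cells_per_state or config.controls_per_state
    states = np.repeat(np.arange(config.n_states), per)
    counts, libs = _draw_counts(means[states], config, rng)
    ids = [f"ctrl_s{c}_{i}" for c in range(config.n_states) for i in range(per)]
    gene_ids = (
        graph.gene_ids if graph is not None
        else [f"g{i:04d}" for i in range(config.n_genes)]
    )
    return SimulatedCells(
        CountMatrix(ids, list(gene_ids), counts), states, means, libs
    )


def apply_perturbation(
    cells: SimulatedCells,
    graph: DirectedGeneGraph,
    spec: PerturbationSpec,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> CountMatrix:
    """Resample every cell's counts with the perturbation applied to its
    state's means; only the driver and its graph descendants shift in
    expectation."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    means = cells.state_means[cells.states] * spec.effect
    counts, _ = _draw_counts(means, config, rng)
    driver_name = graph.gene_ids[spec.driver]
    ids = [f"pert_{driver_name}_{cid}" for cid in cells.counts.cell_ids]
    return CountMatrix(ids, list(cells.counts.gene_ids), counts)


def _pick_drivers(
    graph: DirectedGeneGraph,
    base_means: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[int]:
    out_deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    thresh = np.quantile(base_means, config.driver_expr_quantile)
    min_deg = config.driver_min_outdegree
    eligible = np.flatnonzero((out_deg >= min_deg) & (base_means >= thresh))
    while eligible.size < config.n_drivers and min_deg > 0:
        min_deg -= 1
        eligible = np.flatnonzero((out_deg >= min_deg) & (base_means >= thresh))
    if eligible.size < config.n_drivers:
        raise ValidationError("graph too sparse to pick the requested drivers")
    return sorted(rng.choice(eligible, size=config.n_drivers, replace=False).tolist())


def build_pair_dataset(
    config: SimConfig,
    split: str = "in_domain",
    graph: DirectedGeneGraph | None = None,
    seed: int | None = None,
) -> PairedSimData:
    """Controls plus perturbed cells for K drivers across C states, paired
    into (same-state control, perturbed cell, driver) triples.

    ``in_domain`` holds out a random fraction of pairs; ``out_of_domain``
    holds out every pair of the last state.  Same seed, same dataset.
    """
    if split not in ("in_domain", "out_of_domain"):
        raise ValueError(f"unknown split {split!r}")
    if split == "out_of_domain" and config.n_states < 2:
        raise ValidationError("out_of_domain needs at least 2 states")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if graph is None:
        graph = generate_graph(config.n_genes, config.graph_density, rng)
    means = _state_means(config, rng)
    base = means.mean(axis=0)
    drivers = _pick_drivers(graph, base, config, rng)
    driver_names = [graph.gene_ids[d] for d in drivers]

    ids: list[str] = []
    blocks: list[np.ndarray] = []
    states: dict[str, int] = {}
    ctrl_ids_by_state: dict[int, list[str]] = {}
    for c in range(config.n_states):
        m = np.tile(means[c], (config.controls_per_state, 1))
        counts, _ = _draw_counts(m, config, rng)
        cids = [f"ctrl_s{c}_{i}" for i in range(config.controls_per_state)]
        ids.extend(cids)
        blocks.append(counts)
        ctrl_ids_by_state[c] = cids
        states.update({cid: c for cid in cids})

    pairs: list[Pair] = []
    held_state = config.n_states - 1
    for d, dname in zip(drivers, driver_names):
        spec = PerturbationSpec.from_driver(graph, d, config)
        for c in range(config.n_states):
            m = np.tile(means[c] * spec.effect, (config.cells_per_pert, 1))
            counts, _ = _draw_counts(m, config, rng)
            for i in range(config.cells_per_pert):
                cid = f"pert_s{c}_{dname}_{i}"
                ids.append(cid)
                states[cid] = c
            blocks.append(counts)
            ctrl_pick = rng.choice(
                config.controls_per_state, size=config.cells_per_pert
            )
            for i, ci in enumerate(ctrl_pick):
                cid = f"pert_s{c}_{dname}_{i}"
                if split == "out_of_domain":
                    tag = "test" if c == held_state else "train"
                else:
                    tag = "test" if rng.random() < config.holdout_frac else "train"
                pairs.append(
                    Pair(ctrl_ids_by_state[c][ci], cid, dname, split=tag)
                )
    counts_all = np.concatenate(blocks, axis=0)
    cm = CountMatrix(ids, list(graph.gene_ids), counts_all)
    dataset = PairedDataset(pairs, candidate_genes=sorted(driver_names))
    return PairedSimData(cm, dataset, graph, states, driver_names, config)
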