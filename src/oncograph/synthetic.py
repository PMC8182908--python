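"""Synthetic interactomes, pathway annotations and labeled molecule sets.

The generator emulates the statistical structure the classifier assumes about
real PPI / drug-target data, at desk scale:

* a sparse, connected, heavy-tailed interactome (preferential attachment by
  default; a stochastic block model for planted-module experiments);
* a pathway annotation covering only a minority of genes, with a small group
  of mutually overlapping *cancer* pathways drawn from one graph-local gene
  module (so the planted anticancer mechanism is modular, not a scattered
  gene list);
* a heavily imbalanced drug set in which positives (anticancer) concentrate
  their targets in cancer-pathway genes with probability ``p_cancer_target``
  while negatives use the background rate ``p_background``;
* unlabeled food molecules, a fraction of which are generated from the
  positive-drug mechanism (that generating mechanism is recorded as ground
  truth for ranking evaluation only, never used in training).

Everything is deterministic given (config, seed) and is emitted in exactly the
text formats :mod:`oncograph.interactome` reads.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .interactome import (
    Interactome,
    LabeledDataset,
    MoleculeSignal,
    PathwayAnnotation,
    largest_connected_component,
    write_cancer_flags,
    write_edge_list,
    write_gmt,
    write_labels,
    write_molecule_targets,
)

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "generate_pathways",
    "generate_labeled_molecules",
    "generate_all",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the imbalance and partial pathway coverage of the real
    drug/interactome data (10.2% positives; ~30% of genes in >=1 pathway) at a
    graph size that trains in seconds.
    """

    n_genes: int = 300
    graph_model: str = "preferential_attachment"  # or "stochastic_block"
    edges_per_node: int = 3
    n_pathways: int = 24
    pathway_size_range: tuple[int, int] = (10, 40)
    n_cancer_pathways: int = 4
    pathway_coverage: float = 0.3
    cancer_module_size: int = 40
    n_drugs: int = 400
    frac_positive: float = 0.102
    targets_per_molecule: float = 5.0
    p_cancer_target: float = 0.6
    p_background: float = 0.02
    n_food: int = 100
    frac_food_anticancer_like: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_positive < 1:
            raise ValueError("frac_positive must lie in (0,1)")
        if self.p_cancer_target <= self.p_background:
            raise ValueError("p_cancer_target must exceed p_background for a learnable signal")
        if self.n_cancer_pathways > self.n_pathways:
            raise ValueError("n_cancer_pathways cannot exceed n_pathways")
        if self.graph_model not in ("preferential_attachment", "stochastic_block"):
            raise ValueError(f"unknown graph_model {self.graph_model!r}")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def generate_interactome(cfg: SyntheticConfig) -> Interactome:
    """Draw a connected undirected graph with the configured topology.

    Preferential attachment yields a heavy-tailed degree distribution akin to
    PPI networks and is connected by construction.  A stochastic-block draw may
    be disconnected; its largest component is kept (size logged via warning).
    """
    if cfg.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    seed = int(_rng(cfg, 0).integers(2**31 - 1))
    if cfg.graph_model == "preferential_attachment":
        gx = nx.barabasi_albert_graph(cfg.n_genes, min(cfg.edges_per_node, cfg.n_genes - 1),
                                      seed=seed)
    else:
        n_blocks = 5
        sizes = [cfg.n_genes // n_blocks] * n_blocks
        sizes[-1] += cfg.n_genes - sum(sizes)
        p_in = min(1.0, 2.0 * cfg.edges_per_node / max(1, sizes[0]))
        p_out = p_in / 10.0
        probs = [[p_in if i == j else p_out for j in range(n_blocks)] for i in range(n_blocks)]
        gx = nx.stochastic_block_model(sizes, probs, seed=seed)
    gene_ids = [_gene_id(i) for i in range(gx.number_of_nodes())]
    adj = nx.to_scipy_sparse_array(gx, nodelist=sorted(gx.nodes()), format="csr")
    adj = sp.csr_matrix((adj > 0).astype(np.float64))
    g = Interactome(gene_ids=gene_ids, adjacency=adj)
    lcc = largest_connected_component(g)
    if lcc.n_genes < g.n_genes:
        warnings.warn(
            f"graph draw disconnected; kept largest component "
            f"({lcc.n_genes}/{g.n_genes} genes)",
            stacklevel=2,
        )
    return lcc


def _grow_module(g: Interactome, size: int, rng: np.random.Generator) -> np.ndarray:
    """BFS-grow a connected gene module of ``size`` nodes around a high-degree seed."""
    deg = g.degrees()
    seed_node = int(np.argmax(deg))
    adj = g.adjacency
    visited = {seed_node}
    frontier = [seed_node]
    order = [seed_node]
    while frontier and len(order) < size:
        nxt: list[int] = []
        for u in frontier:
            nbrs = adj.indices[adj.indptr[u]:adj.indptr[u + 1]]
            nbrs = rng.permutation(nbrs)
            for v in nbrs:
                v = int(v)
                if v not in visited:
                    visited.add(v)
                    order.append(v)
                    nxt.append(v)
                    if len(order) >= size:
                        break
            if len(order) >= size:
                break
        frontier = nxt
    return np.array(order[:size], dtype=np.int64)


def generate_pathways(g: Interactome, cfg: SyntheticConfig) -> PathwayAnnotation:
    """Draw ``n_pathways`` gene sets covering ~``pathway_coverage`` of the genes.

    The first ``n_cancer_pathways`` sets are cancer-flagged and are drawn as
    overlapping subsets of one graph-local module, sharing a common core, so
    the planted signal is modular.  Remaining (background) pathways partition
    the rest of the covered-gene pool and are topped up to their drawn sizes.
    """
    rng = _rng(cfg, 1)
    n = g.n_genes
    lo, hi = cfg.pathway_size_range
    if lo < 1 or hi < lo or hi > n:
        raise ValueError("infeasible pathway_size_range")
    n_cov = int(round(cfg.pathway_coverage * n))
    module_size = min(cfg.cancer_module_size, n_cov)
    module = _grow_module(g, module_size, rng)

    other_pool = np.setdiff1d(np.arange(n), module)
    n_extra = n_cov - module_size
    if n_extra < 0 or n_extra > other_pool.size:
        raise ValueError("infeasible pathway_coverage")
    covered_rest = rng.choice(other_pool, size=n_extra, replace=False)

    n_bg = cfg.n_pathways - cfg.n_cancer_pathways
    sizes_bg = rng.integers(lo, hi + 1, size=n_bg)
    if n_bg and sizes_bg.sum() < covered_rest.size:
        # guarantee every pool gene can be assigned somewhere
        sizes_bg = np.maximum(sizes_bg, int(np.ceil(covered_rest.size / n_bg)))
        sizes_bg = np.minimum(sizes_bg, hi)
        if sizes_bg.sum() < covered_rest.size:
            raise ValueError("infeasible pathway_coverage: background pathways too small")

    rows = np.zeros((cfg.n_pathways, n), dtype=np.int8)
    # cancer pathways: shared core plus private members from the module
    core_size = max(1, int(round(0.5 * module_size)))
    core = module[:core_size]
    for i in range(cfg.n_cancer_pathways):
        size_i = int(rng.integers(lo, hi + 1))
        size_i = min(size_i, module_size)
        extra = max(0, size_i - core_size)
        private = rng.choice(module[core_size:], size=min(extra, module_size - core_size),
                             replace=False) if module_size > core_size else np.array([], int)
        rows[i, core] = 1
        rows[i, private] = 1
    # coverage guarantee: every module gene belongs to >=1 cancer pathway
    uncovered = module[~rows[: cfg.n_cancer_pathways, module].any(axis=0)]
    for gidx in uncovered:
        rows[int(rng.integers(cfg.n_cancer_pathways)), gidx] = 1
    # background pathways: deal the remaining covered genes round-robin, then
    # top each set up to its drawn size with repeats from the pool
    shuffled = rng.permutation(covered_rest)
    capacity = sizes_bg.copy() if n_bg else np.zeros(0, dtype=np.int64)
    j = 0
    for gidx in shuffled:
        # next background pathway with spare capacity
        for _ in range(n_bg):
            k = j % n_bg
            j += 1
            if capacity[k] > 0:
                rows[cfg.n_cancer_pathways + k, gidx] = 1
                capacity[k] -= 1
                break
    covered_all = np.concatenate([module, covered_rest]).astype(np.int64)
    for k in range(n_bg):
        row = cfg.n_cancer_pathways + k
        deficit = int(sizes_bg[k] - rows[row].sum())
        if deficit > 0 and covered_rest.size:
            pool = np.setdiff1d(covered_rest, np.flatnonzero(rows[row]))
            take = rng.choice(pool, size=min(deficit, pool.size), replace=False)
            rows[row, take] = 1
        if rows[row].sum() == 0:
            # invariant: every pathway keeps >=1 member; at tiny coverage the
            # background pool can run dry, so borrow one covered gene
            rows[row, int(rng.choice(covered_all))] = 1
    names = [f"CANCER_PATHWAY_{i:02d}" for i in range(cfg.n_cancer_pathways)] + [
        f"PATHWAY_{k:02d}" for k in range(n_bg)
    ]
    flags = np.array([True] * cfg.n_cancer_pathways + [False] * n_bg)
    pa = PathwayAnnotation(pathway_ids=names, membership=rows, cancer_flag=flags)
    achieved = pa.covered_genes().mean()
    if abs(achieved - cfg.pathway_coverage) > 0.05:
        warnings.warn(
            f"achieved pathway coverage {achieved:.3f} deviates from "
            f"target {cfg.pathway_coverage:.3f} by more than 5 pp",
            stacklevel=2,
        )
    return pa


def _draw_signal(
    n_genes: int,
    cancer_pool: np.ndarray,
    other_pool: np.ndarray,
    p_cancer: float,
    mean_targets: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = int(rng.poisson(mean_targets))
    if t == 0:
        t = int(rng.poisson(mean_targets))  # one resample
        if t == 0:
            warnings.warn("zero-target molecule kept after resample", stacklevel=3)
    x = np.zeros(n_genes, dtype=np.int8)
    for _ in range(t):
        if rng.random() < p_cancer and cancer_pool.size:
            x[int(rng.choice(cancer_pool))] = 1
        else:
            x[int(rng.choice(other_pool))] = 1
    return x


def generate_labeled_molecules(
    g: Interactome,
    pa: PathwayAnnotation,
    cfg: SyntheticConfig,
) -> tuple[LabeledDataset, list[MoleculeSignal], np.ndarray]:
    """Draw the labeled drug set and the unlabeled food set.

    Returns ``(drugs, foods, food_mechanism)`` where ``food_mechanism[i]`` is 1
    when food molecule i was generated from the positive-drug mechanism
    (ground truth for ranking evaluation only).
    """
    rng = _rng(cfg, 2)
    cancer_pool = np.flatnonzero(pa.cancer_gene_mask())
    if cancer_pool.size == 0:
        raise ValueError("cancer-gene pool is empty")
    other_pool = np.setdiff1d(np.arange(g.n_genes), cancer_pool)
    n_pos = int(round(cfg.n_drugs * cfg.frac_positive))
    labels = np.zeros(cfg.n_drugs, dtype=np.int64)
    labels[:n_pos] = 1
    signals: list[MoleculeSignal] = []
    for i in range(cfg.n_drugs):
        p = cfg.p_cancer_target if labels[i] else cfg.p_background
        x = _draw_signal(g.n_genes, cancer_pool, other_pool, p,
                         cfg.targets_per_molecule, rng)
        signals.append(MoleculeSignal(molecule_id=f"drug{i:05d}", role="drug", x=x))
    foods: list[MoleculeSignal] = []
    n_pos_food = int(round(cfg.n_food * cfg.frac_food_anticancer_like))
    food_mech = np.zeros(cfg.n_food, dtype=np.int64)
    food_mech[:n_pos_food] = 1
    for i in range(cfg.n_food):
        p = cfg.p_cancer_target if food_mech[i] else cfg.p_background
        x = _draw_signal(g.n_genes, cancer_pool, other_pool, p,
                         cfg.targets_per_molecule, rng)
        foods.append(MoleculeSignal(molecule_id=f"food{i:05d}", role="food", x=x))
    return LabeledDataset(signals=signals, labels=labels), foods, food_mech


def generate_all(cfg: SyntheticConfig):
    """Convenience: graph, pathways, drugs, foods, food mechanism in one call."""
    g = generate_interactome(cfg)
    pa = generate_pathways(g, cfg)
    data, foods, mech = generate_labeled_molecules(g, pa, cfg)
    return g, pa, data, foods, mech


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> None:
    """Generate and emit a full dataset in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, pa, data, foods, mech = generate_all(cfg)
    write_edge_list(g, outdir / "edges.tsv")
    write_gmt(pa, g.gene_ids, outdir / "pathways.gmt")
    write_cancer_flags(pa, outdir / "cancer_flags.tsv")
    write_molecule_targets(list(data.signals) + foods, g.gene_ids, outdir / "targets.tsv")
    write_labels(data, outdir / "labels.tsv")
    manifest = dataclasses.asdict(cfg)
    manifest["food_mechanism"] = mech.tolist()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
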