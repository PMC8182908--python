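import dataclasses

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from oncograph.interactome import Interactome, build_spectral_operators
from oncograph.layers import init_model
from oncograph.synthetic import SyntheticConfig, generate_all
from oncograph.training import TrainingConfig, stratified_splits, train_model


def random_interactome(n: int, m: int = 2, seed: int = 0) -> Interactome:
    """Connected preferential-attachment test graph with string gene ids."""
    gx = nx.barabasi_albert_graph(n, m, seed=seed)
    adj = sp.csr_matrix(nx.to_scipy_sparse_array(gx, nodelist=range(n),
                                                 format="csr").astype(float))
    return Interactome(gene_ids=[f"g{i:03d}" for i in range(n)], adjacency=adj)


@pytest.fixture(scope="session")
def two_node():
    g = Interactome(["A", "B"], sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
    return g, build_spectral_operators(g)


@pytest.fixture(scope="session")
def toy_graph():
    g = random_interactome(10, 2, seed=3)
    return g, build_spectral_operators(g)


@pytest.fixture(scope="session")
def small_synthetic():
    """A quick strong-signal dataset: graph, pathways, drugs, split plan."""
    cfg = SyntheticConfig(n_genes=120, n_drugs=160, cancer_module_size=25,
                          n_pathways=12, n_cancer_pathways=3,
                          pathway_size_range=(6, 20), seed=7)
    g, pa, data, foods, mech = generate_all(cfg)
    ops = build_spectral_operators(g)
    plan = stratified_splits(data.labels, seed=7)
    return g, ops, pa, data, foods, mech, plan


@pytest.fixture(scope="session")
def trained_toy(small_synthetic):
    """A ChebNet trained on one fold of the small synthetic dataset."""
    g, ops, pa, data, _foods, _mech, plan = small_synthetic
    arch = init_model(n_nodes=g.n_genes, kind="cheb", n_conv_layers=2, cheb_n=3,
                      dropout_layers=2, seed=17, gene_ids=g.gene_ids)
    cfg = TrainingConfig(seed=17, max_epochs=40)
    result = train_model(data, ops, arch, cfg, plan.folds[0])
    return result


@pytest.fixture()
def single_fold_plan(small_synthetic):
    _g, _ops, _pa, _data, _foods, _mech, plan = small_synthetic
    return dataclasses.replace(plan, folds=[plan.folds[0]])
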