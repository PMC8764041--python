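import networkx as nx
import numpy as np
import pandas as pd
import pytest

from digestnet.community import network_filter, subsample_steady_state, to_relative
from digestnet.correlation import select_edges, spearman_matrix
from digestnet.network import CoNetwork, build_network
from digestnet.synthetic import SimConfig, simulate_community, simulate_reactor_params


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic fixture: 52 samples, 5 groups, planted modules."""
    cfg = SimConfig()
    table, truth = simulate_community(cfg)
    params = simulate_reactor_params(cfg, truth)
    return cfg, table, truth, params


@pytest.fixture(scope="session")
def group_networks(default_sim):
    """Thresholded per-group networks for the groups with >= 8 retained samples."""
    cfg, table, truth, _ = default_sim
    rel, _ = subsample_steady_state(to_relative(table), truth.metadata)
    nets = {}
    for g in cfg.group_names:
        samples = [s for s in truth.metadata.index[truth.metadata.group == g]
                   if s in rel.data.index]
        if len(samples) < 8:
            continue
        filtered, _ = network_filter(rel.subset_samples(samples))
        edges = select_edges(spearman_matrix(filtered))
        abund = to_relative(rel.subset_samples(samples)).data[filtered.taxon_ids].mean(axis=0)
        nets[g] = build_network(edges, pd.DataFrame({"abundance": abund}), group=g)
    return nets


@pytest.fixture
def two_triangles():
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return CoNetwork(graph=g, group="toy")


@pytest.fixture
def bridged_cliques():
    """Two triangles joined through a bridge node: 0-1-2, bridge 3, 4-5-6."""
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (5, 6), (4, 6)])
    return CoNetwork(graph=g, group="toy",
                     partition={0: 0, 1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 1})


def random_graphs(n_graphs, n_lo, n_hi, seed, ensure_edges=True):
    """Seeded stream of small G(n, p) graphs for oracle comparison."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_graphs:
        n = int(rng.integers(n_lo, n_hi + 1))
        p = float(rng.uniform(0.15, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if ensure_edges and g.number_of_edges() == 0:
            continue
        out.append(g)
    return out
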