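"""Co-occurrence graph construction and network-level topology.

The per-group graph is an undirected simple graph whose edges are the
correlation pairs that passed thresholding; edge sign and |rho| weight are
stored as attributes, but every topology metric here is computed on the
unweighted, sign-agnostic skeleton. The topology panel gathers, for one
network: clustering coefficient (with an Erdos-Renyi random baseline),
modularity of a detected partition, positive-edge ratio, average path length,
average (normalized) degree, average normalized betweenness, and order/size.

A discrete power-law fit of the degree sequence (maximum-likelihood exponent,
KS-minimizing lower cutoff, parametric-bootstrap goodness of fit) is provided
for degree-distribution characterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CoNetwork",
    "TopologyPanel",
    "build_network",
    "clustering_coefficient",
    "modularity_partition",
    "average_path_length",
    "positive_ratio",
    "degree_stats",
    "betweenness_stats",
    "random_baseline",
    "powerlaw_fit",
    "topology_panel",
]


@dataclass
class CoNetwork:
    """One group's co-occurrence network.

    ``graph`` is a simple undirected networkx graph; nodes carry ``abundance``
    (mean relative abundance over the group's samples) and optional
    ``lineage``; edges carry ``sign`` (+1/-1) and ``weight`` (|rho|).
    ``partition`` (node -> module id) is filled by :func:`modularity_partition`.
    """

    graph: nx.Graph
    group: str = ""
    partition: dict | None = None
    isolated_dropped: list = None

    @property
    def order(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def size(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class TopologyPanel:
    """Network-level property row for one group."""

    group: str
    order: int
    size: int
    clustering_coefficient: float
    random_clustering_coefficient: float
    random_clustering_sd: float
    modularity: float
    n_modules: int
    positive_ratio: float
    average_path_length: float
    average_degree: float
    average_normalized_degree: float
    average_normalized_betweenness: float

    def as_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def build_network(edges: pd.DataFrame, node_metadata: pd.DataFrame | None = None,
                  group: str = "") -> CoNetwork:
    """Build the group graph from a kept-edge list.

    Duplicate pairs collapse to one edge; conflicting signs for the same pair
    raise. Nodes present in ``node_metadata`` (index = taxon id, columns e.g.
    ``abundance``, ``lineage``) but with no kept edge are logged as isolated
    and excluded from the graph.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        u, v = row.source, row.target
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        sign = int(row.sign)
        if g.has_edge(u, v):
            if g[u][v]["sign"] != sign:
                raise ValueError(f"conflicting signs for edge ({u}, {v})")
            continue
        g.add_edge(u, v, sign=sign, weight=float(row.weight), rho=float(row.rho))
    isolated: list = []
    if node_metadata is not None:
        isolated = [t for t in node_metadata.index if t not in g]
        for node in g.nodes:
            if node in node_metadata.index:
                for col in node_metadata.columns:
                    g.nodes[node][col] = node_metadata.loc[node, col]
    if g.number_of_edges() == 0:
        warnings.warn(f"group {group!r}: no edges passed thresholds; empty network")
    return CoNetwork(graph=g, group=group, isolated_dropped=isolated)


def _skeleton(net) -> nx.Graph:
    return net.graph if isinstance(net, CoNetwork) else net


def clustering_coefficient(net, variant: str = "local_average") -> float:
    """Unweighted clustering coefficient.

    ``local_average`` (default): mean over nodes of triangles/(k(k-1)/2), with
    degree<2 nodes contributing 0. ``transitivity``: global 3*triangles/triads
    — exposed because published panels use either convention.
    """
    g = _skeleton(net)
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined on an empty graph")
    if variant == "local_average":
        return float(nx.average_clustering(g, count_zeros=True))
    if variant == "transitivity":
        return float(nx.transitivity(g))
    raise ValueError(f"unknown variant {variant!r}")


def modularity_partition(net, method: str = "greedy", seed: int = 0,
                         resolution: float = 1.0) -> tuple[dict, float]:
    """Detect modules on the unweighted skeleton and score Newman-Girvan Q.

    Q = sum_c [ e_c/m - (d_c/2m)^2 ]. ``greedy`` (default) is deterministic
    agglomerative modularity maximization, so repeated runs of a pipeline give
    identical partitions; ``louvain`` is the seeded randomized alternative.
    The partition is stored on the CoNetwork when one is passed.
    """
    g = _skeleton(net)
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined without edges")
    h = nx.Graph(g.edges)  # strip weights: sign-agnostic, unweighted
    h.add_nodes_from(g.nodes)
    if h.number_of_nodes() <= 8 and resolution == 1.0:
        # exact optimum is affordable on tiny graphs (Bell(8) = 4140 partitions)
        comms = _exact_max_modularity(h)
        q = float(nx.community.modularity(h, comms))
        partition = {node: i for i, c in enumerate(comms) for node in c}
        if isinstance(net, CoNetwork):
            net.partition = partition
        return partition, q
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(h, resolution=resolution)
    elif method == "louvain":
        comms = nx.community.louvain_communities(h, seed=seed, resolution=resolution)
    else:
        raise ValueError(f"unknown method {method!r}")
    comms = _refine_partition(h, [set(c) for c in comms], resolution)
    q = float(nx.community.modularity(h, comms, resolution=resolution))
    partition = {node: i for i, c in enumerate(comms) for node in c}
    if isinstance(net, CoNetwork):
        net.partition = partition
    return partition, q


def _exact_max_modularity(g: nx.Graph) -> list[set]:
    """Maximum-modularity partition by restricted-growth enumeration (n <= 8)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    best_q, best = -np.inf, None
    code = [0] * n

    def walk(i: int, n_blocks: int):
        nonlocal best_q, best
        if i == n:
            blocks: list[set] = [set() for _ in range(n_blocks)]
            for node, b in zip(nodes, code):
                blocks[b].add(node)
            q = nx.community.modularity(g, blocks)
            if q > best_q:
                best_q, best = q, blocks
            return
        for b in range(n_blocks + 1):
            code[i] = b
            walk(i + 1, max(n_blocks, b + 1))

    walk(0, 0)
    return best


def _refine_partition(g: nx.Graph, comms: list[set], resolution: float) -> list[set]:
    """Deterministic local refinement: single-node moves and community merges.

    Agglomerative detection can stop short of the modularity optimum on small
    graphs; hill-climbing over node reassignments (including to a fresh
    singleton) and pairwise merges until no move improves Q closes most of
    that gap without introducing randomness.
    """
    def q_of(cs) -> float:
        return nx.community.modularity(g, [c for c in cs if c], resolution=resolution)

    comms = [set(c) for c in comms if c]
    best_q = q_of(comms)
    improved = True
    while improved:
        improved = False
        for node in sorted(g.nodes):
            src = next(i for i, c in enumerate(comms) if node in c)
            targets = list(range(len(comms))) + [len(comms)]
            for dst in targets:
                if dst == src:
                    continue
                trial = [set(c) for c in comms] + ([set()] if dst == len(comms) else [])
                trial[src].discard(node)
                trial[dst].add(node)
                q = q_of(trial)
                if q > best_q + 1e-12:
                    comms = [c for c in trial if c]
                    best_q = q
                    improved = True
                    break
        for i in range(len(comms)):
            done = False
            for j in range(i + 1, len(comms)):
                trial = [c for k, c in enumerate(comms) if k not in (i, j)]
                trial.append(comms[i] | comms[j])
                q = q_of(trial)
                if q > best_q + 1e-12:
                    comms = trial
                    best_q = q
                    improved = done = True
                    break
            if done:
                break
    return comms


def average_path_length(net) -> float:
    """Mean shortest-path length over connected node pairs (unweighted BFS).

    Disconnected pairs are excluded: on a disconnected graph this is the
    pair-count-weighted mean of the per-component averages.
    """
    g = _skeleton(net)
    if g.number_of_nodes() < 2:
        raise ValueError("average path length needs >= 2 nodes")
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # exclude self
    if pairs == 0:
        raise ValueError("no connected pairs")
    return total / pairs


def positive_ratio(net) -> float:
    """Fraction of edges whose correlation sign is positive."""
    g = _skeleton(net)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("positive ratio undefined without edges")
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    return pos / m


def degree_stats(net) -> tuple[float, float]:
    """(average degree, average normalized degree k/(order-1))."""
    g = _skeleton(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("degree stats need >= 2 nodes")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    return float(degrees.mean()), float((degrees / (n - 1)).mean())


def betweenness_stats(net) -> tuple[float, pd.Series]:
    """Average normalized betweenness and the per-node values.

    Shortest-path betweenness (Brandes accumulation), endpoints excluded,
    normalized by (n-1)(n-2)/2 for undirected graphs.
    """
    g = _skeleton(net)
    if g.number_of_nodes() < 3:
        raise ValueError("normalized betweenness needs >= 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=True, endpoints=False)
    s = pd.Series(bc, name="normalized_betweenness").sort_index()
    return float(s.mean()), s


def random_baseline(net, n_reps: int = 100, seed: int = 0) -> tuple[float, float]:
    """Clustering coefficient of Erdos-Renyi G(n, m) graphs matching order/size.

    Returns (mean, sd) over ``n_reps`` replicates — the null expectation a
    constructed network's clustering coefficient is compared against.
    """
    g = _skeleton(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    rng = np.random.default_rng(seed)
    ccs = np.empty(n_reps)
    for i in range(n_reps):
        r = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        ccs[i] = nx.average_clustering(r, count_zeros=True)
    return float(ccs.mean()), float(ccs.std(ddof=1)) if n_reps > 1 else 0.0


@dataclass(frozen=True)
class PowerlawFit:
    alpha: float
    x_min: int
    ks: float
    p_value: float
    n_tail: int
    flagged: bool = False  # too few distinct degrees for a meaningful fit


def _zeta_tail_cdf(alpha: float, x_min: int, xs: np.ndarray) -> np.ndarray:
    """P(X <= x) for the discrete power law on {x_min, x_min+1, ...}."""
    z = special.zeta(alpha, x_min)
    # cumulative sums up to max(xs)
    hi = int(xs.max())
    ks = np.arange(x_min, hi + 1, dtype=float)
    pmf = ks ** (-alpha) / z
    cdf = np.cumsum(pmf)
    return cdf[(xs - x_min).astype(int)]


def _fit_alpha(tail: np.ndarray, x_min: int) -> float:
    """Exact discrete MLE: minimize n*ln zeta(alpha, x_min) + alpha*sum(ln x)."""
    n = len(tail)
    log_sum = float(np.sum(np.log(tail)))

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, x_min)) + alpha * log_sum

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def _ks_stat(tail: np.ndarray, alpha: float, x_min: int) -> float:
    """KS distance on distinct values (correct for the ties of discrete data)."""
    xs, counts = np.unique(tail, return_counts=True)
    emp = np.cumsum(counts) / len(tail)
    model = _zeta_tail_cdf(alpha, x_min, xs)
    return float(np.max(np.abs(emp - model)))


def _sample_zeta(alpha: float, x_min: int, size: int, rng: np.random.Generator) -> np.ndarray:
    # inverse-CDF sampling with a generous precomputed support
    hi = max(10_000, x_min * 100)
    ks = np.arange(x_min, hi + 1, dtype=float)
    pmf = ks ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(ks.astype(int), size=size, p=pmf)


def powerlaw_fit(degrees, x_min_mode: str | int = "ks", n_boot: int = 100,
                 seed: int = 0) -> PowerlawFit:
    """Discrete power-law fit of a degree sequence (Clauset-style).

    The exponent alpha is the discrete maximum-likelihood estimate on the tail
    x >= x_min; ``x_min_mode='ks'`` scans candidate cutoffs and keeps the one
    minimizing the KS distance (an integer fixes the cutoff instead). The
    goodness-of-fit p-value is a parametric bootstrap: ``n_boot`` synthetic
    tails are drawn from the fitted law and p is the fraction whose refitted
    KS distance exceeds the observed one (p < 0.05 rejects the power law).

    Degree sequences with < 10 distinct positive values are fit anyway but
    flagged.
    """
    deg = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if deg.size < 2:
        raise ValueError("need at least 2 positive degrees")
    flagged = len(np.unique(deg)) < 10
    if flagged:
        warnings.warn("fewer than 10 distinct degree values; power-law fit is weakly constrained")

    if x_min_mode == "ks":
        candidates = np.unique(deg)[:-1] if len(np.unique(deg)) > 1 else np.unique(deg)
        best = None
        for xm in candidates.astype(int):
            tail = deg[deg >= xm]
            if len(tail) < 2 or np.all(tail == tail[0]):
                continue
            a = _fit_alpha(tail, xm)
            ks = _ks_stat(tail, a, xm)
            if best is None or ks < best[2]:
                best = (a, xm, ks, len(tail))
        if best is None:  # e.g. constant degrees: fall back to full sequence
            xm = int(deg.min())
            tail = deg
            a = _fit_alpha(tail, xm) if not np.all(tail == tail[0]) else float("inf")
            best = (a, xm, _ks_stat(tail, a, xm) if np.isfinite(a) else 1.0, len(tail))
        alpha, x_min, ks, n_tail = best
    else:
        x_min = int(x_min_mode)
        tail = deg[deg >= x_min]
        if len(tail) < 2:
            raise ValueError(f"fewer than 2 degrees >= x_min={x_min}")
        alpha = _fit_alpha(tail, x_min) if not np.all(tail == tail[0]) else float("inf")
        ks = _ks_stat(tail, alpha, x_min) if np.isfinite(alpha) else 1.0
        n_tail = len(tail)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        if not np.isfinite(alpha):
            # degenerate observed fit can never be beaten by synthetic tails
            break
        synth = _sample_zeta(alpha, x_min, n_tail, rng).astype(float)
        if np.all(synth == synth[0]):
            exceed += 1
            continue
        a_b = _fit_alpha(synth, x_min)
        exceed += _ks_stat(synth, a_b, x_min) >= ks
    p = exceed / n_boot if np.isfinite(alpha) else 0.0
    return PowerlawFit(alpha=float(alpha), x_min=int(x_min), ks=float(ks),
                       p_value=float(p), n_tail=int(n_tail), flagged=flagged)


def topology_panel(net: CoNetwork, n_reps: int = 100, seed: int = 0,
                   method: str = "greedy") -> TopologyPanel:
    """Assemble the full network-property row for one group (seeded, deterministic)."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("topology panel undefined on an empty network")
    partition, q = modularity_partition(net, method=method, seed=seed)
    cc = clustering_coefficient(net)
    rand_cc, rand_sd = random_baseline(net, n_reps=n_reps, seed=seed)
    apl = average_path_length(net)
    avg_deg, avg_norm_deg = degree_stats(net)
    avg_btw, _ = betweenness_stats(net)
    return TopologyPanel(
        group=net.group,
        order=net.order,
        size=net.size,
        clustering_coefficient=cc,
        random_clustering_coefficient=rand_cc,
        random_clustering_sd=rand_sd,
        modularity=q,
        n_modules=len(set(partition.values())),
        positive_ratio=positive_ratio(net),
        average_path_length=apl,
        average_degree=avg_deg,
        average_normalized_degree=avg_norm_deg,
        average_normalized_betweenness=avg_btw,
    )


def write_graphml(net: CoNetwork, path) -> None:
    """GraphML including sign, weight, module and abundance attributes."""
    g = net.graph.copy()
    if net.partition:
        nx.set_node_attributes(g, net.partition, "module")
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, (np.floating, np.integer)):
                d[k] = v.item()
    nx.write_graphml(g, path)


def write_edgelist_tsv(net: CoNetwork, path, header_comment: str = "") -> None:
    rows = [
        {"source": u, "target": v, "rho": d.get("rho", np.nan),
         "weight": d.get("weight", np.nan), "sign": d.get("sign", 1)}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows, columns=["source", "target", "rho", "weight", "sign"]).to_csv(
            fh, sep="\t", index=False)
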