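"""Per-node ecological roles: within/among-module connectivity and hub ranking.

Given a network and its module partition, each taxon gets a within-module
degree z-score Z_i and an among-module participation coefficient P_i:

    Z_i = (kappa_i - mean kappa over i's module) / sd(kappa over module)
    P_i = 1 - sum_s (k_is / k_i)^2

with kappa_i the node's links inside its own module and k_is its links into
module s (the node's own module included). The (Z, P) plane splits into four
ecological roles at the conventional thresholds Z = 2.5, P = 0.62:
peripherals, module hubs, connectors and network hubs. Ranking nodes by
normalized degree and normalized betweenness identifies the central hubs and
the communication ("gatekeeper") taxa; comparing those ranks with relative
abundance tests whether low-abundance genera occupy central roles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .network import CoNetwork, betweenness_stats

__all__ = ["zi_pi", "classify_roles", "rank_hubs", "abundance_role_association"]

ROLES = ("peripheral", "module_hub", "connector", "network_hub")


def zi_pi(net: CoNetwork) -> pd.DataFrame:
    """Z_i and P_i for every node, plus degree/centrality/abundance columns.

    Requires ``net.partition``. Z_i uses the population sd of within-module
    degree over the node's module; a zero sd (single-node or degree-regular
    module) maps to Z_i = 0 with ``zi_degenerate=True`` rather than NaN.
    """
    if net.partition is None:
        raise ValueError("run modularity_partition first: no module partition on network")
    g = net.graph
    part = net.partition
    n = g.number_of_nodes()
    rows = []
    # within-module degree of every node, grouped by module
    kappa = {
        node: sum(1 for nb in g[node] if part[nb] == part[node]) for node in g
    }
    by_module: dict[int, list[float]] = {}
    for node, k in kappa.items():
        by_module.setdefault(part[node], []).append(k)
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}  # population sd

    _, btw = betweenness_stats(net) if n >= 3 else (np.nan, pd.Series(dtype=float))
    for node in sorted(g.nodes):
        k_i = g.degree(node)
        links_per_module: dict[int, int] = {}
        for nb in g[node]:
            links_per_module[part[nb]] = links_per_module.get(part[nb], 0) + 1
        assert sum(links_per_module.values()) == k_i
        pi = 1.0 - sum((ks / k_i) ** 2 for ks in links_per_module.values()) if k_i else 0.0
        sd = mod_sd[part[node]]
        degenerate = sd == 0
        zi = 0.0 if degenerate else (kappa[node] - mod_mean[part[node]]) / sd
        rows.append(
            {
                "taxon_id": node,
                "module": part[node],
                "degree": k_i,
                "within_module_degree": kappa[node],
                "zi": zi,
                "zi_degenerate": degenerate,
                "pi": pi,
                "normalized_degree": k_i / (n - 1) if n > 1 else np.nan,
                "normalized_betweenness": btw.get(node, np.nan),
                "abundance": g.nodes[node].get("abundance", np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def classify_roles(nodes: pd.DataFrame, z_threshold: float = 2.5,
                   p_threshold: float = 0.62) -> pd.DataFrame:
    """Assign the four (Z, P)-quadrant roles.

    peripheral (Z<=z_t, P<=p_t), module_hub (Z>z_t, P<=p_t),
    connector (Z<=z_t, P>p_t), network_hub (Z>z_t, P>p_t).
    Thresholds follow the Guimera-Amaral convention and are configurable.
    """
    out = nodes.copy()
    hi_z = out["zi"] > z_threshold
    hi_p = out["pi"] > p_threshold
    role = np.where(
        hi_z & hi_p, "network_hub",
        np.where(hi_z, "module_hub", np.where(hi_p, "connector", "peripheral")),
    )
    out["role"] = pd.Categorical(role, categories=list(ROLES))
    out.attrs["z_threshold"] = z_threshold
    out.attrs["p_threshold"] = p_threshold
    return out


def rank_hubs(nodes: pd.DataFrame, top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Top taxa by normalized degree and by normalized betweenness.

    Deterministic: ties broken by taxon id. Returns (by_degree, by_betweenness,
    overlap) where overlap counts taxa appearing in both top lists — central
    hubs and communication roles typically share only a couple of taxa.
    """
    def top(col: str) -> pd.DataFrame:
        ranked = nodes.sort_index(kind="mergesort").sort_values(
            col, ascending=False, kind="mergesort"
        )
        return ranked.head(top_n)

    by_deg = top("normalized_degree")
    by_btw = top("normalized_betweenness")
    overlap = len(set(by_deg.index) & set(by_btw.index))
    return by_deg, by_btw, overlap


def abundance_role_association(nodes: pd.DataFrame, low_abundance: float = 0.001,
                               top_n: int = 10) -> dict:
    """Spearman association of relative abundance with centrality.

    Returns rho and p for abundance vs normalized degree and vs normalized
    betweenness, plus the low-abundance taxa (relative abundance below
    ``low_abundance``) that nevertheless appear in either top-``top_n``
    centrality list — the signature of low-abundance keystones.
    """
    if len(nodes) < 2:
        raise ValueError("association needs >= 2 nodes")
    ab = nodes["abundance"].to_numpy(dtype=float)
    if np.isnan(ab).all():
        raise ValueError("no abundance annotations on nodes")
    out: dict = {}
    for col in ("normalized_degree", "normalized_betweenness"):
        rho, p = stats.spearmanr(ab, nodes[col].to_numpy(dtype=float))
        out[col] = {"rho": float(rho), "p": float(p)}
    by_deg, by_btw, _ = rank_hubs(nodes, top_n=top_n)
    flagged = sorted(
        set(by_deg.index[by_deg["abundance"] < low_abundance])
        | set(by_btw.index[by_btw["abundance"] < low_abundance])
    )
    out["low_abundance_keystones"] = flagged
    return out


def write_node_tsv(nodes: pd.DataFrame, path, group: str = "", header_comment: str = "") -> None:
    """One row per taxon; roles summary appended as comment lines."""
    df = nodes.copy()
    if group:
        df.insert(0, "group", group)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if "role" in df.columns:
            counts = df["role"].value_counts()
            fh.write("# roles: " + ", ".join(f"{r}={counts.get(r, 0)}" for r in ROLES) + "\n")
        df.to_csv(fh, sep="\t")
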