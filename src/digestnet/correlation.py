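"""All-pairs Spearman correlation and edge selection for network construction.

Edges are the taxon pairs whose Spearman rank correlation passes the study
thresholds (|rho| > 0.6, p < 0.01 by default). The p-value uses the usual
t-approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom
(two-sided); an exact permutation p-value is available for small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "spearman_matrix", "select_edges", "permutation_pvalue"]


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Spearman rho and p over the taxa of one group.

    ``rho``/``p`` are symmetric taxon x taxon DataFrames (diagonal excluded
    from edge candidacy). ``excluded`` lists constant taxa whose correlation
    is undefined; their rows/columns are NaN.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n_samples: int
    excluded: list[str] = field(default_factory=list)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rho.index)


_EXACT_NULL_CACHE: dict[int, np.ndarray] = {}


def _exact_null_rhos(n: int) -> np.ndarray:
    """Sorted |rho| of all n! rank permutations (tie-free null), cached per n."""
    if n not in _EXACT_NULL_CACHE:
        perms = np.array(list(permutations(range(1, n + 1))), dtype=np.int8)
        base = np.arange(1, n + 1, dtype=float)
        bc = base - base.mean()
        pc = perms - (n + 1) / 2
        rhos = (pc @ bc) / (np.sqrt(bc @ bc) * np.sqrt((pc * pc).sum(axis=1)))
        _EXACT_NULL_CACHE[n] = np.sort(np.abs(rhos))
    return _EXACT_NULL_CACHE[n]


def spearman_matrix(table, p_mode: str = "t") -> CorrelationResult:
    """Spearman correlation (mid-ranks for ties) for every taxon pair.

    Constant taxa have no rank variation, so their correlations are undefined;
    they are flagged in ``excluded`` and left NaN rather than aborting.
    Requires >= 4 samples. |rho| = 1 yields p = 0 under the t-approximation.

    ``p_mode='t'`` (default) uses the two-sided t-approximation, which is
    anticonservative for n below about 12; ``p_mode='exact'`` (n <= 10)
    replaces p with the exact two-sided permutation tail probability of |rho|
    under the tie-free null, enumerated once per n — the small-n option for
    calibrated false-positive control.
    """
    data = table.data if hasattr(table, "data") else pd.DataFrame(table)
    n = len(data)
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation, got {n}")
    x = data.to_numpy(dtype=float)
    const_mask = np.ptp(x, axis=0) == 0
    constant = data.columns[const_mask].tolist()
    # scipy returns a bare NaN when any column is constant: correlate the
    # varying taxa only and reinsert NaN rows/columns for the flagged ones
    xv = x[:, ~const_mask]
    if xv.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant taxa")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_v, p_v = stats.spearmanr(xv)
    if np.ndim(rho_v) == 0:  # spearmanr collapses the 2-taxon case to scalars
        rho_v = np.array([[1.0, rho_v], [rho_v, 1.0]])
        p_v = np.array([[0.0, p_v], [p_v, 0.0]])
    k = x.shape[1]
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    var_idx = np.nonzero(~const_mask)[0]
    rho[np.ix_(var_idx, var_idx)] = rho_v
    p[np.ix_(var_idx, var_idx)] = p_v
    if p_mode == "exact":
        if n > 10:
            raise ValueError("exact permutation p-values limited to n <= 10")
        null = _exact_null_rhos(n)
        absr = np.abs(rho)
        ok = np.isfinite(absr)
        # P(|rho_null| >= |rho_obs|), right-closed with a tolerance for float ties
        counts = null.size - np.searchsorted(null, absr[ok] - 1e-12, side="left")
        p = np.where(ok, 1.0, np.nan)
        p[ok] = counts / null.size
    elif p_mode != "t":
        raise ValueError(f"unknown p_mode {p_mode!r}")
    ids = data.columns
    rho_df = pd.DataFrame(rho, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    rho_df.loc[constant, :] = np.nan
    rho_df.loc[:, constant] = np.nan
    p_df.loc[constant, :] = np.nan
    p_df.loc[:, constant] = np.nan
    np.fill_diagonal(rho_df.values, 1.0)
    np.fill_diagonal(p_df.values, 0.0)
    return CorrelationResult(rho=rho_df, p=p_df, n_samples=n, excluded=constant)


def permutation_pvalue(x, y, max_n: int = 10) -> float:
    """Exact two-sided permutation p-value for Spearman rho.

    Enumerates all n! orderings of y (n <= ``max_n``); p is the fraction of
    permutations whose |rho| is at least the observed |rho| (within 1e-12).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > max_n:
        raise ValueError(f"exact permutation limited to n <= {max_n}, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(_rank_corr(rx, ry[list(perm)]))
        count += r >= obs - 1e-12
        total += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float((rx @ ry) / denom)


def select_edges(
    corr: CorrelationResult,
    r_min: float = 0.6,
    p_max: float = 0.01,
    mode: str = "absolute",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Select network edges at the correlation thresholds.

    ``mode='absolute'`` keeps |rho| > r_min (both signs — constructed networks
    contain negative edges, so this is the default); ``mode='positive'`` is a
    strict-positive sensitivity variant. ``bh_correct`` optionally applies
    Benjamini-Hochberg to the upper-triangle p-values before thresholding
    (off by default: raw p-values match the stated procedure).

    Returns a tidy edge list (source, target, rho, p, sign, weight=|rho|)
    sorted by (source, target).
    """
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = corr.taxon_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    rho = corr.rho.to_numpy()[iu, ju]
    p = corr.p.to_numpy()[iu, ju]
    if bh_correct:
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        adj[finite] = stats.false_discovery_control(p[finite], method="bh")
        p = adj
    with np.errstate(invalid="ignore"):
        strength = np.abs(rho) if mode == "absolute" else rho
        kept = np.isfinite(rho) & np.isfinite(p) & (strength > r_min) & (p < p_max)
    edges = pd.DataFrame(
        {
            "source": np.asarray(ids, dtype=object)[iu[kept]],
            "target": np.asarray(ids, dtype=object)[ju[kept]],
            "rho": rho[kept],
            "p": p[kept],
        }
    )
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    edges["weight"] = edges["rho"].abs()
    return edges.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)


def write_correlation_tsv(corr: CorrelationResult, rho_path, edge_df: pd.DataFrame, edge_path,
                          header_comment: str = "") -> None:
    """Write the full rho matrix and the kept-edge list as TSV."""
    with open(rho_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        corr.rho.rename_axis("taxon_id").to_csv(fh, sep="\t")
    with open(edge_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        edge_df.to_csv(fh, sep="\t", index=False)
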