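"""Correlating network topology with reactor performance across groups.

Each analysis group contributes one topology-panel row and one set of derived
reactor parameters; every (network property, reactor parameter) pair gets a
Pearson correlation over the groups with a two-sided t-test p-value. With the
study-scale five groups these p-values are fragile — the functions warn on
n < 6 but do not block. A companion check correlates group sample counts and
network order against every property to flag sample-size confounding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["linkage_matrix", "size_confound_check", "to_matrix_form"]

#: TopologyPanel columns that are group metadata, not correlatable properties
_PANEL_META = {"group", "random_clustering_sd", "n_modules"}


def _pairwise(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def linkage_matrix(
    panels: pd.DataFrame,
    params: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Correlate every network property with every reactor parameter.

    ``panels``: one TopologyPanel row per group (index = group). ``params``:
    one row of derived reactor metrics per group (index = group). Rows are
    aligned on group; needs >= 3 common groups. Pearson by default (Spearman
    optional for a rank-based sensitivity check). Returns a tidy grid with
    columns (property, parameter, r, p, significant); a constant property or
    parameter yields NaN r/p and significant=False.
    """
    common = panels.index.intersection(params.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 groups with panel and parameters, got {len(common)}")
    if len(common) < 6:
        warnings.warn(
            f"only {len(common)} groups: correlation p-values over so few points are fragile"
        )
    pan = panels.loc[common].drop(columns=[c for c in _PANEL_META if c in panels.columns])
    par = params.loc[common]
    rows = []
    for prop in pan.columns:
        x = pan[prop].to_numpy(dtype=float)
        for param in par.columns:
            y = par[param].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                r, p = _pairwise(x[ok], y[ok], method)
            else:
                r, p = np.nan, np.nan
            rows.append({"property": prop, "parameter": param, "r": r, "p": p})
    grid = pd.DataFrame(rows)
    p = grid["p"].to_numpy()
    if bh_correct:
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        adj[finite] = stats.false_discovery_control(p[finite], method="bh")
        grid["p_adjusted"] = adj
        p = adj
    grid["significant"] = np.isfinite(p) & (p < alpha)
    return grid


def size_confound_check(
    panels: pd.DataFrame,
    sample_counts: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate sample count and network order against every panel property.

    Any significant correlation is flagged as a potential sample-size
    confound on cross-group comparisons (network size itself is expected to
    track sample count; other properties should not).
    """
    common = panels.index.intersection(sample_counts.index)
    pan = panels.loc[common]
    confounders = pd.DataFrame(
        {"sample_count": sample_counts.loc[common].astype(float), "order": pan["order"].astype(float)}
    )
    props = pan.drop(columns=[c for c in _PANEL_META if c in pan.columns])
    rows = []
    for conf in confounders.columns:
        x = confounders[conf].to_numpy()
        for prop in props.columns:
            if prop == conf:
                continue
            y = props[prop].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            r, p = _pairwise(x[ok], y[ok], "pearson") if ok.sum() >= 3 else (np.nan, np.nan)
            flag = bool(np.isfinite(p) and p < alpha)
            rows.append({"confounder": conf, "property": prop, "r": r, "p": p,
                         "confound_flag": flag})
    out = pd.DataFrame(rows)
    for row in out.itertuples(index=False):
        if row.confound_flag:
            warnings.warn(
                f"possible sample-size confound: {row.property} vs {row.confounder} "
                f"(r={row.r:.2f}, p={row.p:.3f})"
            )
    return out


def to_matrix_form(grid: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the tidy grid to a property x parameter matrix."""
    return grid.pivot(index="property", columns="parameter", values=value)


def write_linkage_tsv(grid: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        grid.to_csv(fh, sep="\t", index=False)
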