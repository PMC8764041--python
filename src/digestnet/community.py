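"""Abundance-table preparation and community ecology summaries.

Holds the genus-level abundance table container, relative-abundance
normalization, the inclusion filter applied before network construction
(relative abundance > 0.1% in at least three samples of the analysis group),
alpha diversity (Shannon, richness, Pielou evenness), Bray-Curtis distances,
principal coordinates analysis, and steady-state subsampling of
over-represented groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix

__all__ = [
    "AbundanceTable",
    "GroupAssignment",
    "read_abundance_tsv",
    "read_biom_json",
    "to_relative",
    "network_filter",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "subsample_steady_state",
    "propose_groups",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa abundance matrix.

    ``data`` is indexed by sample id with unique taxon-id columns; lineage
    strings (k__/p__/.../g__ convention) may annotate taxa. ``relative``
    records whether rows are proportions summing to 1.
    """

    data: pd.DataFrame
    relative: bool = False
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.relative:
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def to_tsv(self, path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.rename_axis("sample_id").to_csv(fh, sep="\t")


@dataclass(frozen=True)
class GroupAssignment:
    """Map sample id -> analysis-group label.

    ``provenance`` records whether grouping came from user config or from the
    clustering helper (which only ever proposes; see :func:`propose_groups`).
    """

    groups: dict[str, str]
    provenance: str = "config"

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @classmethod
    def from_tsv(cls, path) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError("group TSV needs columns sample_id and group")
        if df["sample_id"].duplicated().any():
            raise ValueError("a sample may belong to exactly one group")
        return cls(dict(zip(df["sample_id"], df["group"])))


def read_abundance_tsv(path, orientation: str = "samples_by_taxa") -> AbundanceTable:
    """Read an abundance TSV; ``orientation`` names what the rows are."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValueError(f"unknown orientation {orientation!r}")
    arr = df.to_numpy(dtype=float)
    rel = bool(np.allclose(arr.sum(axis=1), 1.0, atol=1e-8))
    return AbundanceTable(df.astype(float), relative=rel)


def read_biom_json(path) -> AbundanceTable:
    """Read a BIOM v1 (plain JSON) table; rows are observations (taxa)."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    lineage = {}
    for r in doc["rows"]:
        tax = (r.get("metadata") or {}).get("taxonomy")
        if tax:
            lineage[r["id"]] = tax if isinstance(tax, str) else "; ".join(tax)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return AbundanceTable(df, relative=False, lineage=lineage)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample to proportions; idempotent on relative input."""
    if table.relative:
        return table
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples cannot be normalized: {list(zero.index)}")
    return replace(table, data=table.data.div(totals, axis=0), relative=True)


def network_filter(
    table: AbundanceTable,
    min_rel_abund: float = 0.001,
    min_occurrence: int = 3,
    min_samples: int = 4,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Inclusion filter applied per analysis group before network construction.

    Keeps taxa whose relative abundance exceeds ``min_rel_abund`` in at least
    ``min_occurrence`` samples ("more than two samples" read strictly as >= 3).
    Returns the filtered table and a report of dropped taxa with the count of
    qualifying samples each had.
    """
    if len(table.data) < min_samples:
        raise ValueError(
            f"group has {len(table.data)} samples; need >= {min_samples} "
            "for meaningful correlations"
        )
    rel = to_relative(table)
    hits = (rel.data > min_rel_abund).sum(axis=0)
    keep = hits[hits >= min_occurrence].index
    dropped = hits[hits < min_occurrence]
    report = pd.DataFrame(
        {"taxon_id": dropped.index, "n_samples_above_threshold": dropped.to_numpy()}
    ).reset_index(drop=True)
    filtered = AbundanceTable(
        rel.data[keep],
        relative=False,  # rows no longer sum to 1 after dropping taxa
        lineage={t: l for t, l in rel.lineage.items() if t in set(keep)},
    )
    return filtered, report


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon H (natural log), genus richness and Pielou evenness.

    H = -sum p ln p over nonzero proportions; evenness = H / ln(richness),
    defined as 0 when richness is 1.
    """
    rel = to_relative(table)
    p = rel.data.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (p > 0).sum(axis=1)
    evenness = np.where(richness > 1, shannon / np.log(np.maximum(richness, 2)), 0.0)
    return pd.DataFrame(
        {"shannon": shannon, "richness": richness, "evenness": evenness},
        index=rel.data.index,
    )


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    rel = to_relative(table) if not table.relative else table
    d = squareform(pdist(rel.data.to_numpy(), metric="braycurtis"))
    ids = rel.data.index
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray            # all eigenvalues, negatives included
    proportion_explained: np.ndarray   # for the retained (non-negative) axes
    n_negative: int


def pcoa(dist: pd.DataFrame) -> PCoAResult:
    """Classical metric scaling (PCoA) of a square distance matrix.

    Axes are ordered by eigenvalue. Negative eigenvalues (non-Euclidean
    distances such as Bray-Curtis produce them) are reported in
    ``eigenvalues`` but their axes are dropped; no Cailliez correction.
    """
    m = np.asarray(dist, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    ids = [str(i) for i in dist.index] if isinstance(dist, pd.DataFrame) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(DistanceMatrix(m, ids=ids), method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12  # eigh returns axes sorted by eigenvalue, positives first
    coords = res.samples.iloc[:, : int(pos.sum())]
    total = eig[pos].sum()
    prop = eig[pos] / total if total > 0 else eig[pos]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=prop,
        n_negative=int((eig < -1e-12).sum()),
    )


def subsample_steady_state(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    max_per_group: int = 8,
    steady_col: str = "steady_state",
    stage_col: str = "stage",
    group_col: str = "group",
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Cap each group's sample count, preferring steady-state, late-stage samples.

    Deterministic: within a group, samples are ranked by (steady-state flag
    desc, stage desc, sample id asc) and the top ``max_per_group`` retained.
    Returns the reduced table and a log of dropped samples. Mirrors reducing an
    over-sampled condition to avoid biasing network comparisons toward large n.
    """
    meta = metadata.loc[list(table.data.index)].copy()
    meta["_steady"] = meta.get(steady_col, pd.Series(True, index=meta.index)).astype(bool)
    meta["_stage"] = meta.get(stage_col, pd.Series(0, index=meta.index))
    keep: list[str] = []
    dropped_rows = []
    for group, sub in meta.groupby(group_col, sort=True):
        # stable sort after lexical index sort => sample id breaks ties
        ranked = sub.sort_index(kind="mergesort").sort_values(
            by=["_steady", "_stage"], ascending=[False, False], kind="mergesort"
        )
        kept = list(ranked.index[:max_per_group])
        keep.extend(kept)
        for s in ranked.index[max_per_group:]:
            dropped_rows.append({"sample_id": s, "group": group, "reason": "over group cap"})
    keep = [s for s in table.data.index if s in set(keep)]
    return table.subset_samples(keep), pd.DataFrame(dropped_rows, columns=["sample_id", "group", "reason"])


def propose_groups(table: AbundanceTable, k: int) -> GroupAssignment:
    """Propose k sample groups by average-linkage clustering on Bray-Curtis.

    A helper only: community grouping in practice combines ordination patterns
    with dominant-genus knowledge, so the result is marked
    ``provenance='clustering-assisted'`` and is never applied silently.
    """
    d = bray_curtis(table)
    z = _scipy_linkage(squareform(d.to_numpy(), checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    groups = {s: f"cluster_{c}" for s, c in zip(d.index, labels)}
    return GroupAssignment(groups, provenance="clustering-assisted")
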