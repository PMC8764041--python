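"""Pipeline driver: configuration, per-group network stages, manifest.

Ties the stages together — filter -> correlate -> build -> topology ->
keystone -> linkage — over every analysis group, writing plain-text artifacts
(TSV tables, GraphML graphs) plus a JSON manifest of file checksums so that
identical config + seed reproduces byte-identical outputs. The thin command
line in :mod:`digestnet.cli` wraps these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (AbundanceTable, GroupAssignment, network_filter,
                        read_abundance_tsv, subsample_steady_state, to_relative)
from .correlation import select_edges, spearman_matrix, write_correlation_tsv
from .keystone import classify_roles, rank_hubs, write_node_tsv, zi_pi
from .linkage import linkage_matrix, size_confound_check, write_linkage_tsv
from .network import (build_network, modularity_partition, topology_panel,
                      write_edgelist_tsv, write_graphml)
from .synthetic import SimConfig, simulate_community, simulate_reactor_params, write_truth_json

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("digestnet")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; round-trips through YAML unchanged."""

    out_dir: str = "digestnet_out"
    # inputs (ignored when simulate=True)
    abundance_tsv: str | None = None
    groups_tsv: str | None = None
    params_tsv: str | None = None
    simulate: bool = False
    # thresholds, at their conventional defaults
    min_rel_abund: float = 0.001
    min_occurrence: int = 3
    r_min: float = 0.6
    p_max: float = 0.01
    edge_mode: str = "absolute"
    z_threshold: float = 2.5
    p_threshold: float = 0.62
    alpha: float = 0.05
    max_per_group: int = 8
    min_group_samples: int = 4
    community_method: str = "greedy"
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_rel_abund < 1 and 0 < self.r_min < 1 and 0 < self.p_max <= 1
                and 0 < self.alpha <= 1 and 0 <= self.p_threshold < 1):
            raise ValueError("a threshold is outside its valid range")
        if self.min_occurrence < 1 or self.n_reps < 1 or self.min_group_samples < 2:
            raise ValueError("counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are: exclude it so the
        # same analysis in two directories stamps (and checksums) identically
        doc = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class MissingInputError(FileNotFoundError):
    pass


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        sim = SimConfig(seed=cfg.seed)
        table, truth = simulate_community(sim)
        params = simulate_reactor_params(sim, truth)
        groups = GroupAssignment(dict(truth.metadata["group"]))
        return table, truth.metadata, groups, params, truth
    for name in ("abundance_tsv", "groups_tsv"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise MissingInputError(f"missing required input {name}: {p!r}")
    table = read_abundance_tsv(cfg.abundance_tsv)
    groups = GroupAssignment.from_tsv(cfg.groups_tsv)
    meta = pd.DataFrame({"group": pd.Series(groups.groups)})
    params = None
    if cfg.params_tsv:
        if not Path(cfg.params_tsv).exists():
            raise MissingInputError(f"missing input params_tsv: {cfg.params_tsv!r}")
        params = pd.read_csv(cfg.params_tsv, sep="\t", comment="#", index_col=0)
    return table, meta, groups, params, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written to disk).

    The manifest records config echo + hash, seed, package versions, per-stage
    timings, warnings, and a checksum per written file. Identical config and
    seed yield identical checksums.
    """
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"stage=%s config={cfg.config_hash()} seed={cfg.seed}"
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"digestnet": __version__},
        "warnings": [],
        "timings_s": {},
        "files": {},
        "groups": {},
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        table, metadata, groups, params, truth = _load_inputs(cfg)
        if truth is not None:
            table.to_tsv(out / "abundance_counts.tsv", stamp % "simulate")
            metadata.reset_index().to_csv(out / "metadata.tsv", sep="\t", index=False)
            params.reset_index().to_csv(out / "reactor_params.tsv", sep="\t", index=False)
            write_truth_json(truth, out / "sim_truth.json")
        manifest["timings_s"]["load"] = round(time.perf_counter() - t0, 3)

        rel = to_relative(table)
        if "group" in metadata.columns:
            rel, dropped = subsample_steady_state(rel, metadata, max_per_group=cfg.max_per_group)
            if len(dropped):
                dropped.to_csv(out / "subsample_dropped.tsv", sep="\t", index=False)

        panels = []
        sample_counts = {}
        for label in groups.labels():
            t_g = time.perf_counter()
            samples = [s for s in groups.samples_in(label) if s in rel.data.index]
            if len(samples) < cfg.min_group_samples:
                log.warning("group %s skipped: only %d samples", label, len(samples))
                manifest["groups"][label] = {"skipped": f"{len(samples)} samples"}
                continue
            sub = rel.subset_samples(samples)
            filtered, drop_report = network_filter(
                sub, cfg.min_rel_abund, cfg.min_occurrence, cfg.min_group_samples)
            corr = spearman_matrix(filtered)
            edges = select_edges(corr, cfg.r_min, cfg.p_max, cfg.edge_mode)
            node_meta = pd.DataFrame({
                "abundance": to_relative(sub).data[filtered.taxon_ids].mean(axis=0)})
            net = build_network(edges, node_meta, group=label)
            ginfo = {
                "n_samples": len(samples),
                "n_taxa_filtered": len(filtered.taxon_ids),
                "n_taxa_dropped": len(drop_report),
                "order": net.order,
                "size": net.size,
                "isolated": len(net.isolated_dropped or []),
            }
            if net.size == 0:
                ginfo["skipped"] = "no edges passed thresholds"
                manifest["groups"][label] = ginfo
                continue
            panel = topology_panel(net, n_reps=cfg.n_reps, seed=cfg.seed,
                                   method=cfg.community_method)
            panels.append(panel.as_series())
            nodes = classify_roles(zi_pi(net), cfg.z_threshold, cfg.p_threshold)
            write_correlation_tsv(corr, out / f"{label}_rho.tsv", edges,
                                  out / f"{label}_edges.tsv", stamp % "correlate")
            write_graphml(net, out / f"{label}_network.graphml")
            write_edgelist_tsv(net, out / f"{label}_network_edges.tsv", stamp % "network")
            write_node_tsv(nodes, out / f"{label}_nodes.tsv", group=label,
                           header_comment=stamp % "keystone")
            by_deg, by_btw, overlap = rank_hubs(nodes)
            ginfo["hub_overlap"] = overlap
            ginfo["role_counts"] = {str(k): int(v) for k, v in
                                    nodes["role"].value_counts().items()}
            manifest["groups"][label] = ginfo
            sample_counts[label] = len(samples)
            manifest["timings_s"][f"group:{label}"] = round(time.perf_counter() - t_g, 3)

        if panels:
            panel_df = pd.DataFrame(panels).set_index("group")
            with open(out / "topology_panel.tsv", "w") as fh:
                fh.write(f"# {stamp % 'topology'}\n")
                panel_df.to_csv(fh, sep="\t")
            if params is not None and len(panel_df) >= 3:
                t_l = time.perf_counter()
                grid = linkage_matrix(panel_df, params.loc[:, params.dtypes != object],
                                      alpha=cfg.alpha)
                write_linkage_tsv(grid, out / "linkage.tsv", stamp % "linkage")
                confound = size_confound_check(panel_df, pd.Series(sample_counts),
                                               alpha=cfg.alpha)
                write_linkage_tsv(confound, out / "size_confound.tsv", stamp % "linkage")
                manifest["timings_s"]["linkage"] = round(time.perf_counter() - t_l, 3)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    manifest["timings_s"]["total"] = round(time.perf_counter() - t0, 3)
    for stage, secs in manifest["timings_s"].items():
        log.info("stage %s: %.3f s", stage, secs)
    # timings stay out of the file so reruns are byte-identical
    blob = {k: v for k, v in manifest.items() if k != "timings_s"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(blob, fh, indent=1, sort_keys=True, default=str)
    manifest["checksum_of_files"] = hashlib.sha256(
        json.dumps(blob["files"], sort_keys=True).encode()).hexdigest()
    return manifest
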