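"""Synthetic communities and reactor chemistry with known ground truth.

Emulates the shape of a multi-reactor anaerobic-digestion survey — 52 samples
from 12 reactors falling into 5 analysis groups, genus-level bacterial plus
archaeal abundances — with *planted* structure so every downstream stage
(filtering, correlation thresholding, module detection, Zi-Pi roles, the
topology-performance linkage) can be checked against truth:

* taxa within a planted module share a latent factor per sample
  (log-abundance = base + loading * factor + Gaussian noise), giving
  block-structured rank correlations; a configurable fraction of loadings is
  negative, producing negative edges;
* taxa outside modules are conditionally independent;
* counts arise by multinomial resampling at a sequencing depth followed by
  zero inflation (dropout);
* per-group reactor parameters co-vary linearly with the group's module
  strength, so linkage correlations have known sign.

This is a latent-factor compositional test harness, not a mechanistic model
of digester ecology; see the methods note for what it does and does not
emulate. All randomness flows from the single ``seed`` in :class:`SimConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .reactor_metrics import ChemMeasurement, derive_metrics, free_ammonia

__all__ = ["SimConfig", "SimTruth", "simulate_community", "simulate_reactor_params",
           "write_truth_json"]

_DEFAULT_GROUPS = ("ambient", "meso_low_solid", "mesophilic", "meso_codigestion",
                   "thermophilic")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs; defaults mirror the emulated 52-sample survey."""

    n_groups: int = 5
    samples_per_group: tuple = (20, 6, 13, 5, 8)
    reactors_per_group: tuple = (5, 2, 2, 1, 2)
    group_names: tuple = _DEFAULT_GROUPS
    n_bacteria: int = 150
    n_archaea: int = 15
    n_modules: int = 4
    module_taxa_per_group: int = 48
    module_strength: tuple = (1.0, 1.25, 1.5, 1.75, 2.0)
    negative_loading_frac: float = 0.10
    noise_sd: float = 0.20
    background_sd: float = 1.00
    zero_inflation_prob: float = 0.02
    sequencing_depth: int = 50_000
    param_dependence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.samples_per_group) == len(self.reactors_per_group)
                == len(self.group_names) == len(self.module_strength) == self.n_groups):
            raise ValueError("per-group tuples must have length n_groups")
        if min(self.samples_per_group) < 1 or min(self.reactors_per_group) < 1:
            raise ValueError("sample and reactor counts must be positive")
        if not (0 <= self.zero_inflation_prob <= 1 and 0 <= self.negative_loading_frac <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sequencing_depth < 1 or self.n_modules < 1:
            raise ValueError("depth and module count must be positive")
        if self.module_taxa_per_group > self.n_bacteria + self.n_archaea:
            raise ValueError("more module taxa than taxa")

    @property
    def n_taxa(self) -> int:
        return self.n_bacteria + self.n_archaea


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset.

    ``modules[group]`` maps module-carrying taxon ids to planted module
    labels; ``sign[group]`` is the symmetric true-association sign matrix over
    those taxa (+1 shared factor & same loading sign, -1 opposite sign, 0
    different modules); ``metadata`` assigns every sample its group, reactor,
    stage and steady-state flag; ``strengths`` records each group's latent
    module strength; ``group_params`` is filled by
    :func:`simulate_reactor_params`.
    """

    modules: dict
    sign: dict
    metadata: pd.DataFrame
    strengths: dict
    group_params: pd.DataFrame | None = None


def _orthogonal_factors(rng: np.random.Generator, n_s: int, k: int) -> np.ndarray:
    """Per-sample module factors, orthogonalized across the group's samples.

    With few samples, independently drawn factors can be strongly correlated
    by chance, which would couple modules that are *planted* as independent
    and falsify the ground truth. Centering and QR-orthogonalizing the draw
    (then rescaling columns to unit sd) makes the realized factors exactly
    uncorrelated, so cross-module taxon correlations come only from counting
    noise. Requires n_s > k; falls back to raw draws otherwise.
    """
    raw = rng.normal(0.0, 1.0, size=(n_s, k))
    if n_s <= k:
        return raw
    centered = raw - raw.mean(axis=0)
    q, r = np.linalg.qr(centered)
    q = q[:, :k] * np.sign(np.diag(r))  # sign-fix for determinism
    return q * np.sqrt(n_s - 1)


def _taxon_ids(cfg: SimConfig) -> list[str]:
    bact = [f"g__Bact{i:03d}" for i in range(cfg.n_bacteria)]
    arch = [f"g__Arch{i:02d}" for i in range(cfg.n_archaea)]
    return bact + arch


def simulate_community(cfg: SimConfig) -> tuple[AbundanceTable, SimTruth]:
    """Simulate the genus count table and its planted truth.

    Returns the counts table (samples x taxa) and a :class:`SimTruth`; sample
    metadata (group, reactor, stage, steady_state) lives on the truth object.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = _taxon_ids(cfg)
    n_taxa = cfg.n_taxa

    # per-taxon baseline log-abundance, shared across groups
    base = rng.normal(0.0, 1.2, size=n_taxa)
    # archaea: fewer genera, a handful dominant (acetoclastic/hydrogenotrophic
    # methanogens dominate digester archaeal communities)
    arch_slice = slice(cfg.n_bacteria, n_taxa)
    base[arch_slice] -= 1.0

    modules: dict = {}
    signs: dict = {}
    sample_rows = []
    count_blocks = []
    sample_ids = []

    for gi, gname in enumerate(cfg.group_names):
        n_s = cfg.samples_per_group[gi]
        n_r = cfg.reactors_per_group[gi]
        strength = cfg.module_strength[gi]

        # group-specific dominant genera (5 bacterial + 2 archaeal)
        g_base = base.copy()
        dom_b = rng.choice(cfg.n_bacteria, size=5, replace=False)
        dom_a = cfg.n_bacteria + rng.choice(cfg.n_archaea, size=2, replace=False)
        g_base[dom_b] += 3.0
        g_base[dom_a] += 3.5

        # plant modules on a subset of taxa. Their baseline is set low enough
        # that module taxa stay a minor share of total reads (otherwise one
        # module's factor swing moves the compositional denominator and
        # couples all modules) yet high enough to clear the 0.1% inclusion
        # filter in the samples where their factor is up.
        mod_taxa = rng.choice(n_taxa, size=cfg.module_taxa_per_group, replace=False)
        g_base[mod_taxa] = rng.normal(-0.3, 0.3, size=mod_taxa.size)
        assignment = np.repeat(np.arange(cfg.n_modules),
                               int(np.ceil(mod_taxa.size / cfg.n_modules)))[: mod_taxa.size]
        loading_sign = np.where(rng.random(mod_taxa.size) < cfg.negative_loading_frac, -1.0, 1.0)

        mod_names = [taxa[t] for t in mod_taxa]
        modules[gname] = {taxa[t]: int(m) for t, m in zip(mod_taxa, assignment)}
        same = assignment[:, None] == assignment[None, :]
        sgn = np.where(same, np.sign(loading_sign[:, None] * loading_sign[None, :]), 0).astype(int)
        np.fill_diagonal(sgn, 0)
        signs[gname] = pd.DataFrame(sgn, index=mod_names, columns=mod_names)

        factors = _orthogonal_factors(rng, n_s, cfg.n_modules)
        # background taxa vary independently (sd background_sd); module taxa
        # get the shared factor plus a small residual (sd noise_sd)
        log_a = np.tile(g_base, (n_s, 1)) + rng.normal(0.0, cfg.background_sd, size=(n_s, n_taxa))
        # dominant genera are persistently dominant (small noise): otherwise
        # their swings move the compositional denominator for every taxon and
        # induce correlations between taxa planted as independent
        dom = np.concatenate([dom_b, dom_a])
        log_a[:, dom] = g_base[dom] + rng.normal(0.0, cfg.noise_sd, size=(n_s, dom.size))
        log_a[:, mod_taxa] = (
            g_base[mod_taxa]
            + strength * loading_sign * factors[:, assignment]
            + rng.normal(0.0, cfg.noise_sd, size=(n_s, mod_taxa.size))
        )

        p = np.exp(log_a)
        p /= p.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(cfg.sequencing_depth, p[j]) for j in range(n_s)])
        drop = rng.random(counts.shape) < cfg.zero_inflation_prob
        counts = np.where(drop, 0, counts)
        count_blocks.append(counts)

        reactors = [f"{gname}_R{r + 1}" for r in range(n_r)]
        for j in range(n_s):
            sid = f"{gname}_S{j + 1:02d}"
            sample_ids.append(sid)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "group": gname,
                    "reactor_id": reactors[j % n_r],
                    "stage": j // n_r + 1,
                    # later stages have settled into steady operation
                    "steady_state": bool(j >= n_s // 3),
                }
            )

    table = AbundanceTable(
        pd.DataFrame(np.vstack(count_blocks), index=sample_ids, columns=taxa).astype(float),
        relative=False,
    )
    metadata = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = SimTruth(
        modules=modules,
        sign=signs,
        metadata=metadata,
        strengths=dict(zip(cfg.group_names, cfg.module_strength)),
    )
    return table, truth


# plausible digester operating ranges used to anchor simulated chemistry
_GROUP_TEMP = {0: 22.0, 1: 35.0, 2: 35.0, 3: 35.0, 4: 52.0}


def simulate_reactor_params(cfg: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Per-group reactor chemistry and derived metrics tied to module strength.

    Group-level hydrolysis efficiency, particulate-COD ratio and hydrolysis
    rate constant K_H increase linearly with the group's module strength,
    scaled by ``cfg.param_dependence`` (0 decouples them entirely), so the
    expected sign of every topology-parameter correlation is known. Raw
    chemistry is constructed to be internally consistent and the derived
    metrics are computed through the reactor-metrics code path, not assigned.
    Values stay within ordinary blackwater-digester ranges (influent tCOD
    1-33 g/L, TAN up to ~1.4 g-N/L, pH 7-8.2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9_117]))
    strengths = np.array([truth.strengths[g] for g in cfg.group_names], dtype=float)
    span = strengths.max() - strengths.min()
    s = (strengths - strengths.min()) / span if span > 0 else np.zeros_like(strengths)
    dep = cfg.param_dependence

    rows = []
    for gi, gname in enumerate(cfg.group_names):
        tCOD_inf = float(rng.uniform(1.0, 33.0))
        pcod = float(np.clip(0.35 + 0.45 * dep * s[gi] + rng.normal(0, 0.03), 0.05, 0.95))
        sCOD_inf = tCOD_inf * (1.0 - pcod)
        hyd = float(np.clip(0.16 + 0.62 * dep * s[gi] + rng.normal(0, 0.03), 0.05, 0.95))
        meth = float(np.clip(hyd * rng.uniform(0.88, 0.98), 0.02, hyd))
        d = hyd - meth
        # effluent tCOD consistent with the targeted efficiencies
        tCOD_eff = max(0.5 * tCOD_inf, 1.05 * (sCOD_inf + d * tCOD_inf) / (1.0 + d))
        tCOD_eff = min(tCOD_eff, 0.99 * tCOD_inf)
        delta = tCOD_inf - tCOD_eff
        COD_CH4 = meth * delta
        sCOD_eff = sCOD_inf + d * delta
        TAN = float(rng.uniform(90, 1400))
        pH = float(rng.uniform(7.0, 8.2))
        temp = _GROUP_TEMP[gi % 5]
        K_H = float(np.clip(0.05 + 0.45 * dep * s[gi] + rng.normal(0, 0.02), 0.01, 1.0))
        SMA_total = float(rng.uniform(0.05, 0.40))
        SMA_obs = float(SMA_total * rng.uniform(0.3, 0.9))

        m = ChemMeasurement(
            tCOD_inf=tCOD_inf, tCOD_eff=tCOD_eff, sCOD_inf=sCOD_inf, sCOD_eff=sCOD_eff,
            COD_CH4=COD_CH4, TAN=TAN, pH=pH, temperature_C=temp,
            SMA_total=SMA_total, SMA_obs=SMA_obs, reactor_id=f"{gname}_R1", stage="final",
        )
        dm = derive_metrics(m, K_H=K_H)
        rows.append(
            {
                "group": gname,
                "tCOD_inf": tCOD_inf,
                "sCOD_inf": sCOD_inf,
                "pCOD_ratio": dm.pCOD_ratio,
                "hydrolysis_eff": dm.hydrolysis_eff,
                "methanogenesis_eff": dm.methanogenesis_eff,
                "D_efficiency": dm.D_efficiency,
                "K_H": K_H,
                "SMA_total": SMA_total,
                "SMA_obs": SMA_obs,
                "D_rate": dm.D_rate,
                "TAN": TAN,
                "pH": pH,
                "temperature_C": temp,
                "FA": free_ammonia(TAN, pH, temp),
            }
        )
    params = pd.DataFrame(rows).set_index("group")
    truth.group_params = params
    return params


def write_truth_json(truth: SimTruth, path) -> None:
    doc = {
        "modules": truth.modules,
        "strengths": truth.strengths,
        "sign": {g: {"taxa": list(df.index), "matrix": df.to_numpy().tolist()}
                 for g, df in truth.sign.items()},
        "metadata": truth.metadata.reset_index().to_dict(orient="records"),
        "group_params": (truth.group_params.reset_index().to_dict(orient="records")
                         if truth.group_params is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
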