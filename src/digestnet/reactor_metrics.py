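"""Derived anaerobic-digestion reactor performance parameters.

Measured chemistry (COD fractions, methane-as-COD, ammonia, pH, temperature,
specific methanogenic activity) is turned into the derived process metrics
used throughout the analysis:

* free ammonia (FA) — the un-ionized, methanogenesis-inhibiting NH3 fraction
  of total ammonia nitrogen, from the ammonia dissociation equilibrium;
* hydrolysis and methanogenesis efficiency — fractions of degraded
  particulate COD that were solubilized and converted to methane;
* first-order hydrolysis rate constant ``K_H`` from a batch time series;
* the relative differential efficiency ``D_efficiency`` and relative
  differential rate ``D_rate``, dimensionless hydrolysis-vs-methanogenesis
  imbalance measures.

Efficiencies are returned as fractions; formatting to percent is left to the
presentation layer. Metrics computed from stage-mean inputs differ from means
of per-sample metrics (Jensen gap); both modes are supported via
:func:`derive_metrics` over per-sample rows or over a pre-averaged row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemMeasurement",
    "BatchSeries",
    "DerivedMetrics",
    "free_ammonia",
    "hydrolysis_efficiency",
    "methanogenesis_efficiency",
    "hydrolysis_rate_constant",
    "d_efficiency",
    "d_rate",
    "pcod_ratio",
    "derive_metrics",
    "read_chemistry_tsv",
    "write_metrics_tsv",
]


class UndefinedMetricError(ValueError):
    """A derived metric's denominator is zero or its log argument non-positive."""


@dataclass(frozen=True)
class ChemMeasurement:
    """One reactor-stage chemistry record.

    Concentrations are g/L except TAN (mg-N/L); SMA is gCOD/gVSS/d.
    """

    tCOD_inf: float
    tCOD_eff: float
    sCOD_inf: float
    sCOD_eff: float
    COD_CH4: float
    TAN: float
    pH: float
    temperature_C: float
    SMA_total: float = float("nan")
    SMA_obs: float = float("nan")
    reactor_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        conc = {
            "tCOD_inf": self.tCOD_inf,
            "tCOD_eff": self.tCOD_eff,
            "sCOD_inf": self.sCOD_inf,
            "sCOD_eff": self.sCOD_eff,
            "COD_CH4": self.COD_CH4,
            "TAN": self.TAN,
        }
        for name, v in conc.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH must lie in (0, 14), got {self.pH!r}")
        if self.sCOD_inf > self.tCOD_inf + 1e-12:
            raise ValueError("sCOD_inf exceeds tCOD_inf")
        if self.sCOD_eff > self.tCOD_eff + 1e-12:
            raise ValueError("sCOD_eff exceeds tCOD_eff")


@dataclass(frozen=True)
class BatchSeries:
    """Batch degradation time series: soluble COD and cumulative CH4-as-COD."""

    times: Sequence[float]
    sCOD_t: Sequence[float]
    COD_CH4_t: Sequence[float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sCOD_t, dtype=float)
        m = np.asarray(self.COD_CH4_t, dtype=float)
        if t.size < 2:
            raise ValueError("a batch series needs at least 2 time points")
        if not (t.size == s.size == m.size):
            raise ValueError("times, sCOD_t and COD_CH4_t must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(m) < -1e-12):
            raise ValueError("cumulative COD_CH4_t must be non-decreasing")


@dataclass(frozen=True)
class DerivedMetrics:
    """Derived metrics for one reactor stage. Efficiencies are fractions."""

    FA: float
    hydrolysis_eff: float
    methanogenesis_eff: float
    D_efficiency: float
    pCOD_ratio: float
    K_H: float = float("nan")
    D_rate: float = float("nan")
    reactor_id: str = ""
    stage: str = ""


def free_ammonia(TAN, pH, temperature_C):
    """Free (un-ionized) ammonia, mg-N/L, from TAN, pH and temperature.

    FA = 1.214 * TAN * (1 + 10^(-pH) / 10^(-(0.09018 + 2729.92/T_K)))^-1
    with T_K the absolute temperature. The equilibrium constant term makes FA
    strictly increasing in both pH and temperature; FA <= 1.214 * TAN always.

    Accepts scalars or arrays (broadcast); temperature is given in Celsius and
    converted internally (T_K = temperature_C + 273.15).
    """
    TAN = np.asarray(TAN, dtype=float)
    pH = np.asarray(pH, dtype=float)
    temperature_C = np.asarray(temperature_C, dtype=float)
    if not (np.all(np.isfinite(TAN)) and np.all(np.isfinite(pH)) and np.all(np.isfinite(temperature_C))):
        raise ValueError("free_ammonia requires finite TAN, pH and temperature")
    if np.any(TAN < 0):
        raise ValueError("TAN must be >= 0")
    if np.any((pH <= 0) | (pH >= 14)):
        raise ValueError("pH must lie in (0, 14)")
    T_K = temperature_C + 273.15
    pKa = 0.09018 + 2729.92 / T_K
    fa = 1.214 * TAN / (1.0 + 10.0 ** (-pH) / 10.0 ** (-pKa))
    return fa if fa.ndim else float(fa)


def _degraded_tcod(m: ChemMeasurement) -> float:
    d = m.tCOD_inf - m.tCOD_eff
    if d <= 0:
        raise UndefinedMetricError(
            f"tCOD_inf ({m.tCOD_inf}) must exceed tCOD_eff ({m.tCOD_eff}): "
            "no net COD degradation, efficiency undefined"
        )
    return d


def hydrolysis_efficiency(m: ChemMeasurement) -> float:
    """(sCOD_eff - sCOD_inf + COD_CH4) / (tCOD_inf - tCOD_eff)."""
    return (m.sCOD_eff - m.sCOD_inf + m.COD_CH4) / _degraded_tcod(m)


def methanogenesis_efficiency(m: ChemMeasurement) -> float:
    """COD_CH4 / (tCOD_inf - tCOD_eff)."""
    return m.COD_CH4 / _degraded_tcod(m)


def hydrolysis_rate_constant(
    b: BatchSeries,
    t_index: int | None = None,
    method: str = "point",
) -> float:
    """First-order hydrolysis rate constant K_H (1/day) from a batch series.

    K_H = (1/dt) * ln[(CH4_end + sCOD_end - sCOD_0) /
                      ((CH4_end + sCOD_end) - (CH4_t + sCOD_t))]

    which inverts S_t = S_end * (1 - exp(-k dt)) for the degradable pool
    S_t = CH4_t + sCOD_t - sCOD_0. ``t_index`` selects the interior time point
    (default: midpoint of the series). ``method='lsq'`` instead least-squares
    fits ln(1 - S_t/S_end) = -k dt over all interior points — an extension
    beyond the single-point definition, off by default.
    """
    t = np.asarray(b.times, dtype=float)
    s = np.asarray(b.sCOD_t, dtype=float)
    ch4 = np.asarray(b.COD_CH4_t, dtype=float)
    total_end = ch4[-1] + s[-1]
    numer = total_end - s[0]
    if numer <= 0:
        raise UndefinedMetricError("no net degradable COD: CH4_end + sCOD_end <= sCOD_0")

    if method == "lsq":
        dt = t[1:] - t[0]
        denom = total_end - (ch4[1:] + s[1:])
        ok = denom > 0
        if not np.any(ok):
            raise UndefinedMetricError("degradation complete at every interior point")
        y = np.log(numer / denom[ok])
        x = dt[ok]
        return float(np.dot(x, y) / np.dot(x, x))

    if method != "point":
        raise ValueError(f"unknown method {method!r}")
    if t_index is None:
        t_index = len(t) // 2
    if not (0 < t_index < len(t)) :
        raise ValueError(f"t_index must be an interior/terminal index in [1, {len(t) - 1}]")
    dt = t[t_index] - t[0]
    if dt == 0:
        raise UndefinedMetricError("zero elapsed time")
    denom = total_end - (ch4[t_index] + s[t_index])
    if denom <= 0:
        raise UndefinedMetricError(
            "degradation already complete at the chosen time point (non-positive log argument)"
        )
    return float(np.log(numer / denom) / dt)


def d_efficiency(hyd: float, meth: float) -> float:
    """Relative differential efficiency (hyd - meth) / hyd."""
    if hyd == 0:
        raise UndefinedMetricError("D_efficiency undefined for zero hydrolysis efficiency")
    return (hyd - meth) / hyd


def d_rate(K_H: float, SMA: float) -> float:
    """Relative differential rate (K_H - SMA) / K_H."""
    if K_H == 0:
        raise UndefinedMetricError("D_rate undefined for zero hydrolysis rate constant")
    return (K_H - SMA) / K_H


def pcod_ratio(m: ChemMeasurement) -> float:
    """Fraction of influent total COD that is particulate: 1 - sCOD_inf/tCOD_inf."""
    if m.tCOD_inf <= 0:
        raise UndefinedMetricError("pCOD ratio undefined for zero influent tCOD")
    return 1.0 - m.sCOD_inf / m.tCOD_inf


def derive_metrics(m: ChemMeasurement, K_H: float = float("nan")) -> DerivedMetrics:
    """All derived metrics for one chemistry record.

    ``K_H`` (from a separate batch assay) is optional; ``D_rate`` is NaN
    without it or without SMA_total.
    """
    hyd = hydrolysis_efficiency(m)
    meth = methanogenesis_efficiency(m)
    dr = float("nan")
    if math.isfinite(K_H) and K_H != 0 and math.isfinite(m.SMA_total):
        dr = d_rate(K_H, m.SMA_total)
    return DerivedMetrics(
        FA=free_ammonia(m.TAN, m.pH, m.temperature_C),
        hydrolysis_eff=hyd,
        methanogenesis_eff=meth,
        D_efficiency=d_efficiency(hyd, meth) if hyd != 0 else float("nan"),
        pCOD_ratio=pcod_ratio(m),
        K_H=K_H,
        D_rate=dr,
        reactor_id=m.reactor_id,
        stage=m.stage,
    )


_CHEM_FIELDS = {f.name for f in fields(ChemMeasurement)} - {"reactor_id", "stage"}


def read_chemistry_tsv(path) -> list[ChemMeasurement]:
    """Read long-format chemistry TSV (reactor_id, stage, variable, value, unit)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"reactor_id", "stage", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemistry TSV missing columns: {sorted(missing)}")
    out: list[ChemMeasurement] = []
    for (rid, stage), grp in df.groupby(["reactor_id", "stage"], sort=True):
        vals = dict(zip(grp["variable"], grp["value"]))
        unknown = set(vals) - _CHEM_FIELDS
        if unknown:
            raise ValueError(f"unknown chemistry variables for {rid}/{stage}: {sorted(unknown)}")
        out.append(ChemMeasurement(reactor_id=str(rid), stage=str(stage), **vals))
    return out


def write_metrics_tsv(metrics: Sequence[DerivedMetrics], path, header_comment: str = "") -> None:
    """Write a tidy DerivedMetrics table."""
    rows = [
        {
            "reactor_id": m.reactor_id,
            "stage": m.stage,
            "FA": m.FA,
            "hydrolysis_eff": m.hydrolysis_eff,
            "methanogenesis_eff": m.methanogenesis_eff,
            "K_H": m.K_H,
            "D_efficiency": m.D_efficiency,
            "D_rate": m.D_rate,
            "pCOD_ratio": m.pCOD_ratio,
        }
        for m in metrics
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
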