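# digestnet

Co-occurrence network analysis for anaerobic-digestion (AD) microbiomes:
from reactor chemistry and genus-level abundance tables to per-group Spearman
co-occurrence networks, their topology, per-genus ecological roles, and the
correlation between network structure and reactor performance.

It is written for environmental engineers and microbial ecologists who run
multi-reactor AD experiments (blackwater, co-digestion, mesophilic vs
thermophilic…) and want the community-network side of the analysis to be
scripted, seeded and testable rather than a pile of one-off notebook cells.

## What it computes

**Derived reactor metrics** (`digestnet.reactor_metrics`) — free ammonia
FA = 1.214·TAN·(1 + 10^(−pH)/10^(−(0.09018 + 2729.92/T)))^(−1) (T in K);
hydrolysis efficiency (sCOD_eff − sCOD_inf + COD_CH4)/(tCOD_inf − tCOD_eff);
methanogenesis efficiency COD_CH4/(tCOD_inf − tCOD_eff); first-order
hydrolysis rate constant K_H from batch series; the imbalance measures
D_efficiency = (hyd − meth)/hyd and D_rate = (K_H − SMA)/K_H; pCOD ratio.

**Community preparation** (`digestnet.community`) — normalization, the
network inclusion filter (relative abundance > 0.1% in ≥ 3 samples of the
group), Shannon/richness/evenness, Bray–Curtis, PCoA, steady-state
subsampling of over-represented groups.

**Networks** (`digestnet.correlation`, `digestnet.network`) — all-pairs
Spearman rho with t-approximation p (exact permutation p for n ≤ 10), edges
at |rho| > 0.6 and p < 0.01 with sign; per-group topology panel: clustering
coefficient with an Erdős–Rényi G(n,m) baseline, modularity (deterministic
greedy + refinement, exact for n ≤ 8, seeded Louvain optional), positive
ratio, average path length, average (normalized) degree, normalized
betweenness, order and size; discrete power-law degree fit (Clauset-style
MLE, KS cutoff selection, bootstrap goodness of fit).

**Keystone roles** (`digestnet.keystone`) — within-module connectivity
Z_i = (κ_i − mean κ)/sd κ and among-module connectivity
P_i = 1 − Σ_s (k_is/k_i)²; Guimerà–Amaral quadrants (peripheral / module hub
/ connector / network hub at Z = 2.5, P = 0.62); top-10 rankings by
normalized degree and betweenness with low-abundance-keystone flagging.

**Linkage** (`digestnet.linkage`) — Pearson correlation of every network
property with every reactor parameter across groups, significance stars at
p < 0.05, and a sample-size confound check.

**Synthetic data** (`digestnet.synthetic`) — a seeded generator emulating a
52-sample / 12-reactor / 5-group survey with planted module structure,
group-dominant genera, multinomial counts, zero inflation, and reactor
parameters that co-vary with the planted signal, so every stage is testable
against ground truth. See `docs/methods.md` for what it does and does not
emulate.

## Worked example

`examples/reactor_metrics_basics.py`:

```
FA mesophilic  (TAN=93,  pH=7.5, 35 degC):   3.88 mg-N/L
FA thermophilic(TAN=1217, pH=7.0, 52 degC):  46.72 mg-N/L
K_H recovered from batch series: 0.250 1/d (true 0.250)
hydrolysis efficiency      0.833   (fraction of degraded tCOD solubilized)
methanogenesis efficiency  0.750   (fraction converted to CH4)
D_efficiency               0.100   (relative hydrolysis-methanogenesis gap)
D_rate                     0.201   (relative K_H vs SMA gap)
pCOD ratio                 0.800   (particulate share of influent COD)
free ammonia               26.7 mg-N/L
```

The first two lines reproduce published stage-mean free-ammonia levels: a
mesophilic low-ammonia digester sits near 4 mg-N/L while a thermophilic
high-TAN one reaches ~47 mg-N/L — the temperature and pH dependence of the
NH3 equilibrium, not a difference in measurement. The remaining lines derive
one reactor stage's performance: 83% of the degraded COD was solubilized and
75% ended up as methane, so hydrolysis outpaces methanogenesis by 10%
relative (D_efficiency = 0.10), on a feed that is 80% particulate.

The full pipeline on synthetic data (`examples/simulate_and_analyze.py`):

```python
from digestnet.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(simulate=True, seed=7, out_dir="out"))
```

writes one network per group (GraphML + edge list), the topology panel, node
roles, the linkage grid and a checksummed manifest; rerunning with the same
config and seed is byte-identical. `examples/keystone_roles.py` walks one
group's Zi–Pi role analysis and hub rankings.

A thin CLI wraps the same functions:

```
digestnet simulate --seed 7 --out-dir out
digestnet network --abundance counts.tsv --groups groups.tsv --params params.tsv
digestnet metrics --chemistry chem.tsv --out metrics.tsv
```

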