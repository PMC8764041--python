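# Methods

`digestnet` links anaerobic-digestion (AD) reactor performance to the
topology of microbial co-occurrence networks. This note documents the models
and procedures it implements, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter.

## Derived reactor metrics

All metrics are computed from measured chemistry; none is fitted.

**Free ammonia** (mg-N/L), the un-ionized and methanogenesis-inhibiting
fraction of total ammonia nitrogen (TAN), follows the ammonia dissociation
equilibrium

    FA = 1.214 · TAN · (1 + 10^(−pH) / 10^(−(0.09018 + 2729.92/T)))^(−1)

with T in kelvin. The API takes °C (how operating temperatures are recorded)
and converts internally. FA is strictly increasing in pH and temperature and
bounded by 1.214·TAN; FA/TAN depends on (pH, T) only. Both properties are
regression-tested.

**Hydrolysis and methanogenesis efficiency** are fractions of the degraded
total COD (tCOD_inf − tCOD_eff):

    hydrolysis      = (sCOD_eff − sCOD_inf + COD_CH4) / (tCOD_inf − tCOD_eff)
    methanogenesis  =  COD_CH4                        / (tCOD_inf − tCOD_eff)

so their difference is exactly (sCOD_eff − sCOD_inf)/(tCOD_inf − tCOD_eff);
methanogenesis can exceed hydrolysis only for soluble-rich feeds
(sCOD_eff < sCOD_inf). Efficiencies are returned as fractions; percent
formatting is presentation only. Metrics of stage means differ from means of
per-sample metrics (Jensen gap); both modes are supported by choosing what to
pass in.

**Hydrolysis rate constant** K_H (1/day) inverts first-order substrate
release S_t = S_end(1 − e^(−k·Δt)), where S_t = COD_CH4,t + sCOD_t − sCOD_0:

    K_H = (1/Δt) · ln[(COD_CH4,end + sCOD_end − sCOD_0)
                      / ((COD_CH4,end + sCOD_end) − (COD_CH4,t + sCOD_t))]

The evaluation time t within the batch is a free choice; the default is the
midpoint sample (exposed as `t_index`), and a least-squares variant over all
interior points is available (`method="lsq"`, off by default) for noisy
series. Points where degradation is numerically complete (non-positive log
argument) are errors in point mode and skipped in lsq mode.

**D_efficiency = (hyd − meth)/hyd** and **D_rate = (K_H − SMA)/K_H** are the
dimensionless hydrolysis-vs-methanogenesis imbalance measures; both are
undefined (error) at zero denominator. **pCOD ratio = 1 − sCOD_inf/tCOD_inf**
is the particulate share of influent COD, the demand for hydrolysis.

## Community preparation

Tables are samples × genera. Relative abundance is per-sample closure;
zero-total samples are rejected. The network inclusion filter keeps taxa with
relative abundance **> 0.1% in ≥ 3 samples of the analysis group** ("more
than two" read strictly; both knobs configurable). The filter is applied per
group because networks are built per group; it is idempotent and refuses
groups with fewer than 4 samples. Alpha diversity is Shannon H (natural log),
genus richness, and Pielou evenness H/ln(richness) with the richness-1 case
defined as 0. Beta diversity is Bray–Curtis; ordination is classical PCoA
(double-centered Gower eigendecomposition via scikit-bio) with negative
eigenvalues reported and their axes dropped — no Cailliez correction, the
simplest defensible treatment of Bray–Curtis non-Euclideanness. Groups with
many samples can be capped (default 8/group) by a deterministic preference
for steady-state, late-stage samples with lexical tie-breaks, to avoid
sample-size bias between networks. Group assignment is config-driven; a
hierarchical-clustering helper (average linkage on Bray–Curtis) can propose
groups but never assigns silently, since grouping in practice is a judgment
combining ordination and dominant genera.

## Co-occurrence networks

Edges are Spearman correlations with **|rho| > 0.6 and p < 0.01** (both
configurable). The absolute-value reading is the default because observed
networks contain negative edges; a strict-positive mode exists for
sensitivity analysis. p-values are two-sided from t = rho·√((n−2)/(1−rho²))
on n−2 df, the convention of standard correlation packages, and are
deliberately uncorrected (a Benjamini–Hochberg flag exists, off by default).
The t-approximation is **anticonservative at small n** (its realized
false-positive rate at p < 0.01 is ≈1.4% for n = 10 and ≈2% for n = 8); for
calibrated decisions at n ≤ 10 `p_mode="exact"` replaces p with the exact
permutation tail probability of |rho|, enumerated once per n from the
tie-free null and matched against a brute-force oracle in the tests. Constant
taxa have undefined rank correlation; they are flagged and excluded from edge
candidacy rather than aborting the group.

Graphs are simple and undirected; edge sign and |rho| are stored, but **all
topology is computed on the unweighted, sign-agnostic skeleton** — there is
no weighted-metric convention worth defaulting to, and signed variants are
deliberately out. Isolated taxa are dropped from the graph but logged.

Topology panel per group: order, size, mean local clustering coefficient
(nodes with degree < 2 score 0; global transitivity available under a flag),
Erdős–Rényi G(n, m) baseline clustering (mean ± sd over 100 seeded
replicates, exact edge-count match), modularity Q of the detected partition,
positive-edge ratio, average shortest-path length over connected pairs only
(per-component sizes logged on disconnected graphs), average degree,
normalized degree k/(n−1), and normalized betweenness (Brandes, endpoints
excluded, normalization (n−1)(n−2)/2).

**Community detection.** Default is deterministic greedy modularity
agglomeration followed by a local refinement pass (single-node moves,
including to fresh singletons, and pairwise community merges until no move
improves Q) — determinism keeps panel rows reproducible run to run. For
graphs with ≤ 8 nodes the exact maximum-modularity partition is found by
enumerating all set partitions (Bell(8) = 4140), so tiny-graph results are
optimal, not heuristic. Seeded Louvain is available as an alternative. On
random ≤ 8-node graphs the default matches exhaustive search in ≥ 95% of
cases (tested).

**Power-law degree fit.** Discrete maximum likelihood for the exponent
(numerical minimization of n·ln ζ(α, x_min) + α·Σ ln x), lower cutoff x_min
chosen by minimizing the Kolmogorov–Smirnov distance computed on distinct
values (the correct form for tied, discrete data), and a parametric bootstrap
goodness-of-fit p (n_boot replicates; p < 0.05 rejects the power law).
Sequences with < 10 distinct degrees are fitted but flagged.

## Keystone (Zi–Pi) analysis

Given a module partition, within-module connectivity Zi is the z-score of a
node's within-module degree against its module (population sd; sd = 0 maps
to Zi = 0 with a flag so regular or singleton modules do not crash), and
among-module connectivity Pi = 1 − Σ_s (k_is/k_i)² sums over **all** modules
including the node's own. Roles follow the Guimerà–Amaral quadrants at
Zi = 2.5 and Pi = 0.62 — thresholds the upstream literature uses but rarely
prints, so they are explicit config and echoed in output metadata:
peripheral, module hub (Zi > 2.5), connector (Pi > 0.62), network hub (both).
Link conservation Σ_s k_is = k_i is asserted on every node. Hub rankings by
normalized degree and normalized betweenness use lexical tie-breaks; the
overlap between the two top-10 lists is reported, and taxa below a
configurable abundance (default 0.1%) appearing in either list are flagged —
the low-abundance-keystone signature.

On Erdős–Rényi null graphs peripherals dominate and Zi-hubs are rare, but a
nontrivial connector fraction (~10–20% at mean degree 3) is *expected*: any
degree-3 node splitting links evenly over three modules already has
Pi = 0.667. Tests assert the defensible null (peripheral-dominated, ≤ 5%
hubs), not an all-peripheral fiction.

## Topology–performance linkage

Each group contributes one topology-panel row and one derived-metrics row;
every property × parameter pair gets a Pearson r (Spearman optional) with a
two-sided t-test p on n−2 df and a significance flag at α = 0.05,
uncorrected by default to match starred-matrix presentation (BH flag
available). With five groups these p-values are fragile; the code warns at
n < 6 but does not block. A companion check correlates group sample count
and network order against every property and flags significant correlations
as potential size confounds — network size is expected to track sample
count; other properties should not.

## Synthetic data generator

The generator exists so every stage is testable against known truth with no
sequencing data. It emulates the *shape* of a 52-sample, 12-reactor,
five-group blackwater-digestion survey: per-group sample counts
(20, 6, 13, 5, 8), reactor counts (5, 2, 2, 1, 2), 150 bacterial + 15
archaeal genera with a handful of persistently dominant genera per group
(dominant methanogens and fermenters are stable features of digester
communities), genus-level counts by multinomial resampling at 50k reads with
2% zero inflation.

It is a **latent-factor compositional test harness, not a mechanistic model
of digester ecology**. Per group, 48 taxa are partitioned into 4 modules;
log-abundance of a module taxon is base + loading·factor + N(0, 0.2), other
taxa vary independently with sd 1.0, and 10% of loadings are negative
(producing negative edges and a positive ratio below 1). Three design
choices keep the planted truth true in small samples:

* module factors are QR-orthogonalized within each group, because at n = 8
  independently drawn factors are often strongly correlated by chance, which
  would couple modules planted as independent;
* module taxa get low baselines (≈0.1–1% relative abundance) so they stay a
  minor share of reads — a module that episodically dominates the sample
  moves the compositional denominator of *every* taxon and induces spurious
  cross-module correlation;
* dominant genera vary little between samples for the same
  closure reason.

Per-group module strength rises from 1.0 to 2.0 across groups, and the
reactor-parameter simulator makes hydrolysis efficiency, pCOD ratio and K_H
increase linearly with it (coefficient `param_dependence`, 0 decouples),
with raw chemistry constructed to be internally consistent and run through
the real derived-metrics code path; values stay within ordinary blackwater
ranges (influent tCOD 1–33 g/L, TAN ≤ 1.4 g-N/L, pH 7–8.2, temperatures
22/35/52 °C). All randomness flows from one seed.

What the generator does **not** emulate: taxon–taxon interaction mechanisms,
phylogenetic correlation, overdispersion beyond multinomial + dropout,
abundance-dependent dropout, temporal autocorrelation within reactors, or
any causal link from chemistry to community. Passing tests therefore
demonstrate that the *pipeline* recovers planted structure and calibrated
error rates under a compositional count model — not that real digester data
have such structure.

## Problem sizes and tolerances in the test suite

Oracle equivalence uses 100 random graphs with n ≤ 12 (exhaustive
betweenness/path enumeration stays tractable) and exhaustive modularity on
n ≤ 8. The Erdős–Rényi baseline check uses n = 200, 100 replicates, 15%
relative tolerance (sampling noise of the mean at that size). Planted-module
recovery on the default fixture requires adjusted Rand ≥ 0.8 on every group
with ≥ 8 retained samples; groups of 5–6 samples are excluded because at
n = 5 the minimum attainable t-approximation p exceeds 0.01 for any
imperfect rank correlation, so those networks keep only |rho| = 1 edges by
construction. The null false-positive check uses exact p-values (see above)
and binomial 99% bounds around the nominal 1%. Numerical comparisons to
closed forms use 1e−9–1e−12 absolute tolerance.

## Known limitations

* The t-approximation default mirrors common practice but is miscalibrated
  at the sample sizes where these networks are typically built; the exact
  mode is limited to n ≤ 10 by factorial enumeration.
* Plain Spearman on relative abundances ignores compositionality;
  compositionality-aware association (SparCC-style) is deliberately out of
  scope.
* Group-level linkage has 5 observations per correlation; its p-values
  should be read as descriptive.
* Exact modularity is limited to n ≤ 8; above that the refined greedy
  heuristic can still miss the optimum on adversarial graphs.
* PCoA axes for strongly non-Euclidean distance matrices lose the variance
  carried by negative eigenvalues (reported, not corrected).
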