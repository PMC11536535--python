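# Methods

This note documents the statistical models and procedures the package
implements, the choices made where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Study design

All metabolomics machinery assumes a two-by-two factorial design on T-cell
samples: CELL (resting naive CD4+ T cells vs an autoreactive,
antigen-specific line, "PLP") crossed with TREATMENT (vehicle control vs
pantethine, "PTTH"), with incubation TIME (6 h / 12 h) nested as a nuisance
factor. Default group sizes are 3 (Naive/CTRL), 4 (Naive/PTTH) and 7 each
for PLP/CTRL and PLP/PTTH — 21 samples. The antibody-microarray arm
compares two conditions (CTRL vs PTTH) with duplicate arrays per condition.

## Metabolomics preprocessing

**Missingness grading.** Semi-quantitative metabolite panels miss values
for two distinct reasons: at random (technical dropouts) and structurally
(a metabolite absent from a biological group). Features with < 30 %
missingness in *every* group are usable for both multivariate and
univariate analysis (`MVA_UVA`). Features essentially absent (≥ 90 %
missing, configurable) in at least one group but complete enough (< 30 %)
in the remaining groups are treated as not-missing-at-random and analysed
univariately in those usable groups only (`UVA_only`). Everything else is
excluded. The 90 % group-absence cut is this package's operationalization
of "not missing at random": group-wise absence should not hinge on a single
stray NA. A raw-intensity floor for very-low-signal features exists but is
disabled by default — no principled threshold is available.

**Normalization.** Each MVA feature is min–max scaled to [0, 1] across
samples (non-missing values only; constant features pin to 0.5); the
per-sample factor is the median of that sample's scaled MVA values; every
raw intensity is divided by its sample's factor and log10-transformed. A
zero or negative median falls back to the sample's mean scaled value, and a
still-nonpositive factor is an error (tiny toy matrices can zero a whole
scaled row). This median-of-scaled factor corrects per-sample loading
(cell-number) differences *approximately*, not exactly: rescaling one
sample's raw row by c > 0 changes every normalized profile by a per-sample
additive constant (shapes are preserved exactly), and the bulk — not all —
of log10(c) is absorbed by the factor. Exact absorption would require a
scale-equivariant factor (e.g. the median of raw intensities); we keep the
scaled-median convention because it weights all metabolites equally
regardless of their intensity ranges.

**QC.** Per feature: a one-sample Kolmogorov–Smirnov test against a normal
with the feature's own mean/SD, and a Brown–Forsythe (median-centred
Levene) test across the four groups. Per sample: outlier flags when the
sample median, the protein-content covariate or the distance from the
centroid in 2-component PCA score space exceeds 3 scaled MADs (k
configurable). Features with < 3 non-missing values are skipped and
recorded. QC only reports; flagged samples are excluded only on explicit
request, mirroring analyst-driven exclusion.

## Multivariate analysis

PCA is computed by NIPALS with missing-value support (score/loading
regressions skip missing cells), centered and unit-scaled, sign-fixed so
each component's largest-magnitude loading is positive; on complete data it
reproduces the SVD solution. PLS-DA first imputes missing cells by an
EM-style iterative rank-k PCA reconstruction (tolerance 1e-6, ≤ 200
iterations; a no-op on complete data), then fits a 2-component PLS
regression on one-hot group membership. The predicted score for group *g*
is the fitted response column for *g*; group separation is the ROC AUC of
that score, group vs rest, oriented ≥ 0.5, with a two-sided Wilcoxon
rank-sum p-value on the same scores. These are *in-sample* scores: with ~21
samples and > 100 features a 2-component PLS partially fits noise, so null
AUCs sit above 0.5 (calibration approaches the nominal level only when n
well exceeds the effective dimension). The AUC ≥ 0.95 separation claim
should therefore be read as descriptive, exactly as this ROC convention is
used in practice.

## Per-metabolite mixed models

For each metabolite the normalized log10 response is fit twice by maximum
likelihood: a linear mixed model with fixed effects CELL * TREATMENT and a
random intercept for TIME, and a fixed-effects-only competitor (generalized
least squares; with homoscedastic errors this is OLS). ML rather than REML
so AIC and log-likelihood are comparable across different random
structures. The lower AIC wins; ties go to the simpler model. The
likelihood-ratio test for the variance component uses the boundary-corrected
50:50 mixture of χ²₀ and χ²₁ (plain χ²₁ via config). Non-convergent mixed
fits fall back to the fixed-only model with a per-feature flag.

Contrasts are differences of estimated marginal means of the four
CELL × TREATMENT cells (TIME carries no fixed effect, so cell means are
fixed-effect combinations): PLP.CTRL − Naive.CTRL, PLP.PTTH − PLP.CTRL and
Naive.PTTH − Naive.CTRL. Standard errors come from the chosen model's
fixed-effect covariance; t-tests use residual degrees of freedom (no
Kenward–Roger/Satterthwaite — with two time levels those corrections are
unstable; this is a documented approximation). Benjamini–Hochberg FDR is
applied across features separately within each comparison. `UVA_only`
features are fit on their usable groups with constant factors dropped;
contrasts touching an unusable cell are reported missing and excluded from
that comparison's FDR family. Constant responses yield zero estimates with
p = 1. Model choice by "direct comparison of fitted values" is available
only as a diagnostic table, never as an automatic criterion.

## Set-level statistics

**Quantitative enrichment (global test).** Missing values are imputed
feature-wise by KNN (a missing cell is filled from the k = 10 features
nearest in Euclidean distance over shared observed samples), features are
autoscaled, and per pathway the quadratic statistic
Q = (y − ȳ)ᵀ X Xᵀ (y − ȳ) / m is computed over the pathway's m member
columns and the centered binary phenotype. Significance is by permutation
of y (≥ 1000 draws, seeded), p = (b + 1)/(n_perm + 1), BH across pathways.
The permutation null replaces the asymptotic gamma approximation, which is
fragile at n ≤ 21. Note that with a *balanced* phenotype the complement
labeling is itself a permutation with identical Q, so the minimal p is
attained only up to that degeneracy; the study's unbalanced 7-vs-14 design
does not have it.

**Pathway topological impact.** Per-pathway node importance is out-degree
centrality normalized to sum 1 within the pathway graph (relative
betweenness available via config); impact is the summed importance of hit
nodes, hence in [0, 1]. Pathways without a graph get a missing impact, not
zero.

**Over-representation.** Hypergeometric upper-tail p of the hit/set
overlap against the measured background, BH across sets, with the
conventional dual cut (p < 0.001 and FDR < 0.05) flagged.

## Antibody-microarray Z ratios

Background-corrected spot intensities are log2-transformed and standardized
within each array: z = (log2 x − mean over spots)/SD over spots, using the
sample (n − 1) SD by default (population SD via config). Duplicate arrays
are averaged *after* Z-scoring. The per-protein difference of
condition-mean Z scores, divided by the SD of all proteins' differences, is
the Z ratio; |Z ratio| ≥ 1.1 is called significant. By construction the
Z-ratio vector has SD exactly 1, asserted after every run. Pan-specific and
phospho-site-specific antibodies are analysed pooled (separable by a filter
flag). The probe for network interrogation is the set intersection of the
significantly down-regulated enriched pathways' member proteins.

## Network reduction

The interactome is compiled from one or more edge lists: IDs normalized
through a user-supplied map, undirected duplicates collapsed, self-loops
dropped; direction annotations are kept per edge and merge to "both" when
sources disagree. Probe interrogation takes the induced subgraph on the
probe plus its direct neighbors. Five node scores are computed on that
first-neighbors network:

- degree; unnormalized shortest-path betweenness;
- centroid: min over other nodes w of γ_v(w) − γ_w(v), where γ_v(w)
  counts third nodes strictly closer to v than to w (hop counts;
  unreachable nodes excluded, so cross-component pairs contribute 0);
- bridging: betweenness × (1/deg(v)) / Σ_{u∈N(v)} 1/deg(u);
- heat: the probe-seeded entry of expm(−tL)·s, t = 0.1 by default.

Node selection keeps nodes whose index is ≥ 50 % of that index's mean — for
every index (default, conjunctive) or for at least one (`mode="any"`).
Caveat: the 50 %-of-average rule presumes nonnegative scores; the centroid
index usually has a *negative* mean on star-like first-neighbor networks,
which makes the conjunctive rule stricter than the average itself and can
collapse the selection to a handful of nodes. Both modes are exposed; the
demonstration cascade in `scripts/acceptance.py` uses the disjunctive mode
for this reason. Heat diffusion is computed and reported but not used for
selection by default (the index list is configurable). The surviving
subgraph is then restricted to direction-annotated edges, yielding the
directed signalling subnetwork ("both" produces two arcs).

**MCODE.** Vertex weight = (highest-k-core k of the closed neighborhood) ×
(density of that k-core). Complexes grow outward from the highest-weight
unvisited seed, admitting neighbors with weight ≥ (1 − vwp) × seed weight
(vwp = 0.2); modules are node-disjoint; the haircut reduces each module to
its 2-core; score = density × size; ties break on lexicographic node ID so
the output is deterministic.

## Synthetic data

The generators emulate the study conditions so that every stage is testable
offline with known ground truth:

- **Metabolomics**: raw intensity = 10^(baseline + fixed effects + shared
  per-time random intercept + noise), with per-group sample counts 3/4/7/7
  and alternating 6h/12h assignment. Defaults: baseline log10 mean 6, SD 1;
  residual SD 0.25 (log10); time-intercept SD 0.05 — chosen as a plausible
  technical/biological split for semi-quantitative panels (the magnitude of
  either variance source is a free parameter, not a claim about any real
  dataset). Missingness: forced group-wise deletion (MNAR emulation),
  left-censoring of values whose *noise-free* signal falls below a
  per-metabolite quantile (so constant-signal metabolites are untouched and
  censoring tracks group structure), then MCAR. A per-sample
  protein-content covariate proportional to total signal feeds the outlier
  screen. Not emulated: peak detection, batch/drift structure, correlated
  metabolite classes beyond the injected effects — so passing tests
  demonstrate algorithmic correctness, not robustness to those artefacts.
- **Antibody arrays**: two conditions × duplicate arrays; planted proteins
  shift by ±shift log2 units (alternating sign) in the second condition;
  duplicate noise SD on the log2 scale.
- **Interactomes**: Barabási–Albert (default) or Erdős–Rényi background
  with a planted module of configurable size and internal density, probe
  nodes inside the module, and direction annotations on a configurable
  fraction of edges.

All generators are bit-reproducible given their seed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
centrality oracles on 100 random graphs of ≤ 30 nodes; MCODE recovery on
100 200-node graphs; FDR control on 20 (tests) / 10 (script) null
replicates of the 200-metabolite design; permutation tests at 99–999
draws. These sizes give stable statistics at interactive runtimes.

## Known limitations

- Contrast degrees of freedom are residual-based; with only two time
  levels the variance component is weakly identified, and the LMM/GLS AIC
  comparison is the main guard against overfitting it.
- PLS-DA AUCs are in-sample and optimistic at small n (see above).
- The normalization factor removes per-sample scale only approximately
  (see above); group contrasts inherit the small residual constants.
- The network cascade's absolute node counts depend strongly on the
  background topology and the direction-annotation coverage; only planted-
  structure recovery, not absolute counts, is a meaningful benchmark on
  synthetic graphs.
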