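"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the three data modalities the pipeline consumes:

* :func:`simulate_metabolomics` — a metabolite intensity matrix under the
  study design (four CELL x TREATMENT groups of sizes 3/4/7/7, a nested
  6h/12h incubation-time factor shared as a random intercept, log10-scale
  fixed effects, left-censored and MCAR missingness);
* :func:`simulate_phospho_array` — a duplicate-spotted two-condition antibody
  microarray with a planted set of shifted proteins on the log2 scale;
* :func:`simulate_interactome` — a sparse background graph with a planted
  dense module containing a probe set, and direction annotations on a
  configurable fraction of edges.

Each generator is deterministic given its spec's seed and returns the ground
truth alongside the data, so downstream inference can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_GROUP_SIZES = {
    "Naive/CTRL": 3,
    "Naive/PTTH": 4,
    "PLP/CTRL": 7,
    "PLP/PTTH": 7,
}

DEFAULT_TIME_LEVELS = ("6h", "12h")


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------

@dataclass
class MetabSimSpec:
    """Parameters of the metabolomics generator.

    Effects are on the log10 scale (the scale the downstream models fit).
    ``effect_table`` maps feature index -> (cell, treatment, interaction)
    effect sizes; unlisted features are null.  ``groups_forced_missing`` maps
    feature index -> set of group labels whose values are removed entirely,
    emulating group-wise (not-at-random) absence.
    """

    n_metabolites: int = 200
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    time_levels: tuple[str, ...] = DEFAULT_TIME_LEVELS
    effect_table: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    mcar_rate: float = 0.0
    lod_quantile: float = 0.0
    groups_forced_missing: dict[int, set[str]] = field(default_factory=dict)
    noise_sd: float = 0.25
    time_sd: float = 0.05
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must be in [0, 1)")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.time_sd < 0:
            raise ValueError("time_sd must be >= 0")
        bad = [i for i in self.effect_table if not 0 <= i < self.n_metabolites]
        if bad:
            raise ValueError(f"effect_table indexes out of range: {bad}")


def simulate_metabolomics(
    spec: MetabSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (intensity matrix, sample design, truth table).

    The raw intensity of sample *i*, metabolite *m* is
    ``10 ** (baseline_m + effects_m(i) + b_time(i) + eps)`` with
    ``b_time ~ N(0, time_sd)`` shared by all samples at the same incubation
    time (one draw per metabolite and time level) and
    ``eps ~ N(0, noise_sd)``.  Missingness is applied afterwards: forced
    group-wise removal, left-censoring of the lowest ``lod_quantile`` of each
    metabolite's noise-free signal, then MCAR at ``mcar_rate``.

    The design also carries a ``protein_content`` covariate proportional to
    each sample's total raw signal, feeding the QC outlier screen.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # -- design ------------------------------------------------------------
    samples, cells, treatments, times, groups = [], [], [], [], []
    for group, n in spec.group_sizes.items():
        cell, trt = group.split("/")
        for k in range(n):
            samples.append(f"{cell}-{trt}-{k + 1:02d}")
            cells.append(cell)
            treatments.append(trt)
            # alternate time levels within each group (nested time factor)
            times.append(spec.time_levels[k % len(spec.time_levels)])
            groups.append(group)
    design = pd.DataFrame(
        {"CELL": cells, "TREATMENT": treatments, "TIME": times, "group": groups},
        index=pd.Index(samples, name="sample"))

    n_s, n_m = len(samples), spec.n_metabolites
    features = [f"met{j + 1:04d}" for j in range(n_m)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_m)
    is_plp = (design["CELL"] == "PLP").to_numpy()
    is_ptth = (design["TREATMENT"] == "PTTH").to_numpy()

    log10 = np.tile(baseline, (n_s, 1))
    for j, (ce, te, ie) in spec.effect_table.items():
        log10[:, j] += ce * is_plp + te * is_ptth + ie * (is_plp & is_ptth)
    signal = log10.copy()  # noise-free, for the left-censoring threshold

    # shared random intercept per (metabolite, time level)
    time_codes = design["TIME"].map(
        {t: i for i, t in enumerate(spec.time_levels)}).to_numpy()
    b_time = rng.normal(0.0, spec.time_sd, size=(len(spec.time_levels), n_m))
    log10 += b_time[time_codes, :]
    log10 += rng.normal(0.0, spec.noise_sd, size=(n_s, n_m))

    values = 10.0 ** log10

    # -- missingness -------------------------------------------------------
    mask = np.zeros((n_s, n_m), dtype=bool)
    for j, bad_groups in spec.groups_forced_missing.items():
        mask[:, j] |= design["group"].isin(bad_groups).to_numpy()
    if spec.lod_quantile > 0:
        for j in range(n_m):
            thr = np.quantile(signal[:, j], spec.lod_quantile)
            mask[:, j] |= signal[:, j] < thr
    if spec.mcar_rate > 0:
        mask |= rng.random((n_s, n_m)) < spec.mcar_rate
    values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=design.index, columns=features)
    design["protein_content"] = np.nansum(values, axis=1)

    truth = pd.DataFrame(
        {
            "cell_effect": [spec.effect_table.get(j, (0, 0, 0))[0] for j in range(n_m)],
            "treatment_effect": [spec.effect_table.get(j, (0, 0, 0))[1]
                                 for j in range(n_m)],
            "interaction_effect": [spec.effect_table.get(j, (0, 0, 0))[2]
                                   for j in range(n_m)],
            "forced_missing_groups": [
                ";".join(sorted(spec.groups_forced_missing.get(j, set())))
                for j in range(n_m)],
        },
        index=pd.Index(features, name="feature"))
    truth["is_null"] = (
        (truth[["cell_effect", "treatment_effect", "interaction_effect"]] == 0)
        .all(axis=1))
    return matrix, design, truth


# ---------------------------------------------------------------------------
# antibody microarray
# ---------------------------------------------------------------------------

@dataclass
class PhosphoSimSpec:
    """Parameters of the two-condition duplicate-array generator."""

    n_proteins: int = 500
    n_diff: int = 10
    shift: float = 2.0
    duplicate_cv: float = 0.05
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    conditions: tuple[str, str] = ("CTRL", "PTTH")
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_diff <= self.n_proteins:
            raise ValueError("n_diff must satisfy 0 <= n_diff <= n_proteins")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")
        if self.duplicate_cv < 0:
            raise ValueError("duplicate_cv must be >= 0")


def simulate_phospho_array(
    spec: PhosphoSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Generate (intensity matrix, array design, truth set of shifted IDs).

    Four arrays: two duplicate spottings per condition.  Log2 intensity of a
    spot is baseline + shift (for planted proteins under the second
    condition) + technical noise with SD ``duplicate_cv`` on the log2 scale.
    The second condition's planted proteins move by ``shift`` log2 units,
    half up, half down.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteins = [f"prot{j + 1:04d}" for j in range(spec.n_proteins)]
    diff_idx = rng.choice(spec.n_proteins, size=spec.n_diff, replace=False)
    signs = np.where(np.arange(spec.n_diff) % 2 == 0, 1.0, -1.0)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)
    arrays, labels = [], []
    for ci, cond in enumerate(spec.conditions):
        log2 = baseline.copy()
        if ci == 1:
            log2[diff_idx] += signs * spec.shift
        for rep in (1, 2):
            noise = (rng.normal(0.0, spec.duplicate_cv, spec.n_proteins)
                     if spec.duplicate_cv > 0 else 0.0)
            arrays.append(2.0 ** (log2 + noise))
            labels.append((f"{cond}_rep{rep}", cond, rep))
    sample_ids = [lab[0] for lab in labels]
    matrix = pd.DataFrame(np.column_stack(arrays).T,
                          index=pd.Index(sample_ids, name="sample"),
                          columns=proteins)
    design = pd.DataFrame(
        {"condition": [lab[1] for lab in labels],
         "replicate": [lab[2] for lab in labels]},
        index=pd.Index(sample_ids, name="sample"))
    truth = {proteins[j] for j in diff_idx}
    return matrix, design, truth


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

@dataclass
class NetSimSpec:
    """Parameters of the interactome generator.

    ``model`` picks the background topology: "scale-free" (Barabási–Albert
    preferential attachment) or "erdos-renyi".  A module of
    ``module_size`` nodes is planted at internal edge density
    ``module_density``; ``probe_size`` of its nodes form the probe set.
    """

    n_nodes: int = 200
    model: str = "scale-free"
    attach_m: int = 2
    er_p: float = 0.02
    module_size: int = 6
    module_density: float = 1.0
    probe_size: int = 3
    directed_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.module_size > self.n_nodes:
            raise ValueError("planted module larger than the graph")
        if not 0 < self.module_density <= 1:
            raise ValueError("module_density must be in (0, 1]")
        if self.probe_size > self.module_size:
            raise ValueError("probe_size must be <= module_size")
        if not 0 <= self.directed_fraction <= 1:
            raise ValueError("directed_fraction must be in [0, 1]")
        if self.model not in {"scale-free", "erdos-renyi"}:
            raise ValueError(f"unknown model {self.model!r}")


def simulate_interactome(
    spec: NetSimSpec,
) -> tuple[nx.Graph, set[str], set[str]]:
    """Generate (graph, probe set, planted-module node set).

    The graph is simple and undirected; edges carry a ``direction`` attribute
    ("AB", "BA" or "none") with ``directed_fraction`` of edges annotated.
    Probe nodes are placed inside the planted module.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx_seed = int(rng.integers(2**31))
    if spec.model == "scale-free":
        g0 = nx.barabasi_albert_graph(spec.n_nodes, spec.attach_m, seed=nx_seed)
    else:
        g0 = nx.gnp_random_graph(spec.n_nodes, spec.er_p, seed=nx_seed)

    names = {i: f"n{i + 1:04d}" for i in range(spec.n_nodes)}
    g = nx.relabel_nodes(g0, names)

    module_idx = rng.choice(spec.n_nodes, size=spec.module_size, replace=False)
    module = {names[i] for i in module_idx}
    pairs = [(names[a], names[b])
             for k, a in enumerate(module_idx) for b in module_idx[k + 1:]]
    n_possible = len(pairs)
    n_internal = int(round(spec.module_density * n_possible))
    chosen = rng.choice(n_possible, size=n_internal, replace=False)
    for idx in chosen:
        g.add_edge(*pairs[idx])

    g.remove_edges_from(nx.selfloop_edges(g))

    edges = sorted(tuple(sorted(e)) for e in g.edges())
    n_dir = int(round(spec.directed_fraction * len(edges)))
    dir_idx = set(rng.choice(len(edges), size=n_dir, replace=False).tolist())
    for k, (a, b) in enumerate(edges):
        if k in dir_idx:
            g.edges[a, b]["direction"] = "AB" if rng.random() < 0.5 else "BA"
        else:
            g.edges[a, b]["direction"] = "none"

    probe_idx = rng.choice(spec.module_size, size=spec.probe_size, replace=False)
    probe = {names[module_idx[i]] for i in probe_idx}
    return g, probe, module


# ---------------------------------------------------------------------------
# pathway membership for simulated features
# ---------------------------------------------------------------------------

def simulate_pathways(features: list[str], n_pathways: int, set_size: int,
                      seed: int = 0,
                      planted: dict[str, list[str]] | None = None,
                      ) -> dict[str, list[str]]:
    """Random gene sets over ``features``, plus optional planted sets.

    Used to exercise the enrichment stage with a known-null or known-hit
    pathway structure.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for k in range(n_pathways):
        members = rng.choice(len(features), size=min(set_size, len(features)),
                             replace=False)
        sets[f"pw{k + 1:03d}"] = [features[j] for j in sorted(members)]
    for name, members in (planted or {}).items():
        sets[name] = list(members)
    return sets
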