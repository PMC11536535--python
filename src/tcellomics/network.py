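"""Topological interactome reduction.

The reduction cascade compiles one or more protein–protein interaction edge
lists into a single simple undirected graph (IDs normalized, duplicates and
self-loops removed), expands a probe set to its first-neighbors induced
subgraph, scores every node with four centrality indexes plus heat
diffusion, keeps nodes at or above half the average index, restricts to
direction-annotated edges to obtain a directed signalling subnetwork, and
finally extracts densely interconnected modules with MCODE.

Centrality definitions (hop-count distances, disconnected pairs excluded):

* degree — number of incident edges;
* betweenness — unnormalized shortest-path betweenness;
* centroid — min over other nodes w of gamma_v(w) - gamma_w(v), where
  gamma_v(w) counts nodes strictly closer to v than to w (the Centiscape
  index: positive for nodes nearer the topological center);
* bridging — betweenness times the bridging coefficient
  (1/deg(v)) / sum over neighbours u of 1/deg(u) (Hwang's formulation,
  highlighting bottlenecks between modules);
* heat — entry of expm(-t L) s for the combinatorial Laplacian L and a
  seed-indicator vector s (network propagation from the probe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

logger = logging.getLogger(__name__)

CENTRALITY_NAMES = ("degree", "betweenness", "centroid", "bridging", "heat")
DEFAULT_THRESHOLD_INDEXES = ("degree", "betweenness", "centroid", "bridging")


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def compile_interactome(edge_lists: list[pd.DataFrame],
                        id_map: dict[str, str] | None = None,
                        allow_unmapped: bool = True,
                        sources: list[str] | None = None) -> nx.Graph:
    """Merge edge lists into one simple undirected graph.

    IDs are translated through ``id_map`` (pass-through for unlisted IDs
    when ``allow_unmapped``); undirected duplicates are collapsed to one
    edge, self-loops dropped.  Direction annotations are kept on the edge
    (an edge annotated in both orientations across sources becomes
    ``both``); provenance tags accumulate per edge.
    """
    id_map = id_map or {}
    g = nx.Graph()
    n_dup = n_self = 0
    for si, edges in enumerate(edge_lists):
        tag = (sources[si] if sources else f"source{si + 1}")
        for _, row in edges.iterrows():
            a, b = str(row["nodeA"]), str(row["nodeB"])
            if not allow_unmapped:
                stray = [x for x in (a, b) if x not in id_map]
                if stray:
                    raise ValueError(f"unmapped IDs without pass-through: {stray}")
            a, b = id_map.get(a, a), id_map.get(b, b)
            if a == b:
                n_self += 1
                continue
            direction = row.get("direction", "none") or "none"
            # direction is stored relative to the sorted endpoint order
            u, v = sorted((a, b))
            if direction in ("AB", "BA") and (u, v) != (a, b):
                direction = "BA" if direction == "AB" else "AB"
            if g.has_edge(u, v):
                n_dup += 1
                prev = g.edges[u, v]["direction"]
                if prev != direction and "none" not in (prev, direction):
                    g.edges[u, v]["direction"] = "both"
                elif prev == "none":
                    g.edges[u, v]["direction"] = direction
                g.edges[u, v]["sources"].add(tag)
            else:
                g.add_edge(u, v, direction=direction, sources={tag})
    logger.info("compiled interactome: %d nodes, %d edges "
                "(%d duplicates, %d self-loops dropped)",
                g.number_of_nodes(), g.number_of_edges(), n_dup, n_self)
    return g


def first_neighbors(g: nx.Graph, probe: set[str]) -> nx.Graph:
    """Induced subgraph on the probe plus its direct interactors."""
    present = probe & set(g.nodes)
    missing = probe - present
    if missing:
        logger.warning("probe members absent from the graph: %s",
                       sorted(missing))
    if not present:
        raise ValueError("no probe member is present in the graph")
    nodes = set(present)
    for v in present:
        nodes.update(g.neighbors(v))
    return g.subgraph(nodes).copy()


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

@dataclass
class CentralityProfile:
    """Per-node centrality vectors as a nodes x indexes frame."""

    table: pd.DataFrame          # columns: degree, betweenness, centroid,
                                 # bridging, heat
    isolated: list[str]


def _centroid_values(g: nx.Graph) -> dict:
    """Centroid via all-pairs BFS closer-node counts.

    gamma_v(w) counts third nodes u reachable from both v and w with
    d(v,u) < d(w,u); unreachable pairs contribute nothing.  The minimum of
    gamma_v(w) - gamma_w(v) over all other nodes w is taken over the whole
    graph, so on disconnected graphs cross-component pairs contribute 0.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    for v in nodes:
        for w, d in nx.single_source_shortest_path_length(g, v).items():
            dist[idx[v], idx[w]] = d
    centroid = {}
    for i, v in enumerate(nodes):
        best = np.inf
        for j, w in enumerate(nodes):
            if i == j:
                continue
            reach = np.isfinite(dist[i]) & np.isfinite(dist[j])
            reach[i] = reach[j] = False
            gamma_vw = int(np.sum(dist[i][reach] < dist[j][reach]))
            gamma_wv = int(np.sum(dist[j][reach] < dist[i][reach]))
            best = min(best, gamma_vw - gamma_wv)
        centroid[v] = float(best) if np.isfinite(best) else 0.0
    return centroid


def _bridging_values(g: nx.Graph, betweenness: dict) -> tuple[dict, list]:
    bridging, isolated = {}, []
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0:
            bridging[v] = 0.0
            isolated.append(v)
            continue
        denom = sum(1.0 / g.degree(u) for u in g.neighbors(v))
        coef = (1.0 / deg) / denom if denom > 0 else 0.0
        bridging[v] = betweenness[v] * coef
    return bridging, isolated


def heat_diffusion(g: nx.Graph, seeds: set[str], t: float = 0.1) -> dict:
    """Heat after time t from the seed indicator: h = expm(-t L) s."""
    nodes = list(g.nodes)
    L = nx.laplacian_matrix(g, nodelist=nodes).toarray().astype(float)
    s = np.array([1.0 if v in seeds else 0.0 for v in nodes])
    h = expm(-t * L) @ s
    return dict(zip(nodes, np.maximum(h, 0.0)))


def compute_centralities(g: nx.Graph, heat_seeds: set[str] | None = None,
                         heat_time: float = 0.1) -> CentralityProfile:
    """All five node scores; disconnected graphs are scored per component.

    Betweenness and centroid are computed within each connected component
    (paths cannot cross components); heat diffusion uses the full Laplacian,
    which is block-diagonal over components anyway.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        logger.warning("graph is disconnected (%d components); centralities "
                       "computed per component",
                       nx.number_connected_components(g))
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    centroid = (_centroid_values(g) if g.number_of_nodes() > 1
                else {next(iter(g.nodes)): 0.0})
    bridging, isolated = _bridging_values(g, betweenness)
    heat = heat_diffusion(g, heat_seeds or set(), t=heat_time)
    table = pd.DataFrame({
        "degree": degree, "betweenness": betweenness, "centroid": centroid,
        "bridging": bridging, "heat": heat,
    }).loc[sorted(g.nodes)]
    table.index.name = "node"
    return CentralityProfile(table=table, isolated=sorted(isolated))


# ---------------------------------------------------------------------------
# threshold + directed extraction
# ---------------------------------------------------------------------------

def threshold_directed_subnetwork(g: nx.Graph, profile: CentralityProfile,
                                  fraction: float = 0.5, mode: str = "all",
                                  indexes: tuple[str, ...] =
                                  DEFAULT_THRESHOLD_INDEXES,
                                  ) -> tuple[nx.Graph, nx.DiGraph]:
    """Keep high-centrality nodes, then restrict to directed edges.

    A node survives when its index value is >= ``fraction`` times that
    index's mean over all nodes — for every index (``mode="all"``) or for at
    least one (``mode="any"``).  The survivors' induced subgraph is then
    restricted to edges carrying a direction annotation, yielding a directed
    graph (``both`` produces two arcs).

    Returns (undirected thresholded subgraph, directed restriction).
    """
    if mode not in {"all", "any"}:
        raise ValueError("mode must be 'all' or 'any'")
    missing = [v for v in g.nodes if v not in profile.table.index]
    if missing:
        raise ValueError(f"profile does not cover nodes: {missing[:5]}")
    tab = profile.table.loc[list(g.nodes), list(indexes)]
    means = tab.mean(axis=0)
    ok = tab.ge(fraction * means, axis=1)
    keep = ok.all(axis=1) if mode == "all" else ok.any(axis=1)
    survivors = keep.index[keep].tolist()
    if not survivors:
        raise ValueError("no node survives the threshold; relax `fraction` "
                         "or use mode='any'")
    sub = g.subgraph(survivors).copy()

    directed = nx.DiGraph()
    directed.add_nodes_from(sub.nodes)
    for u, v, data in sub.edges(data=True):
        a, b = sorted((u, v))
        d = data.get("direction", "none")
        if d in ("AB", "both"):
            directed.add_edge(a, b)
        if d in ("BA", "both"):
            directed.add_edge(b, a)
    directed.remove_nodes_from([v for v in list(directed.nodes)
                                if directed.degree(v) == 0])
    return sub, directed


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass
class NetworkModule:
    members: list[str]
    edges: list[tuple[str, str]]
    score: float
    seed: str

    @property
    def density(self) -> float:
        n = len(self.members)
        return 2 * len(self.edges) / (n * (n - 1)) if n > 1 else 0.0


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 2 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0


def _core_clustering_weight(g: nx.Graph, v, degree_cut: int) -> float:
    """MCODE vertex weight: highest-k-core k of the closed neighborhood
    times that k-core's density."""
    if g.degree(v) < degree_cut:
        return 0.0
    nbhd = set(g.neighbors(v)) | {v}
    sub = g.subgraph(nbhd)
    core_nums = nx.core_number(sub)
    kmax = max(core_nums.values())
    core = sub.subgraph([u for u, k in core_nums.items() if k >= kmax])
    return kmax * _density(core)


def mcode_modules(g: nx.Graph, vwp: float = 0.2, degree_cut: int = 2,
                  haircut: bool = True, fluff: bool = False,
                  ) -> list[NetworkModule]:
    """Molecular-complex detection on a simple graph.

    Each vertex is weighted by the core-clustering coefficient of its closed
    neighborhood; complexes grow outward from the highest-weight unvisited
    seed, admitting neighbours whose weight is at least ``(1 - vwp)`` times
    the seed weight.  Modules are node-disjoint; the haircut removes
    singly-connected members (iterated to the module's 2-core); modules are
    ranked by score = density x size.  Determinism: weight ties break on
    lexicographic node ID.  ``fluff`` is accepted for interface parity but
    not applied (kept off in this pipeline).
    """
    if isinstance(g, nx.DiGraph):
        g = g.to_undirected()
    weights = {v: _core_clustering_weight(g, v, degree_cut) for v in g.nodes}
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[NetworkModule] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(g.neighbors(v), key=str):
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        visited.add(u)
                        nxt.append(u)
            frontier = nxt
        sub = g.subgraph(members).copy()
        if haircut and sub.number_of_nodes() > 2:
            core = nx.k_core(sub, 2)
            if core.number_of_nodes() >= 2 and seed in core:
                sub = core
            elif core.number_of_nodes() >= 2:
                sub = core  # seed trimmed off a tree-like fringe
        if sub.number_of_nodes() < 2 or not nx.is_connected(sub):
            comps = sorted(nx.connected_components(sub), key=len, reverse=True)
            if not comps or len(comps[0]) < 2:
                continue
            sub = sub.subgraph(comps[0]).copy()
        score = _density(sub) * sub.number_of_nodes()
        if score <= 0:
            continue
        modules.append(NetworkModule(
            members=sorted(sub.nodes, key=str),
            edges=sorted((tuple(sorted(e, key=str)) for e in sub.edges),
                         key=lambda e: (str(e[0]), str(e[1]))),
            score=float(score), seed=seed))
    modules.sort(key=lambda m: (-m.score, [str(x) for x in m.members]))
    return modules
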