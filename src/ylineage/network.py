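"""Median-joining networks, founder selection, and rho-based TMRCA dating.

The network links observed Y-STR haplotypes (and inferred median vectors)
under the weighted stepwise distance ``d(x, y) = sum_l w_l |x_l - y_l|``.
Construction follows the median-joining scheme: build the epsilon-relaxed
minimum-spanning network, add per-locus median vectors of mutually connected
triples whenever they shorten the total connection cost, iterate to a
fixpoint, then discard median vectors of degree < 3. Tie-breaking is
lexicographic on haplotype vectors so the result is independent of input
order.

The rho statistic is the mean number of (unweighted) one-repeat mutational
steps from each sampled chromosome to the founder node; its standard error
follows the hierarchical branch formula sigma^2 = sum_branches n_b^2 / n^2
with one branch term per mutational step and ``n_b`` the number of sampled
chromosomes descending through that step. rho converts to years as
``T = rho * generation_time / (n_loci * rate)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as _sstats

from .diversity import analysis_matrix
from .types import STRHaplotype

__all__ = [
    "LocusWeights",
    "RhoEstimate",
    "TmrcaEstimate",
    "EVOLUTIONARY_RATE",
    "locus_weights",
    "build_mj_network",
    "select_founder",
    "rho_statistic",
    "tmrca_from_rho",
    "write_graphml",
]

#: Zhivotovsky's "evolutionary" Y-STR mutation rate, per locus per 25-year
#: generation, calibrated on population divergences rather than pedigrees.
EVOLUTIONARY_RATE = 6.9e-4


@dataclass(frozen=True)
class LocusWeights:
    """Integer locus weights in [1, 5]; high weight = low-variance locus."""

    weights: Mapping[str, int]

    def __post_init__(self):
        bad = {l: w for l, w in self.weights.items() if not (1 <= int(w) <= 5)}
        if bad:
            raise ValueError(f"weights must be integers in [1, 5]: {bad}")
        object.__setattr__(self, "weights", dict(self.weights))

    def vector(self, loci: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[l] for l in loci], dtype=float)


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sigma: float
    n: int
    founder: STRHaplotype


@dataclass(frozen=True)
class TmrcaEstimate:
    years: float
    se_years: float
    rate: float
    gen_years: float
    n_loci: int


def locus_weights(haps: Sequence[STRHaplotype], loci: Sequence[str]) -> LocusWeights:
    """Weights 1-5 from the inverse variance of each locus.

    Loci are ranked by inverse allele-size variance (average ranks for ties)
    and the ranks mapped onto five equal quantile bins: the most variable
    locus gets weight 1, the least variable weight 5. Invariant loci get 5.
    """
    X = analysis_matrix(haps, loci)
    if X.shape[0] < 2:
        raise ValueError("need at least two haplotypes")
    var = X.var(axis=0, ddof=1)
    weights = {}
    variable = var > 0
    if variable.any():
        iv = 1.0 / var[variable]
        ranks = _sstats.rankdata(iv, method="average")
        w = np.ceil(5.0 * ranks / len(iv)).astype(int)
        w = np.clip(w, 1, 5)
        for l, wi in zip(np.array(loci)[variable], w):
            weights[str(l)] = int(wi)
    for l in np.array(loci)[~variable]:
        weights[str(l)] = 5
    return LocusWeights({l: weights[l] for l in loci})


# -- internal helpers on integer haplotype tuples ---------------------------

def _as_tuples(haps: Sequence[STRHaplotype], loci: Sequence[str]) -> list[tuple[int, ...]]:
    out = []
    for h in haps:
        vec = h.vector(loci)
        if any(isinstance(v, Fraction) and v.denominator != 1 for v in vec):
            raise ValueError("median-joining networks require integer repeat counts")
        out.append(tuple(int(v) for v in vec))
    return out


def _wdist(a: tuple, b: tuple, w: np.ndarray) -> float:
    return float(sum(wi * abs(x - y) for wi, x, y in zip(w, a, b)))


def _steps(a: tuple, b: tuple) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def _msn_edges(nodes: list[tuple], w: np.ndarray, eps: float) -> list[tuple]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge is kept iff its weighted length is within ``eps`` of the
    threshold at which its two endpoints' components merge under Kruskal.
    """
    n = len(nodes)
    edges = sorted(
        ((_wdist(nodes[i], nodes[j], w), i, j) for i in range(n) for j in range(i + 1, n))
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # Kruskal by weight class to find each pair's merge threshold
    merge_at = {}
    k = 0
    while k < len(edges):
        wclass = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] == wclass:
            cls.append(edges[k])
            k += 1
        before = {i: find(i) for i in range(n)}
        joined = False
        for _, i, j in cls:
            if before[i] != before[j]:
                parent[find(i)] = find(j)
                joined = True
        if joined:
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) not in merge_at and find(i) == find(j):
                        merge_at[(i, j)] = wclass
    kept = [(d, i, j) for d, i, j in edges if d <= merge_at[(i, j) if i < j else (j, i)] + eps]
    return kept


def _mst_cost(nodes: list[tuple], w: np.ndarray) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    # Prim's algorithm on the complete weighted graph
    in_tree = [False] * n
    best = [math.inf] * n
    best[0] = 0.0
    total = 0.0
    for _ in range(n):
        u = min((b, i) for i, b in enumerate(best) if not in_tree[i])[1]
        in_tree[u] = True
        total += best[u]
        for v in range(n):
            if not in_tree[v]:
                d = _wdist(nodes[u], nodes[v], w)
                if d < best[v]:
                    best[v] = d
    return total


def _median_vector(a: tuple, b: tuple, c: tuple) -> tuple:
    return tuple(int(np.median([x, y, z])) for x, y, z in zip(a, b, c))


def build_mj_network(
    haps: Sequence[STRHaplotype],
    weights: LocusWeights | None = None,
    loci: Sequence[str] | None = None,
    epsilon: float = 0.0,
) -> nx.Graph:
    """Build the median-joining network of the given haplotypes.

    Returns a connected :class:`networkx.Graph`. Node keys are integer
    allele tuples over ``loci``; node attributes: ``multiplicity`` (0 for
    median vectors), ``is_median``, ``loci``. Edge attributes: ``weight``
    (weighted length), ``steps`` (unweighted one-repeat steps).
    """
    if loci is None:
        first = haps[0]
        loci = tuple(l for l in first.alleles)
    loci = tuple(loci)
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes")
    if weights is None:
        weights = LocusWeights({l: 1 for l in loci})
    w = weights.vector(loci)

    tuples = _as_tuples(haps, loci)
    mult: dict[tuple, int] = {}
    for t in tuples:
        mult[t] = mult.get(t, 0) + 1
    observed = sorted(mult)
    nodes = list(observed)

    # iterate: add cost-reducing median vectors of connected triples
    while True:
        node_index = {t: i for i, t in enumerate(nodes)}
        edges = _msn_edges(nodes, w, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(nodes)))
        g.add_edges_from((i, j) for _, i, j in edges)
        base_cost = _mst_cost(nodes, w)
        candidates = set()
        for tri in _triangles(g):
            m = _median_vector(*(nodes[i] for i in tri))
            if m not in node_index:
                candidates.add(m)
        best = None
        for m in sorted(candidates):
            cost = _mst_cost(nodes + [m], w)
            gain = base_cost - cost
            if gain > 1e-9 and (best is None or gain > best[0] + 1e-9):
                best = (gain, m)
        if best is None:
            break
        nodes.append(best[1])
        nodes.sort()

    # final network; prune median vectors of degree < 3
    while True:
        edges = _msn_edges(nodes, w, epsilon)
        deg = {i: 0 for i in range(len(nodes))}
        for _, i, j in edges:
            deg[i] += 1
            deg[j] += 1
        removable = [
            nodes[i]
            for i in range(len(nodes))
            if nodes[i] not in mult and deg[i] < 3
        ]
        if not removable:
            break
        nodes = [t for t in nodes if t not in set(removable)]

    net = nx.Graph(loci=list(loci))
    for t in nodes:
        net.add_node(t, multiplicity=mult.get(t, 0), is_median=t not in mult)
    for d, i, j in edges:
        net.add_edge(nodes[i], nodes[j], weight=d, steps=_steps(nodes[i], nodes[j]))
    return net


def _triangles(g: nx.Graph):
    for u, v in g.edges():
        for x in sorted(set(g[u]) & set(g[v])):
            tri = tuple(sorted((u, v, x)))
            yield tri


def select_founder(
    haps: Sequence[STRHaplotype],
    network: nx.Graph,
    loci: Sequence[str] | None = None,
    override: STRHaplotype | None = None,
) -> tuple[int, ...]:
    """Founder node: the modal observed haplotype; ties broken by maximal
    network degree, then lexicographically. ``override`` forces a haplotype
    (must be a network node)."""
    loci = tuple(loci or network.graph["loci"])
    if override is not None:
        t = tuple(int(v) for v in override.vector(loci))
        if t not in network:
            raise ValueError("override founder is not a network node")
        return t
    tuples = _as_tuples(haps, loci)
    mult: dict[tuple, int] = {}
    for t in tuples:
        mult[t] = mult.get(t, 0) + 1
    return min(mult, key=lambda t: (-mult[t], -network.degree(t), t))


def rho_statistic(
    haps: Sequence[STRHaplotype],
    founder: STRHaplotype | tuple,
    network: nx.Graph | None = None,
    loci: Sequence[str] | None = None,
) -> RhoEstimate:
    """rho and sigma of the sampled haplotypes relative to the founder.

    With a network, steps are shortest-path mutational steps through the
    network and sigma^2 sums ``steps_e * n_e^2`` over the edges of the
    shortest-path tree rooted at the founder (n_e = sampled chromosomes below
    the edge). Without a network, steps are direct stepwise distances and
    chromosomes sharing a haplotype share their branch (exact whenever the
    network would be a homoplasy-free tree, e.g. star genealogies).
    """
    if loci is None:
        loci = tuple(network.graph["loci"]) if network is not None else tuple(haps[0].alleles)
    loci = tuple(loci)
    f = tuple(int(v) for v in founder.vector(loci)) if isinstance(founder, STRHaplotype) else tuple(founder)
    tuples = _as_tuples(haps, loci)
    n = len(tuples)
    mult: dict[tuple, int] = {}
    for t in tuples:
        mult[t] = mult.get(t, 0) + 1

    founder_h = STRHaplotype(dict(zip(loci, f)))
    if network is None:
        total = sum(_steps(t, f) * m for t, m in mult.items())
        var = sum(_steps(t, f) * m * m for t, m in mult.items() if t != f) / (n * n)
        return RhoEstimate(rho=total / n, sigma=math.sqrt(var), n=n, founder=founder_h)

    if f not in network:
        raise ValueError("founder is not a node of the network")
    # deterministic shortest paths by mutational steps
    dist, paths = nx.single_source_dijkstra(network, f, weight="steps")
    missing = [t for t in mult if t not in dist]
    if missing:
        raise ValueError("network does not connect all haplotypes to the founder")
    total = sum(dist[t] * m for t, m in mult.items())
    # shortest-path tree: count sampled chromosomes through each tree edge
    carried: dict[tuple, int] = {}
    for t, m in mult.items():
        path = paths[t]
        for a, b in zip(path[:-1], path[1:]):
            key = (a, b)
            carried[key] = carried.get(key, 0) + m
    var = sum(
        network.edges[a, b]["steps"] * m * m for (a, b), m in carried.items()
    ) / (n * n)
    return RhoEstimate(rho=total / n, sigma=math.sqrt(var), n=n, founder=founder_h)


def tmrca_from_rho(
    r: RhoEstimate | float,
    rate: float = EVOLUTIONARY_RATE,
    gen_years: float = 25.0,
    n_loci: int = 15,
    sigma: float | None = None,
) -> TmrcaEstimate:
    """Convert rho to calendar years: ``T = rho * gen_years / (n_loci * rate)``.

    One mutation anywhere in the panel accumulates at rate ``n_loci * rate``
    per generation, so rho mutations correspond to ``rho / (n_loci * rate)``
    generations. The standard error scales identically from sigma.
    """
    if rate <= 0 or n_loci <= 0 or gen_years <= 0:
        raise ValueError("rate, gen_years and n_loci must be positive")
    if isinstance(r, RhoEstimate):
        rho, sig = r.rho, r.sigma
    else:
        rho, sig = float(r), float(sigma or 0.0)
    if rho < 0:
        raise ValueError("rho must be non-negative")
    scale = gen_years / (n_loci * rate)
    return TmrcaEstimate(
        years=rho * scale, se_years=sig * scale,
        rate=rate, gen_years=gen_years, n_loci=n_loci,
    )


def write_graphml(network: nx.Graph, path) -> None:
    """Write the network as GraphML (nodes keyed by haplotype string)."""
    g = nx.Graph()
    loci = network.graph["loci"]
    g.graph["loci"] = ",".join(loci)
    for t, data in network.nodes(data=True):
        g.add_node("-".join(map(str, t)),
                   multiplicity=int(data["multiplicity"]),
                   is_median=bool(data["is_median"]))
    for a, b, data in network.edges(data=True):
        g.add_edge("-".join(map(str, a)), "-".join(map(str, b)),
                   weight=float(data["weight"]), steps=int(data["steps"]))
    nx.write_graphml(g, path)
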