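"""Semantic network estimation from fluency lists.

A semantic network is an undirected, unweighted graph over response
labels, stored as a symmetric binary adjacency relation with no
self-edges.  Five estimators are provided:

* **First Edge** — connect the first two responses of every list.
* **Naive Random Walk** — connect every pair of adjacent responses.
* **Pathfinder** — measure a pairwise proximity (mean absolute positional
  lag across co-listings) and keep exactly the edges that lie in at least
  one minimum spanning tree of each finite-distance component (the union
  of all MSTs, the sparsest classical Pathfinder parameterization).
* **Correlation-based** — threshold the product-moment correlation of
  per-list presence/absence vectors.
* **Conceptual network** — keep pairs that co-occur within a positional
  window significantly more often than expected if each list's order were
  random, via an exact Poisson-binomial upper tail.

plus **U-INVITE**, which searches for the network maximizing the exact
censored-random-walk likelihood of the observed lists (see
:mod:`fluencynet.walk`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fluency_io import FluencyDataset, Scheme

__all__ = [
    "SemanticNetwork",
    "DistanceMatrix",
    "NetworkStats",
    "estimate_first_edge",
    "estimate_naive_random_walk",
    "pathfinder_distances",
    "pathfinder_union_mst",
    "estimate_pathfinder",
    "estimate_correlation_network",
    "estimate_conceptual_network",
    "estimate_uinvite",
    "network_statistics",
    "category_edge_matrix",
    "export_edge_list",
    "import_edge_list",
    "ESTIMATORS",
]


@dataclass(frozen=True)
class SemanticNetwork:
    """Undirected unweighted graph over item labels.

    Equivalent to a symmetric 0/1 adjacency matrix with zero diagonal.
    Immutable; :meth:`toggle_edge` returns a modified copy.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        nodeset = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if not e <= nodeset:
                raise ValueError(f"edge endpoints {set(e)} not all in node set")

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "SemanticNetwork":
        return cls(
            nodes=tuple(sorted(set(nodes))),
            edges=frozenset(frozenset(e) for e in edges if e[0] != e[1]),
        )

    @cached_property
    def _adj(self) -> dict[str, tuple[str, ...]]:
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].append(v)
            adj[v].append(u)
        return {n: tuple(sorted(vs)) for n, vs in adj.items()}

    def neighbors(self, node: str) -> tuple[str, ...]:
        return self._adj[node]

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def toggle_edge(self, u: str, v: str) -> "SemanticNetwork":
        if u == v:
            raise ValueError("cannot toggle a self-edge")
        e = frozenset((u, v))
        edges = self.edges - {e} if e in self.edges else self.edges | {e}
        return SemanticNetwork(nodes=self.nodes, edges=edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def adjacency_dataframe(self) -> pd.DataFrame:
        """Square symmetric 0/1 matrix with node-label index and columns."""
        n = len(self.nodes)
        idx = {v: i for i, v in enumerate(self.nodes)}
        m = np.zeros((n, n), dtype=int)
        for e in self.edges:
            u, v = tuple(e)
            m[idx[u], idx[v]] = m[idx[v], idx[u]] = 1
        return pd.DataFrame(m, index=list(self.nodes), columns=list(self.nodes))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances; infinite where a pair never co-occurs."""

    nodes: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def value(self, u: str, v: str) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.d[i, j])


def _all_tokens(dataset: FluencyDataset) -> tuple[str, ...]:
    return tuple(sorted(dataset.item_index))


def estimate_first_edge(dataset: FluencyDataset) -> SemanticNetwork:
    """Connect the first two responses of each list; all tokens are nodes."""
    edges = [
        (fl.tokens[0], fl.tokens[1]) for fl in dataset.lists if len(fl.tokens) >= 2
    ]
    return SemanticNetwork.from_edges(_all_tokens(dataset), edges)


def estimate_naive_random_walk(dataset: FluencyDataset) -> SemanticNetwork:
    """Connect every pair of adjacent responses within each list."""
    edges = []
    for fl in dataset.lists:
        edges.extend(zip(fl.tokens, fl.tokens[1:]))
    return SemanticNetwork.from_edges(_all_tokens(dataset), edges)


def pathfinder_distances(dataset: FluencyDataset) -> DistanceMatrix:
    """Mean absolute positional lag between first occurrences, across the
    lists containing both items; infinite for pairs never co-listed."""
    nodes = _all_tokens(dataset)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    tot = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for fl in dataset.lists:
        pos: dict[str, int] = {}
        for p, t in enumerate(fl.tokens):
            pos.setdefault(t, p)
        items = list(pos)
        for a, b in itertools.combinations(items, 2):
            i, j = idx[a], idx[b]
            lag = abs(pos[a] - pos[b])
            tot[i, j] += lag
            tot[j, i] += lag
            cnt[i, j] += 1
            cnt[j, i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.inf)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(nodes=nodes, d=d)


def pathfinder_union_mst(dm: DistanceMatrix) -> SemanticNetwork:
    """Union of all minimum spanning trees of each finite-distance component.

    Decided by the cycle property: an edge of weight *w* belongs to some
    MST iff its endpoints are disconnected using only edges of weight
    strictly less than *w*.  Implemented as Kruskal with tie groups over a
    union-find structure: edges of equal weight are all tested against the
    forest built from strictly lighter edges before any of them is merged.
    """
    nodes = dm.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    weighted = [
        (dm.d[idx[u], idx[v]], u, v)
        for u, v in itertools.combinations(nodes, 2)
        if math.isfinite(dm.d[idx[u], idx[v]])
    ]
    weighted.sort(key=lambda t: t[0])

    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    kept: list[tuple[str, str]] = []
    pos = 0
    while pos < len(weighted):
        w = weighted[pos][0]
        group = []
        while pos < len(weighted) and weighted[pos][0] == w:
            group.append(weighted[pos])
            pos += 1
        for _, u, v in group:
            if find(idx[u]) != find(idx[v]):
                kept.append((u, v))
        for _, u, v in group:
            ru, rv = find(idx[u]), find(idx[v])
            if ru != rv:
                parent[ru] = rv
    return SemanticNetwork.from_edges(nodes, kept)


def estimate_pathfinder(dataset: FluencyDataset) -> SemanticNetwork:
    return pathfinder_union_mst(pathfinder_distances(dataset))


def estimate_correlation_network(
    dataset: FluencyDataset, threshold: float = 0.5
) -> SemanticNetwork:
    """Threshold the correlation of per-list presence/absence profiles.

    Items occurring in every list or in none have zero variance and an
    undefined correlation; they are retained as isolated nodes with a
    warning.
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie in (-1, 1)")
    if len(dataset.lists) < 2:
        raise ValueError("correlation network requires at least 2 lists")
    nodes = _all_tokens(dataset)
    presence = np.array(
        [[1.0 if t in set(fl.tokens) else 0.0 for fl in dataset.lists] for t in nodes]
    )
    var = presence.var(axis=1)
    usable = var > 0
    if not np.all(usable):
        warnings.warn(
            "zero-variance items excluded from correlation: "
            + ", ".join(np.array(nodes)[~usable])
        )
    edges = []
    use_idx = np.flatnonzero(usable)
    if len(use_idx) >= 2:
        r = np.corrcoef(presence[use_idx])
        for a, b in itertools.combinations(range(len(use_idx)), 2):
            if r[a, b] >= threshold:
                edges.append((nodes[use_idx[a]], nodes[use_idx[b]]))
    return SemanticNetwork.from_edges(nodes, edges)


def _poisson_binomial_tail(ps: Sequence[float], c: int) -> float:
    """P(C >= c) for C a sum of independent Bernoulli(p_l), exactly."""
    dist = np.zeros(len(ps) + 1)
    dist[0] = 1.0
    for k, p in enumerate(ps):
        nxt = dist * (1.0 - p)
        nxt[1 : k + 2] += dist[: k + 1] * p
        dist = nxt
    return float(dist[c:].sum())


def estimate_conceptual_network(
    dataset: FluencyDataset, window: int = 2, alpha: float = 0.05
) -> SemanticNetwork:
    """Significant window co-occurrence network.

    A pair co-occurs in a list when the first occurrences of both items
    lie within ``window`` positions of each other (counted at most once
    per list).  Under the null that each list of length *m* is a uniformly
    random ordering, the per-list co-occurrence probability is
    ``p = w(2m - w - 1) / (m(m - 1))`` with ``w = window``.  An edge is
    placed when the exact upper tail P(C >= observed) of the
    Poisson-binomial count over the lists containing both items falls
    below ``alpha``.  No multiple-comparison correction is applied.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    nodes = _all_tokens(dataset)
    longest = max((len(fl.tokens) for fl in dataset.lists), default=0)
    if longest and window >= longest - 1:
        warnings.warn(
            f"window {window} spans the longest list (length {longest}); "
            "co-occurrence is uninformative for short lists"
        )
    # per-pair: observed co-occurrence count and null probabilities per list
    obs: dict[frozenset, int] = {}
    ps: dict[frozenset, list[float]] = {}
    for fl in dataset.lists:
        pos: dict[str, int] = {}
        for p, t in enumerate(fl.tokens):
            pos.setdefault(t, p)
        m = len(fl.tokens)
        if m < 2:
            continue
        w = min(window, m - 1)
        p_l = w * (2 * m - w - 1) / (m * (m - 1))
        for a, b in itertools.combinations(pos, 2):
            key = frozenset((a, b))
            ps.setdefault(key, []).append(p_l)
            if abs(pos[a] - pos[b]) <= window:
                obs[key] = obs.get(key, 0) + 1
    edges = []
    for key, trials in ps.items():
        c = obs.get(key, 0)
        if c >= 1 and _poisson_binomial_tail(trials, c) < alpha:
            edges.append(tuple(sorted(key)))
    return SemanticNetwork.from_edges(nodes, edges)


def estimate_uinvite(
    dataset: FluencyDataset,
    prior_edge_probability: float = 0.5,
    max_passes: int = 20,
    seed: int = 0,
    return_trace: bool = False,
) -> "SemanticNetwork | tuple[SemanticNetwork, list[float]]":
    """Maximum a posteriori network under the censored-random-walk model.

    The walk model (see :mod:`fluencynet.walk`) treats each list as the
    first-visit record of a random walk on the latent network; this
    searches for the network maximizing the exact data log-likelihood plus
    an independent-Bernoulli edge prior.  With the default flat prior
    (``prior_edge_probability = 0.5``) the fit is pure maximum likelihood.

    Search is greedy coordinate ascent: starting from the naive-random-walk
    network (which always has positive likelihood for its own data), node
    pairs are swept in seeded random order and an edge is toggled whenever
    the toggle strictly increases the objective; the search stops after a
    sweep with no accepted toggle or after ``max_passes`` sweeps.  The
    result is a local optimum, deterministic given (dataset, seed).  With
    ``return_trace`` the objective value at the start and after each
    accepted toggle is returned alongside the network.

    Within-list repeats are not representable by a censored walk, so
    perseverations in the data are a precondition error.
    """
    from .walk import list_log_likelihood  # deferred: walk imports this module

    if not 0 < prior_edge_probability < 1:
        raise ValueError("prior_edge_probability must lie in (0, 1)")
    for fl in dataset.lists:
        if len(set(fl.tokens)) != len(fl.tokens):
            raise ValueError(
                f"perseveration in subject {fl.subject_id} list {fl.list_number}: "
                "the censored-walk model does not allow within-list repeats "
                "(load with remove_perseverations or clean the data)"
            )
        if not fl.tokens:
            raise ValueError("empty fluency list cannot be modelled")

    net = estimate_naive_random_walk(dataset)
    nodes = net.nodes
    log_t = math.log(prior_edge_probability)
    log_f = math.log(1.0 - prior_edge_probability)
    lists = [fl.tokens for fl in dataset.lists]

    def list_ll(n: SemanticNetwork, tokens: tuple[str, ...]) -> float:
        return list_log_likelihood(n, tokens).log_likelihood

    # Toggling edge (u, v) only changes the likelihood of lists containing
    # u or v: transition probabilities depend solely on edges incident to
    # already-visited (transient) states, which are list tokens.
    touching: dict[str, list[int]] = {n: [] for n in nodes}
    for i, toks in enumerate(lists):
        for t in set(toks):
            touching[t].append(i)

    per_list = [list_ll(net, toks) for toks in lists]
    score = sum(per_list) + net.n_edges * log_t + (
        len(nodes) * (len(nodes) - 1) // 2 - net.n_edges
    ) * log_f

    trace = [score]
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(nodes, 2))
    n_pairs_total = len(pairs)
    for _ in range(max_passes):
        rng.shuffle(pairs)
        improved = False
        for u, v in pairs:
            cand = net.toggle_edge(u, v)
            affected = sorted(set(touching[u]) | set(touching[v]))
            new_vals = {i: list_ll(cand, lists[i]) for i in affected}
            cand_ll = sum(per_list) + sum(
                new_vals[i] - per_list[i] for i in affected
            )
            cand_score = cand_ll + cand.n_edges * log_t + (
                n_pairs_total - cand.n_edges
            ) * log_f
            if cand_score > score:
                net = cand
                for i, val in new_vals.items():
                    per_list[i] = val
                score = cand_score
                trace.append(score)
                improved = True
        if not improved:
            break
    if return_trace:
        return net, trace
    return net


ESTIMATORS: dict[str, Callable] = {
    "first-edge": estimate_first_edge,
    "naive-random-walk": estimate_naive_random_walk,
    "pathfinder": estimate_pathfinder,
    "correlation": estimate_correlation_network,
    "conceptual": estimate_conceptual_network,
    "uinvite": estimate_uinvite,
}


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of an estimated network."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    mean_degree: float
    mean_shortest_path: float
    n_components: int
    component_sizes: tuple[int, ...]
    largest_component_size: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering_coefficient": self.clustering_coefficient,
            "mean_degree": self.mean_degree,
            "mean_shortest_path": self.mean_shortest_path,
            "n_components": self.n_components,
            "component_sizes": sorted(self.component_sizes, reverse=True),
            "largest_component_size": self.largest_component_size,
        }


def network_statistics(net: SemanticNetwork) -> NetworkStats:
    """Node/edge counts, mean local clustering, mean degree, mean shortest
    path over connected pairs of the largest component, and components.

    Nodes of degree < 2 contribute local clustering 0.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    if n == 0:
        warnings.warn("empty network: statistics are all zero")
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, 0, (), 0)
    comps = [len(c) for c in nx.connected_components(g)]
    largest = max(nx.connected_components(g), key=len)
    if len(largest) >= 2:
        mean_sp = nx.average_shortest_path_length(g.subgraph(largest))
    else:
        mean_sp = 0.0
    return NetworkStats(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        clustering_coefficient=float(nx.average_clustering(g, count_zeros=True)),
        mean_degree=2.0 * g.number_of_edges() / n,
        mean_shortest_path=float(mean_sp),
        n_components=len(comps),
        component_sizes=tuple(sorted(comps, reverse=True)),
        largest_component_size=max(comps),
    )


def category_edge_matrix(
    net: SemanticNetwork,
    scheme: Scheme | None,
    primary_label: Mapping[str, str] | Callable[[str], str],
) -> pd.DataFrame:
    """Proportion of edges between each unordered pair of categories.

    Every node must carry exactly one primary category.  The returned
    square DataFrame is symmetric; each inter-category edge contributes
    half its proportion to each of the two mirrored cells, so the total
    over the whole matrix is 1 and the diagonal sums to the intra-category
    edge fraction (the quantity usually reported alongside the heatmap).
    """
    label = primary_label if callable(primary_label) else primary_label.get
    assigned: dict[str, str] = {}
    missing = []
    for node in net.nodes:
        lab = label(node)
        if lab is None:
            missing.append(node)
        else:
            assigned[node] = lab
    if missing:
        raise ValueError("nodes without a primary category: " + ", ".join(missing))
    cats = sorted(set(assigned.values()))
    df = pd.DataFrame(0.0, index=cats, columns=cats)
    n_edges = len(net.edges)
    if n_edges == 0:
        return df
    for e in net.edges:
        u, v = tuple(e)
        cu, cv = assigned[u], assigned[v]
        if cu == cv:
            df.loc[cu, cv] += 1.0 / n_edges
        else:
            df.loc[cu, cv] += 0.5 / n_edges
            df.loc[cv, cu] += 0.5 / n_edges
    return df


def intra_category_fraction(matrix: pd.DataFrame) -> float:
    """Diagonal mass of a category edge matrix: fraction of edges whose
    endpoints share a primary category."""
    return float(np.trace(matrix.to_numpy()))


_NODES_HEADER = "# nodes"
_EDGES_HEADER = "# edges"


def export_edge_list(net: SemanticNetwork, path: str | Path) -> None:
    """Write a canonical text edge list.

    The file holds a ``# nodes`` section (one label per line, sorted, so
    isolated nodes survive the round trip) followed by a ``# edges``
    section with one edge per line, endpoints alphabetically ordered
    within the line and lines sorted.
    """
    lines = [_NODES_HEADER]
    lines.extend(net.nodes)
    lines.append(_EDGES_HEADER)
    lines.extend(sorted(",".join(sorted(e)) for e in net.edges))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def import_edge_list(path: str | Path) -> SemanticNetwork:
    """Read a network written by :func:`export_edge_list`."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    section = None
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line == _NODES_HEADER:
            section = "nodes"
            continue
        if line == _EDGES_HEADER:
            section = "edges"
            continue
        if section == "nodes":
            if "," in line:
                raise ValueError(f"{path}:{lineno}: unexpected comma in node label")
            nodes.append(line)
        elif section == "edges":
            parts = line.split(",")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
            if parts[0] not in nodes or parts[1] not in nodes:
                raise ValueError(
                    f"{path}:{lineno}: edge endpoint not in nodes section"
                )
            edges.append((parts[0], parts[1]))
        else:
            raise ValueError(f"{path}:{lineno}: content before '# nodes' header")
    return SemanticNetwork.from_edges(nodes, edges)
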