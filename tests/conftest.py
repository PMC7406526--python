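"""Shared fixtures and independent oracles.

The oracles re-derive expected values from first principles, by routes
independent of the implementation: segmentation by recursive
longest-valid-prefix splitting, Pathfinder by explicit enumeration of all
spanning trees, and censored-walk emission probabilities by dynamic
programming over (current node, emission order) states of the raw walk.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fluencynet import Scheme, SemanticNetwork


# ---------------------------------------------------------------------------
# canonical worked example: six animals over three overlapping categories

FIG1_TOKENS = ["hamster", "cat", "dog", "wolf", "coyote", "zebra"]


@pytest.fixture
def fig1_scheme() -> Scheme:
    return Scheme(
        "semantic",
        {
            "Pets": frozenset({"hamster", "cat", "dog"}),
            "Canines": frozenset({"dog", "wolf", "coyote"}),
            "ZooAnimals": frozenset({"zebra"}),
        },
    )


@pytest.fixture
def fig1_tokens() -> list[str]:
    return list(FIG1_TOKENS)


# ---------------------------------------------------------------------------
# segmentation oracle: recursive longest-valid-prefix splitting

def oracle_segment(tokens, labelsets, mode):
    """Segment by repeatedly taking the longest valid prefix.

    A prefix is valid under 'static' when all its label sets share a
    common label; under 'fluid' when every adjacent pair shares a label.
    """
    if not tokens:
        return []

    def valid(ls):
        if mode == "static":
            common = frozenset.intersection(*ls)
            return bool(common)
        return all(a & b for a, b in zip(ls, ls[1:]))

    for k in range(len(tokens), 0, -1):
        if valid(labelsets[:k]):
            return [list(tokens[:k])] + oracle_segment(
                tokens[k:], labelsets[k:], mode
            )
    raise AssertionError("single tokens are always valid prefixes")


def labelsets_for(tokens, scheme):
    """Label sets with unique sentinels for out-of-scheme tokens."""
    out = []
    for pos, t in enumerate(tokens):
        ls = scheme.labels(t)
        out.append(ls if ls else frozenset({("?", pos)}))
    return out


# ---------------------------------------------------------------------------
# Pathfinder oracle: brute-force enumeration of all spanning trees

def oracle_union_of_msts(nodes, weights):
    """Union of all minimum spanning trees by exhaustive enumeration.

    ``weights`` maps frozenset({u, v}) -> finite weight.  Assumes the
    weighted graph is connected.  Only feasible for a handful of nodes.
    """
    nodes = list(nodes)
    edges = list(weights)
    n = len(nodes)
    best = None
    trees = []
    for combo in itertools.combinations(edges, n - 1):
        adj = {v: [] for v in nodes}
        for e in combo:
            u, v = tuple(e)
            adj[u].append(v)
            adj[v].append(u)
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != n:
            continue
        cost = sum(weights[e] for e in combo)
        if best is None or cost < best - 1e-12:
            best = cost
            trees = [combo]
        elif abs(cost - best) <= 1e-12:
            trees.append(combo)
    union = set()
    for t in trees:
        union.update(t)
    return union


# ---------------------------------------------------------------------------
# censored-walk oracle: DP over (current node, emission order) states

def oracle_emission_probabilities(net: SemanticNetwork, start: str,
                                  emit_target: int, n_steps: int = 600):
    """Exact probability of each complete emission order, by forward DP.

    The raw walk is unrolled step by step; the state is (current node,
    tuple of first visits so far).  Orders that reach ``emit_target``
    emissions are moved to an absorbing bucket.  With enough steps the
    residual transient mass is negligible for small connected graphs.
    """
    state = {(start, (start,)): 1.0}
    done: dict[tuple, float] = {}
    if emit_target == 1:
        return {(start,): 1.0}
    for _ in range(n_steps):
        nxt: dict[tuple, float] = {}
        for (cur, order), p in state.items():
            nbrs = net.neighbors(cur)
            if not nbrs:
                continue
            share = p / len(nbrs)
            for v in nbrs:
                new_order = order if v in order else order + (v,)
                if len(new_order) == emit_target:
                    done[new_order] = done.get(new_order, 0.0) + share
                else:
                    key = (v, new_order)
                    nxt[key] = nxt.get(key, 0.0) + share
        state = nxt
        if not state:
            break
    residual = sum(state.values())
    assert residual < 1e-9, f"oracle did not converge; residual {residual}"
    return done


# ---------------------------------------------------------------------------
# small random graph helper

def random_connected_network(rng: np.random.Generator, n_nodes: int,
                             n_edges: int) -> SemanticNetwork:
    """Random connected graph: a random spanning tree plus extra edges."""
    names = [f"n{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    edges = set()
    for i in range(1, n_nodes):
        j = order[int(rng.integers(i))]
        edges.add(frozenset((names[order[i]], names[j])))
    all_pairs = [frozenset((a, b)) for a, b in itertools.combinations(names, 2)]
    rng.shuffle(all_pairs)
    for e in all_pairs:
        if len(edges) >= n_edges:
            break
        edges.add(e)
    return SemanticNetwork(nodes=tuple(names), edges=frozenset(edges))


def all_connected_graphs(n: int):
    """All labeled connected graphs on n nodes (small n only)."""
    names = [chr(ord("a") + i) for i in range(n)]
    pairs = list(itertools.combinations(names, 2))
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, b in zip(pairs, bits) if b]
        net = SemanticNetwork.from_edges(names, edges)
        # connectivity check
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            for v in net.neighbors(stack.pop()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) == n:
            yield net
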