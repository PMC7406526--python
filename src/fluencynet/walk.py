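"""The censored random walk model of fluency production.

A fluency list is modelled as the record of *first visits* of a random
walk on a latent semantic network: the walker starts somewhere, repeatedly
moves to a uniformly chosen neighbor, and a response is emitted only the
first time a node is visited — revisits are censored.  This module
provides the generative direction (simulating lists from a network, which
doubles as the package's synthetic-data generator) and the inferential
direction (the exact log-likelihood of observed lists given a network,
the objective maximized by U-INVITE).

The likelihood of a transition from the k-th to the (k+1)-th emitted item
is the probability that a walk started at the k-th item, free to wander
among the k already-emitted items, first leaves the visited set at exactly
the (k+1)-th item.  This is an absorbing-Markov-chain first-passage
probability: transient states are the visited items, absorbing states are
their unvisited neighbors, and the absorption probabilities solve a small
linear system.  The first item is conditioned on (contributes log 1 = 0),
keeping the objective comparable across candidate networks without
committing to a start distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fluency_io import FluencyDataset, FluencyList
from .networks import SemanticNetwork

__all__ = [
    "WalkParams",
    "LikelihoodResult",
    "simulate_censored_walk",
    "emission_distribution",
    "list_log_likelihood",
    "dataset_log_likelihood",
    "generate_synthetic_dataset",
]

_SOLVE_RTOL = 1e-10  # relative tolerance for sanity-clipping solved probabilities


@dataclass(frozen=True)
class WalkParams:
    """Parameters of a simulated censored walk.

    ``start_rule`` is ``"uniform"`` (uniform over nodes), a node label
    (fixed start), or ``"weighted"`` with ``start_weights`` giving relative
    node weights.  ``emit_target`` is the number of unique items to emit;
    ``max_steps`` bounds the raw number of walk steps so the simulation
    always terminates (a walk trapped away from unvisited nodes is
    truncated and flagged).
    """

    emit_target: int
    max_steps: int = 10_000
    start_rule: str = "uniform"
    start_weights: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emit_target < 1:
            raise ValueError("emit_target must be >= 1")
        if self.max_steps < self.emit_target:
            raise ValueError("max_steps must be >= emit_target")
        if self.start_rule == "weighted" and not self.start_weights:
            raise ValueError("start_rule 'weighted' requires start_weights")


@dataclass(frozen=True)
class LikelihoodResult:
    """Exact log-likelihood of one list, with per-transition terms."""

    log_likelihood: float
    per_transition: tuple[float, ...]


def _component_of(net: SemanticNetwork, node: str) -> set[str]:
    seen = {node}
    stack = [node]
    while stack:
        for nbr in net.neighbors(stack.pop()):
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return seen


def _pick_start(net: SemanticNetwork, params: WalkParams, rng: np.random.Generator) -> str:
    if params.start_rule == "uniform":
        return net.nodes[rng.integers(len(net.nodes))]
    if params.start_rule == "weighted":
        w = np.array([params.start_weights.get(n, 0.0) for n in net.nodes], dtype=float)
        if w.sum() <= 0:
            raise ValueError("start_weights give zero total mass on the network")
        return net.nodes[rng.choice(len(net.nodes), p=w / w.sum())]
    if params.start_rule in net.nodes:
        return params.start_rule
    raise ValueError(f"start_rule {params.start_rule!r} is not a node of the network")


def simulate_censored_walk(
    net: SemanticNetwork,
    params: WalkParams,
    rng: np.random.Generator | None = None,
) -> FluencyList:
    """Simulate one fluency list from a network.

    The start node is emitted first; each step moves uniformly at random
    over neighbors; a node is emitted only on first visit.  The walk stops
    once ``emit_target`` unique nodes are emitted or ``max_steps`` raw
    steps have been taken.  Deterministic given ``params.seed`` (or the
    supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    start = _pick_start(net, params, rng)
    comp_size = len(_component_of(net, start))
    if comp_size < params.emit_target:
        raise ValueError(
            f"component of start node {start!r} has only {comp_size} nodes; "
            f"cannot emit {params.emit_target} unique items"
        )
    emitted = [start]
    visited = {start}
    current = start
    steps = 0
    while len(emitted) < params.emit_target and steps < params.max_steps:
        nbrs = net.neighbors(current)
        if not nbrs:
            break
        current = nbrs[rng.integers(len(nbrs))]
        steps += 1
        if current not in visited:
            visited.add(current)
            emitted.append(current)
    return FluencyList(subject_id="sim", list_number=0, tokens=tuple(emitted))


def emission_distribution(
    net: SemanticNetwork, visited: Sequence[str], current: str
) -> dict[str, float]:
    """Probability of each possible next emission given the visited set.

    Solves the absorbing chain whose transient states are ``visited`` and
    whose absorbing states are the unvisited neighbors of the visited set,
    for a walk currently at ``current``.  Returns a mapping from candidate
    next item to its exact first-passage probability; empty when the
    visited set has no unvisited neighbors.  Probabilities sum to 1
    whenever every transient state can reach the absorbing boundary.
    """
    vlist = list(dict.fromkeys(visited))
    vset = set(vlist)
    if current not in vset:
        raise ValueError("current node must belong to the visited set")
    boundary = sorted(
        {nbr for v in vlist for nbr in net.neighbors(v)} - vset
    )
    if not boundary:
        return {}

    # restrict to transient states from which the boundary is reachable;
    # mass entering the complement is trapped and never absorbed
    can_exit = {v for v in vlist if any(n not in vset for n in net.neighbors(v))}
    frontier = list(can_exit)
    while frontier:
        nxt = []
        for v in vlist:
            if v not in can_exit and any(
                n in can_exit for n in net.neighbors(v) if n in vset
            ):
                can_exit.add(v)
                nxt.append(v)
        frontier = nxt
    if current not in can_exit:
        return {b: 0.0 for b in boundary}

    trans = [v for v in vlist if v in can_exit]
    tidx = {v: i for i, v in enumerate(trans)}
    aidx = {b: j for j, b in enumerate(boundary)}
    n, m = len(trans), len(boundary)
    Q = np.zeros((n, n))
    B = np.zeros((n, m))
    for i, u in enumerate(trans):
        nbrs = net.neighbors(u)
        d = len(nbrs)
        for v in nbrs:
            if v in tidx:
                Q[i, tidx[v]] += 1.0 / d
            elif v in aidx:
                B[i, aidx[v]] += 1.0 / d
            # neighbors in the trapped transient set absorb mass silently
    H = np.linalg.solve(np.eye(n) - Q, B)
    probs = np.clip(H[tidx[current]], 0.0, 1.0)
    return {b: float(p) for b, p in zip(boundary, probs)}


def list_log_likelihood(net: SemanticNetwork, tokens: Sequence[str]) -> LikelihoodResult:
    """Exact censored-walk log-likelihood of one list given a network.

    The first token is conditioned on; each later token contributes the
    log first-passage probability of being the next first-visit given the
    items emitted so far.  Any impossible transition makes the total
    negative infinity.
    """
    tokens = list(tokens)
    if len(set(tokens)) != len(tokens):
        raise ValueError("perseveration in list: censored walks emit each item once")
    nodeset = set(net.nodes)
    for t in tokens:
        if t not in nodeset:
            raise ValueError(f"token {t!r} is not a node of the network")
    per: list[float] = []
    for k in range(1, len(tokens)):
        dist = emission_distribution(net, tokens[:k], tokens[k - 1])
        p = dist.get(tokens[k], 0.0)
        per.append(math.log(p) if p > 0 else -math.inf)
    total = sum(per) if per else 0.0
    return LikelihoodResult(log_likelihood=total, per_transition=tuple(per))


def dataset_log_likelihood(net: SemanticNetwork, dataset: FluencyDataset) -> float:
    """Sum of per-list log-likelihoods over independent lists."""
    total = 0.0
    for fl in dataset.lists:
        total += list_log_likelihood(net, fl.tokens).log_likelihood
        if total == -math.inf:
            return -math.inf
    return total


def generate_synthetic_dataset(
    net: SemanticNetwork,
    n_subjects: int,
    lists_per_subject: int,
    params: WalkParams,
    perseveration_rate: float = 0.0,
    intrusion_rate: float = 0.0,
    intrusion_lexicon: Sequence[str] = (),
    hierarchical: bool = False,
) -> tuple[FluencyDataset, dict]:
    """Generate a fluency dataset by censored walks, with planted errors.

    Each subject contributes ``lists_per_subject`` censored-walk lists.
    Perseverations are planted by inserting a verbatim copy of an earlier
    *walk* token at a random later position (never duplicating a planted
    intrusion, so planted perseveration and intrusion counts stay
    disjoint); intrusions are planted by inserting words drawn without
    replacement per list from ``intrusion_lexicon``, which should be
    disjoint from the network's nodes.  Per-slot planting probability is
    the given rate.  Returns the dataset and a ground-truth ledger with
    exact planted positions and counts, suitable for measure-recovery
    checks.  Deterministic given ``params.seed``.
    """
    for rate, name in ((perseveration_rate, "perseveration_rate"),
                       (intrusion_rate, "intrusion_rate")):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    if intrusion_rate > 0 and not intrusion_lexicon:
        raise ValueError("intrusion_rate > 0 requires an intrusion_lexicon")
    if set(intrusion_lexicon) & set(net.nodes):
        raise ValueError("intrusion_lexicon overlaps the network's nodes")

    rng = np.random.default_rng(params.seed)
    lists: list[FluencyList] = []
    ledger: dict = {
        "network_nodes": list(net.nodes),
        "network_edges": sorted(sorted(e) for e in net.edges),
        "params": {
            "emit_target": params.emit_target,
            "max_steps": params.max_steps,
            "start_rule": params.start_rule,
            "seed": params.seed,
            "perseveration_rate": perseveration_rate,
            "intrusion_rate": intrusion_rate,
        },
        "lists": [],
        "n_perseverations": 0,
        "n_intrusions": 0,
    }
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        for ln in range(lists_per_subject):
            walk = list(simulate_censored_walk(net, params, rng=rng).tokens)
            truncated = len(walk) < params.emit_target
            toks = list(walk)
            persev_pos: list[int] = []
            intr_pos: list[int] = []
            intr_tokens: list[str] = []
            if perseveration_rate > 0 and len(toks) >= 2:
                for _ in range(len(walk)):
                    if rng.random() < perseveration_rate:
                        at = int(rng.integers(1, len(toks) + 1))
                        pool = [t for t in toks[:at] if t in set(walk)]
                        if not pool:
                            continue
                        toks.insert(at, pool[int(rng.integers(len(pool)))])
                        persev_pos = [p if p < at else p + 1 for p in persev_pos]
                        intr_pos = [p if p < at else p + 1 for p in intr_pos]
                        persev_pos.append(at)
            if intrusion_rate > 0:
                avail = [w for w in intrusion_lexicon]
                rng.shuffle(avail)
                for _ in range(len(walk)):
                    if avail and rng.random() < intrusion_rate:
                        word = avail.pop()
                        at = int(rng.integers(0, len(toks) + 1))
                        toks.insert(at, word)
                        persev_pos = [p if p < at else p + 1 for p in persev_pos]
                        intr_pos = [p if p < at else p + 1 for p in intr_pos]
                        intr_pos.append(at)
                        intr_tokens.append(word)
            lists.append(
                FluencyList(subject_id=sid, list_number=ln, tokens=tuple(toks))
            )
            ledger["lists"].append(
                {
                    "id": sid,
                    "listnum": ln,
                    "walk_tokens": walk,
                    "tokens": toks,
                    "perseveration_positions": sorted(persev_pos),
                    "intrusion_positions": sorted(intr_pos),
                    "intrusion_tokens": intr_tokens,
                    "truncated": truncated,
                }
            )
            ledger["n_perseverations"] += len(persev_pos)
            ledger["n_intrusions"] += len(intr_pos)
    dataset = FluencyDataset(lists=tuple(lists), hierarchical=hierarchical)
    return dataset, ledger
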