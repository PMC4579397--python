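"""Candidate Boolean logic models over a background network.

A *logic model* assigns every non-root node of the background network one
input combination: a subset of its incoming edges plus the gate that combines
them (NONE, SINGLE, AND or OR).  What a node is allowed to choose depends on
its role:

* **sink** (measured data site, no outgoing edges) -- exactly one incoming
  K/P edge; with m candidates each has initial probability 1/m.
* **integrator** (protein activity node fed by its own sites) -- each edge
  singly, all edges together as one AND, or no edge: m + 2 bins, each with
  initial probability 1/(m+2).  (With a single incoming edge the AND
  duplicates the single input, leaving two bins.)
* **intermediate** (relay site) -- free logic: each edge is included by an
  independent Bernoulli draw, and if two or more are included a second draw
  picks AND vs OR.  With two edges at the initial weights (0.5 everywhere)
  the induced outcome distribution over (edge1, edge2, none, AND, OR) is
  (0.25, 0.25, 0.25, 0.125, 0.125).

Perturbations are propagated from the drug targets through a sampled model by
monotone Boolean dynamics: a node switches from control (0) to perturbed (1)
when its combination evaluates true, and never switches back.  Monotonicity
guarantees a unique least fixpoint, independent of update order, reached in
at most |nodes| sweeps.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from itertools import combinations as subsets

import numpy as np

from phosflow.network import BackgroundNetwork

logger = logging.getLogger(__name__)

GATES = ("NONE", "SINGLE", "AND", "OR")


@dataclass(frozen=True)
class InputCombination:
    """One node's chosen inputs: a set of source nodes plus the combining gate."""

    node: str
    sources: tuple[str, ...]
    gate: str

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise ValueError(f"unknown gate {self.gate!r}")
        if (self.gate == "NONE") != (len(self.sources) == 0):
            raise ValueError("gate NONE iff no sources")
        if self.gate == "SINGLE" and len(self.sources) != 1:
            raise ValueError("gate SINGLE requires exactly one source")
        if self.gate in ("AND", "OR") and len(self.sources) < 2:
            raise ValueError("AND/OR require at least two sources")

    @property
    def key(self) -> tuple[tuple[str, ...], str]:
        return (self.sources, self.gate)


#: A logic model maps each non-root node to its chosen input combination.
LogicModel = dict[str, InputCombination]


@dataclass
class NodeWeights:
    """Sampling weights for one node.

    Sink and integrator nodes are categorical over their allowed combinations
    (``combos``/``probs``).  Intermediate nodes are factored: a per-edge
    inclusion probability ``edge_p`` plus the AND-vs-OR gate probability
    ``p_and``.
    """

    node: str
    role: str  # sink | integrator | intermediate
    edges: tuple[str, ...]
    combos: list[InputCombination] | None = None
    probs: np.ndarray | None = None
    edge_p: np.ndarray | None = None
    p_and: float = 0.5

    def validate(self) -> None:
        if self.role in ("sink", "integrator"):
            assert self.probs is not None and abs(self.probs.sum() - 1) < 1e-9
            assert np.all(self.probs >= 0)
        else:
            assert self.edge_p is not None
            assert np.all((self.edge_p >= 0) & (self.edge_p <= 1))
            assert 0 <= self.p_and <= 1


def enumerate_combinations(
    node: str,
    role: str,
    in_edges: list[str],
    edge_p: float = 0.5,
    p_and: float = 0.5,
) -> list[tuple[InputCombination, float]]:
    """Allowed input combinations of a node with their sampling probabilities.

    For intermediates the probabilities are the outcome distribution induced
    by the two-stage draw (independent per-edge inclusion at ``edge_p``, then
    gate at ``p_and``), enumerated exactly over all edge subsets.
    """
    srcs = tuple(sorted(in_edges))
    m = len(srcs)
    if m == 0:
        return []
    if role == "sink":
        return [(InputCombination(node, (s,), "SINGLE"), 1.0 / m) for s in srcs]
    if role == "integrator":
        out = [(InputCombination(node, (s,), "SINGLE"), None) for s in srcs]
        if m >= 2:
            out.append((InputCombination(node, srcs, "AND"), None))
        out.append((InputCombination(node, (), "NONE"), None))
        p = 1.0 / len(out)
        return [(c, p) for c, _ in out]
    if role == "intermediate":
        out = []
        for r in range(m + 1):
            for chosen in subsets(range(m), r):
                p_subset = 1.0
                for k in range(m):
                    p_subset *= edge_p if k in chosen else (1 - edge_p)
                sub = tuple(srcs[k] for k in chosen)
                if r == 0:
                    out.append((InputCombination(node, (), "NONE"), p_subset))
                elif r == 1:
                    out.append((InputCombination(node, sub, "SINGLE"), p_subset))
                else:
                    out.append((InputCombination(node, sub, "AND"), p_subset * p_and))
                    out.append((InputCombination(node, sub, "OR"), p_subset * (1 - p_and)))
        return out
    raise ValueError(f"unknown node role {role!r}")


def initial_weights(
    background: BackgroundNetwork, intermediate_edge_p: float | str = 0.5
) -> dict[str, NodeWeights]:
    """Initial (untrained) sampling weights for every non-root node.

    ``intermediate_edge_p`` is the initial per-edge inclusion probability of
    intermediate nodes: 0.5 by default irrespective of the edge count, or the
    string ``"1/m"`` for a count-scaled alternative.
    """
    weights: dict[str, NodeWeights] = {}
    for node in sorted(background.graph.nodes):
        role = background.node_role(node)
        if role == "root":
            continue
        edges = tuple(background.in_edges_of(node))
        if not edges:
            logger.warning("non-root node %s has no incoming edges; treated as root", node)
            continue
        if role in ("sink", "integrator"):
            combos = [c for c, _ in enumerate_combinations(node, role, list(edges))]
            probs = np.array([p for _, p in enumerate_combinations(node, role, list(edges))])
            weights[node] = NodeWeights(node, role, edges, combos=combos, probs=probs)
        else:
            p = 1.0 / len(edges) if intermediate_edge_p == "1/m" else float(intermediate_edge_p)
            weights[node] = NodeWeights(
                node, role, edges, edge_p=np.full(len(edges), p), p_and=0.5
            )
    return weights


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_population(
    weights: dict[str, NodeWeights], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]]:
    """Draw choices for ``n`` models at once, node by node.

    For categorical nodes the value is an array of combination indices; for
    intermediate nodes a pair ``(mask, gate)`` where ``mask[i]`` is the
    bitmask of included edges of model ``i`` and ``gate[i]`` is 1 for AND.
    Nodes are visited in sorted order so a fixed seed reproduces draws.
    """
    choices: dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]] = {}
    for node in sorted(weights):
        w = weights[node]
        if w.role in ("sink", "integrator"):
            choices[node] = rng.choice(len(w.combos), size=n, p=w.probs)
        else:
            inc = rng.random((n, len(w.edges))) < w.edge_p
            mask = inc @ (1 << np.arange(len(w.edges)))
            gate = (rng.random(n) < w.p_and).astype(np.int8)
            choices[node] = (mask.astype(np.int64), gate)
    return choices


def population_model(
    weights: dict[str, NodeWeights],
    choices: dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]],
    i: int,
) -> LogicModel:
    """Materialize model ``i`` of a sampled population."""
    model: LogicModel = {}
    for node, w in weights.items():
        ch = choices[node]
        if w.role in ("sink", "integrator"):
            model[node] = w.combos[int(ch[i])]
        else:
            mask, gate = ch
            model[node] = _combo_from_mask(node, w.edges, int(mask[i]), int(gate[i]))
    return model


def _combo_from_mask(node: str, edges: tuple[str, ...], mask: int, gate_bit: int) -> InputCombination:
    sub = tuple(e for k, e in enumerate(edges) if mask >> k & 1)
    if len(sub) == 0:
        return InputCombination(node, (), "NONE")
    if len(sub) == 1:
        return InputCombination(node, sub, "SINGLE")
    return InputCombination(node, sub, "AND" if gate_bit else "OR")


def sample_model(weights: dict[str, NodeWeights], rng: np.random.Generator | int) -> LogicModel:
    """Draw one logic model from the current sampling weights."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return population_model(weights, sample_population(weights, 1, rng), 0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(model: LogicModel, targets: set[str]) -> set[str]:
    """Propagate perturbations to the unique monotone fixpoint.

    Nodes start at control (0) except the drug targets (1); a node becomes
    perturbed when its input combination evaluates true (SINGLE: its source;
    OR: any chosen source; AND: all chosen sources; NONE: never) and states
    only flip 0 -> 1.  A worklist propagation computes the least fixpoint,
    which equals the limit of synchronous sweeps.
    """
    consumers: dict[str, list[str]] = {}
    need: dict[str, int] = {}
    for node, comb in model.items():
        if comb.gate == "NONE":
            continue
        need[node] = len(comb.sources) if comb.gate == "AND" else 1
        for s in comb.sources:
            consumers.setdefault(s, []).append(node)
    active = set(targets)
    queue = deque(active)
    while queue:
        u = queue.popleft()
        for v in consumers.get(u, ()):
            if v in active:
                continue
            need[v] -= 1
            if need[v] <= 0:
                active.add(v)
                queue.append(v)
    return active


def simulate_sync(model: LogicModel, targets: set[str], order: list[str] | None = None) -> set[str]:
    """Reference simulator: repeated full sweeps until no state changes.

    ``order`` fixes the within-sweep node visiting order (default: sorted node
    ids); used to verify update-order independence of the fixpoint.
    """
    active = set(targets)
    nodes = order if order is not None else sorted(model)
    changed = True
    while changed:
        changed = False
        snapshot = set(active)
        for node in nodes:
            comb = model.get(node)
            if node in active or comb is None or comb.gate == "NONE":
                continue
            if comb.gate == "AND":
                on = all(s in snapshot for s in comb.sources)
            else:
                on = any(s in snapshot for s in comb.sources)
            if on:
                active.add(node)
                changed = True
    return active


def simulate_async(
    model: LogicModel, targets: set[str], rng: np.random.Generator
) -> set[str]:
    """Random-order asynchronous updates; converges to the same least fixpoint."""
    active = set(targets)
    nodes = [n for n in model]
    changed = True
    while changed:
        changed = False
        rng.shuffle(nodes)
        for node in nodes:
            comb = model[node]
            if node in active or comb.gate == "NONE":
                continue
            if comb.gate == "AND":
                on = all(s in active for s in comb.sources)
            else:
                on = any(s in active for s in comb.sources)
            if on:
                active.add(node)
                changed = True
    return active


def predict_conditions(
    model: LogicModel,
    drug_panel: dict[str, frozenset[str]],
    network_nodes: set[str],
    data_sites: set[str],
) -> tuple[dict[str, set[str]], list[str]]:
    """Predicted perturbed data sites per condition.

    Conditions sharing the same in-network target set share one simulation.
    Conditions with no in-network target are flagged and excluded from
    scoring.  Returns ``(predictions, excluded_conditions)``.
    """
    by_targets: dict[frozenset[str], list[str]] = {}
    excluded: list[str] = []
    for cond, targs in drug_panel.items():
        eff = frozenset(t for t in targs if t in network_nodes)
        if not eff:
            excluded.append(cond)
            continue
        by_targets.setdefault(eff, []).append(cond)
    if excluded:
        logger.warning("conditions with no in-network target excluded: %s", excluded)
    predictions: dict[str, set[str]] = {}
    for targs, conds in by_targets.items():
        hit = simulate(model, set(targs)) & data_sites
        for cond in conds:
            predictions[cond] = hit
    return predictions, excluded
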