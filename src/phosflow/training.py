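"""Iterative training of Boolean logic models against perturbation evidence.

Each generation samples a population of *n* logic models from the current
per-node sampling weights, simulates every model to its steady state under
each experimental condition (one simulation per distinct drug-target set),
and scores it against the site-level evidence matrix:

    score = sum_j [ sum_{i predicted perturbed} S_ij
                    - sum_{i not predicted, S_ij < 0} S_ij ]  +  sizeP * |edges|

i.e. true-positive predictions (negative S) + false-positive predictions
(positive S) - false-negative predictions (negative S); true negatives do not
contribute, because with untargeted discovery data unperturbed measurements
vastly outnumber perturbed ones under any condition.  Lower scores are
better.

A best-model family (within a tolerance of the generation's best score) then
drives a weight correction: each input is virtually copied 1 + cap * f times,
f being its frequency in the family, and the copies renormalized into the new
sampling probabilities; the AND-gate probability of intermediate nodes is
averaged with the family's AND frequency.  Training stops when the population
mean score and the edge sampling frequencies stabilize, or after a fixed
number of generations.  Independent runs are averaged and summarized as a
consensus network: per node, the maximum-frequency input plus every input
within a tolerance of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from phosflow.logic import (
    InputCombination,
    LogicModel,
    NodeWeights,
    _combo_from_mask,
    initial_weights,
    predict_conditions,
    sample_population,
)
from phosflow.network import BackgroundNetwork
from phosflow.scoring import SMatrix

logger = logging.getLogger(__name__)

#: key type used for input combinations in frequency tables
ComboKey = tuple[tuple[str, ...], str]


@dataclass
class TrainingParams:
    """Knobs of one optimization.

    ``n`` models per generation (5,000 in the reference configuration), a
    weight ceiling ``cap`` (typically 5 or 20), the best-family tolerance
    ``tol_best`` (0.15 or 0.30), a hard generation limit, a per-edge size
    penalty weight ``sizeP`` (0 or 1), the number of independent runs whose
    final frequencies are averaged, and the consensus tolerance.
    """

    n: int = 5000
    cap: float = 5.0
    tol_best: float = 0.30
    generations: int = 50
    sizeP: float = 1.0
    n_runs: int = 3
    consensus_tol: float = 0.20
    seed: int = 0
    intermediate_edge_p: float | str = 0.5
    score_tol: float = 0.01
    freq_tol: float = 0.01
    patience: int = 3
    tol_absolute: bool = False
    compounding: bool = True

    def __post_init__(self) -> None:
        if self.n < 1 or self.cap < 0 or self.generations < 1 or self.n_runs < 1:
            raise ValueError("invalid training parameters")
        if not (0 <= self.tol_best <= 1 and 0 <= self.consensus_tol <= 1):
            raise ValueError("tolerances must lie in [0, 1]")


@dataclass
class ModelScore:
    """Score of one model with its decomposition (lower is better)."""

    score: float
    tp_sum: float = 0.0
    fp_sum: float = 0.0
    fn_sum: float = 0.0
    size_penalty: float = 0.0
    per_condition: dict[str, float] = field(default_factory=dict)


@dataclass
class TrainingResult:
    """Outcome of a single optimization run."""

    trajectory: pd.DataFrame
    frequencies: dict[str, dict[ComboKey, float]]
    weights: dict[str, NodeWeights]
    converged_at: int | None
    params: TrainingParams


@dataclass
class ConsensusNetwork:
    """Tolerance-filtered summary of combined run frequencies.

    ``top`` maps each node to its maximum-frequency input combination;
    ``retained`` additionally keeps every combination within
    ``consensus_tol`` of the maximum.  ``graph`` holds the union of retained
    input edges, each annotated with the frequency of its best retaining
    combination.
    """

    graph: nx.DiGraph
    top: dict[str, ComboKey]
    retained: dict[str, list[tuple[ComboKey, float]]]
    consensus_tol: float

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_model(
    predictions: dict[str, set[str]],
    smatrix: SMatrix,
    sizeP: float = 0.0,
    n_edges: int = 0,
) -> ModelScore:
    """Score one model's per-condition predictions against the evidence matrix.

    ``predictions`` maps each scored data condition to the set of data sites
    the simulation perturbs.  Sites predicted but never measured are ignored
    (unmeasured relay nodes).  Conditions sharing a target set appear as
    separate entries, so drugs with identical targets accumulate evidence.
    """
    tp = fp = fn = 0.0
    per_condition: dict[str, float] = {}
    measured = set(smatrix.site_s.index)
    for cond, predicted in predictions.items():
        svec = smatrix.site_s[cond]
        unmeasured = predicted - measured
        if unmeasured:
            logger.warning(
                "condition %s: %d predicted sites not in the evidence matrix", cond, len(unmeasured)
            )
        contrib = 0.0
        for site, s in svec.items():
            if not np.isfinite(s):
                continue
            if site in predicted:
                contrib += s
                if s < 0:
                    tp += s
                else:
                    fp += s
            elif s < 0:
                contrib -= s
                fn += s
        per_condition[cond] = contrib
    size_penalty = sizeP * n_edges
    total = tp + fp - fn + size_penalty
    return ModelScore(total, tp, fp, fn, size_penalty, per_condition)


def select_best(scores: np.ndarray, tol_best: float, absolute: bool = False) -> np.ndarray:
    """Indices of the best-model family: scores within tolerance of the minimum.

    The threshold is ``s* + tol_best * |s*|`` (scores are typically negative),
    or ``s* + tol_best`` with ``absolute=True``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to select from")
    s_star = scores.min()
    threshold = s_star + (tol_best if absolute else tol_best * abs(s_star))
    return np.flatnonzero(scores <= threshold)


# ---------------------------------------------------------------------------
# weight correction
# ---------------------------------------------------------------------------


def update_weights(
    current: dict[str, NodeWeights],
    family_freqs: dict[str, dict],
    cap: float,
    compounding: bool = False,
) -> dict[str, NodeWeights]:
    """Cap-bounded weight correction from best-family input frequencies.

    Categorical nodes (sinks and integrators): each combination gets
    ``1 + cap * f`` virtual copies, f its family frequency, normalized into
    probabilities.  Intermediate nodes: each edge gets ``1 + cap * f_e``
    copies normalized across the node's edges; the AND probability becomes
    the average of its previous value and the AND frequency among family
    models with two or more included edges (unchanged when the family has no
    such model).  With ``compounding=True`` (the default) the previous
    probabilities replace the uniform base, so evidence accumulates across
    generations and a uniquely-determined input can converge to frequency 1;
    both modes reproduce the worked two-edge correction examples, whose
    first update starts from the uniform state.  Non-compounding restarts
    from the uniform base each generation, capping any probability at
    ``(1 + cap) / (k + cap)``.

    ``family_freqs`` maps node -> mapping.  Categorical nodes accept keys that
    are combination indices, :class:`InputCombination` objects or their
    ``key`` tuples; intermediate nodes accept source-node names plus the
    special key ``"AND"`` (omit it to leave the gate probability unchanged).
    Missing entries count as frequency zero.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    out: dict[str, NodeWeights] = {}
    for node, w in current.items():
        freqs = family_freqs.get(node, {})
        if w.role in ("sink", "integrator"):
            f = np.zeros(len(w.combos))
            for key, val in freqs.items():
                f[_combo_index(w, key)] = val
            base = w.probs * len(w.combos) if compounding else np.ones(len(w.combos))
            counts = base + cap * f
            out[node] = replace(w, probs=counts / counts.sum())
        else:
            f = np.zeros(len(w.edges))
            and_freq = None
            for key, val in freqs.items():
                if key == "AND":
                    and_freq = val
                else:
                    f[w.edges.index(key)] = val
            base = w.edge_p * len(w.edges) if compounding else np.ones(len(w.edges))
            counts = base + cap * f
            p_and = w.p_and if and_freq is None else (w.p_and + and_freq) / 2
            out[node] = replace(w, edge_p=counts / counts.sum(), p_and=p_and)
        out[node].validate()
    return out


def _combo_index(w: NodeWeights, key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    if isinstance(key, InputCombination):
        key = key.key
    for i, c in enumerate(w.combos):
        if c.key == key:
            return i
    raise KeyError(f"unknown combination {key!r} for node {w.node}")


# ---------------------------------------------------------------------------
# compiled training loop
# ---------------------------------------------------------------------------


class _Compiled:
    """Background + evidence pre-digested for the inner loop."""

    def __init__(self, background: BackgroundNetwork, smatrix: SMatrix, sizeP: float):
        self.background = background
        g = background.graph
        self.data_sites = sorted(background.data_sites & set(smatrix.site_s.index))
        if not self.data_sites:
            raise ValueError("no reachable data site has evidence: refusing to train")
        # conditions grouped by effective in-network target set
        nodes = set(g.nodes)
        self.groups: list[tuple[frozenset[str], list[str]]] = []
        seen: dict[frozenset[str], int] = {}
        for cond in smatrix.data_conditions:
            targs = background.drug_panel.get(cond)
            if targs is None:
                continue
            eff = frozenset(t for t in targs if t in nodes)
            if not eff:
                logger.warning("condition %s has no in-network target; excluded", cond)
                continue
            if eff not in seen:
                seen[eff] = len(self.groups)
                self.groups.append((eff, []))
            self.groups[seen[eff]][1].append(cond)
        if not self.groups:
            raise ValueError("no condition maps to an in-network target set")
        # per condition: score with empty prediction, and per-site delta when
        # predicted; evidence at sites outside the background can never be
        # predicted and enters as a constant false-negative penalty, keeping
        # scores comparable across backgrounds trained on the same data
        self.base = {}
        self.delta = {}
        outside = smatrix.site_s.index.difference(self.data_sites)
        for _, conds in self.groups:
            for cond in conds:
                s = smatrix.site_s[cond].reindex(self.data_sites).to_numpy()
                s = np.nan_to_num(s, nan=0.0)
                s_out = np.nan_to_num(smatrix.site_s.loc[outside, cond].to_numpy(), nan=0.0)
                self.base[cond] = float(-s[s < 0].sum()) + float(-s_out[s_out < 0].sum())
                self.delta[cond] = np.where(s < 0, 2 * s, s)
        self.site_index = {s: k for k, s in enumerate(self.data_sites)}
        self.sizeP = sizeP


def _score_population(
    compiled: _Compiled,
    weights: dict[str, NodeWeights],
    choices: dict,
    n: int,
) -> np.ndarray:
    """Simulate and score every sampled model (worklist fixpoint per model)."""
    nodes = sorted(weights)
    # per-model chosen sources/gate, as python structures for the worklist
    scores = np.empty(n)
    mask_cache: dict[str, dict[int, tuple[str, ...]]] = {}
    for i in range(n):
        consumers: dict[str, list[str]] = {}
        need: dict[str, int] = {}
        n_edges = 0
        for node in nodes:
            w = weights[node]
            ch = choices[node]
            if w.role in ("sink", "integrator"):
                comb = w.combos[int(ch[i])]
                srcs, is_and = comb.sources, comb.gate == "AND"
            else:
                mask, gate = int(ch[0][i]), int(ch[1][i])
                cache = mask_cache.setdefault(node, {})
                srcs = cache.get(mask)
                if srcs is None:
                    srcs = tuple(e for k, e in enumerate(w.edges) if mask >> k & 1)
                    cache[mask] = srcs
                is_and = len(srcs) >= 2 and gate == 1
            if not srcs:
                continue
            n_edges += len(srcs)
            need[node] = len(srcs) if is_and else 1
            for s in srcs:
                consumers.setdefault(s, []).append(node)

        total = compiled.sizeP * n_edges
        for targs, conds in compiled.groups:
            active = set(targs)
            remaining = dict(need)
            queue = list(active)
            while queue:
                u = queue.pop()
                for v in consumers.get(u, ()):
                    if v in active:
                        continue
                    remaining[v] -= 1
                    if remaining[v] <= 0:
                        active.add(v)
                        queue.append(v)
            hit = [compiled.site_index[s] for s in active.intersection(compiled.site_index)]
            for cond in conds:
                total += compiled.base[cond]
                if hit:
                    total += compiled.delta[cond][hit].sum()
        scores[i] = total
    return scores


def _family_frequencies(
    weights: dict[str, NodeWeights], choices: dict, idx: np.ndarray
) -> dict[str, dict]:
    """Per-node input frequencies within a subset of the population."""
    freqs: dict[str, dict] = {}
    m = len(idx)
    for node, w in weights.items():
        if w.role in ("sink", "integrator"):
            counts = np.bincount(choices[node][idx], minlength=len(w.combos))
            freqs[node] = {i: counts[i] / m for i in range(len(w.combos))}
        else:
            mask, gate = choices[node]
            mask, gate = mask[idx], gate[idx]
            d: dict = {}
            for k, e in enumerate(w.edges):
                d[e] = float((mask >> k & 1).mean())
            multi = np.array([bin(v).count("1") >= 2 for v in mask])
            if multi.any():
                d["AND"] = float(gate[multi].mean())
            freqs[node] = d
    return freqs


def _combo_frequencies(
    weights: dict[str, NodeWeights], choices: dict, idx: np.ndarray
) -> dict[str, dict[ComboKey, float]]:
    """Frequency of every realized input combination within a population subset."""
    out: dict[str, dict[ComboKey, float]] = {}
    m = len(idx)
    for node, w in weights.items():
        table: dict[ComboKey, float] = {}
        if w.role in ("sink", "integrator"):
            counts = np.bincount(choices[node][idx], minlength=len(w.combos))
            for i, c in enumerate(w.combos):
                if counts[i]:
                    table[c.key] = counts[i] / m
        else:
            mask, gate = choices[node]
            for mk, gt in zip(mask[idx], gate[idx]):
                key = _combo_from_mask(node, w.edges, int(mk), int(gt)).key
                table[key] = table.get(key, 0.0) + 1.0 / m
        out[node] = table
    return out


def train(
    background: BackgroundNetwork,
    smatrix: SMatrix,
    params: TrainingParams,
    seed: int | None = None,
    weights: dict[str, NodeWeights] | None = None,
) -> TrainingResult:
    """One optimization run: sample, simulate, score, select, correct; iterate.

    Stops at ``params.generations`` or once both the population mean score
    (relative change below ``score_tol``) and every sampling frequency
    (absolute change below ``freq_tol``) have been stable for ``patience``
    consecutive generations.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    compiled = _Compiled(background, smatrix, params.sizeP)
    if weights is None:
        weights = initial_weights(background, params.intermediate_edge_p)
    if not weights:
        raise ValueError("background has no trainable node")

    rows = []
    prev_mean = None
    prev_freq: dict | None = None
    stable = 0
    converged_at = None
    choices = None
    for gen in range(params.generations):
        choices = sample_population(weights, params.n, rng)
        scores = _score_population(compiled, weights, choices, params.n)
        family = select_best(scores, params.tol_best, params.tol_absolute)
        fam_freqs = _family_frequencies(weights, choices, family)
        pop_freqs = _family_frequencies(weights, choices, np.arange(params.n))

        max_dfreq = np.inf
        if prev_freq is not None:
            max_dfreq = max(
                abs(pop_freqs[node].get(k, 0.0) - prev_freq[node].get(k, 0.0))
                for node in pop_freqs
                for k in set(pop_freqs[node]) | set(prev_freq[node])
            )
        mean, best = float(scores.mean()), float(scores.min())
        rows.append((gen, mean, best, len(family), max_dfreq if np.isfinite(max_dfreq) else np.nan))

        if (
            prev_mean is not None
            and abs(mean - prev_mean) < params.score_tol * max(abs(best), 1e-12)
            and max_dfreq < params.freq_tol
        ):
            stable += 1
        else:
            stable = 0
        prev_mean, prev_freq = mean, pop_freqs
        if stable >= params.patience:
            converged_at = gen
            break
        weights = update_weights(weights, fam_freqs, params.cap, params.compounding)

    trajectory = pd.DataFrame(
        rows, columns=["generation", "mean_score", "min_score", "family_size", "max_freq_change"]
    )
    frequencies = _combo_frequencies(weights, choices, np.arange(params.n))
    return TrainingResult(trajectory, frequencies, weights, converged_at, params)


# ---------------------------------------------------------------------------
# combining runs and consensus extraction
# ---------------------------------------------------------------------------


def combine_runs(results: list[TrainingResult]) -> dict[str, dict[ComboKey, float]]:
    """Average final-population combination frequencies across runs."""
    if not results:
        raise ValueError("need at least one run")
    nodes = set(results[0].frequencies)
    for r in results[1:]:
        if set(r.frequencies) != nodes:
            raise ValueError("runs trained on different backgrounds cannot be combined")
    out: dict[str, dict[ComboKey, float]] = {}
    for node in nodes:
        keys = set().union(*(r.frequencies[node] for r in results))
        out[node] = {
            k: float(np.mean([r.frequencies[node].get(k, 0.0) for r in results])) for k in keys
        }
    return out


def consensus_network(
    freqs: dict[str, dict[ComboKey, float]],
    consensus_tol: float = 0.20,
    background: BackgroundNetwork | None = None,
) -> ConsensusNetwork:
    """Extract the consensus model from combined frequencies.

    With ``consensus_tol=0`` this is the majority-voting model: each node
    keeps only its maximum-frequency input (ties broken deterministically by
    the combination key).  With a positive tolerance every input whose
    frequency is at least ``(1 - tol) * max`` is retained, exposing how
    tightly the data constrain each node.
    """
    g = nx.DiGraph()
    top: dict[str, ComboKey] = {}
    retained: dict[str, list[tuple[ComboKey, float]]] = {}
    for node in sorted(freqs):
        table = {k: f for k, f in freqs[node].items() if f > 0}
        if not table:
            logger.warning("node %s has all-zero input frequencies; omitted", node)
            continue
        ordered = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
        best_key, best_f = ordered[0]
        top[node] = best_key
        if consensus_tol == 0:
            keep = [(best_key, best_f)]
        else:
            cut = (1 - consensus_tol) * best_f
            keep = [(k, f) for k, f in ordered if f >= cut]
        retained[node] = keep
        g.add_node(node)
        for key, f in keep:
            sources, gate = key
            for s in sources:
                prev = g.edges.get((s, node), {}).get("frequency", -1.0)
                attrs = {"frequency": max(f, prev), "gate": gate}
                if background is not None and background.graph.has_edge(s, node):
                    attrs["kind"] = background.graph.edges[s, node]["kind"]
                g.add_edge(s, node, **attrs)
    return ConsensusNetwork(g, top, retained, consensus_tol)


def fit(
    background: BackgroundNetwork,
    smatrix: SMatrix,
    params: TrainingParams,
) -> tuple[ConsensusNetwork, dict[str, dict[ComboKey, float]], list[TrainingResult]]:
    """Run ``params.n_runs`` independent optimizations and combine them.

    Per-run seeds are spawned deterministically from ``params.seed``, so the
    result does not depend on execution order.
    """
    seeds = np.random.SeedSequence(params.seed).generate_state(params.n_runs) % (2**31)
    results = [train(background, smatrix, params, seed=int(s)) for s in seeds]
    freqs = combine_runs(results)
    consensus = consensus_network(freqs, params.consensus_tol, background)
    return consensus, freqs, results
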