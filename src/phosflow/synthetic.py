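"""Synthetic ground truths and datasets for end-to-end benchmarking.

The generator emulates the structure of a kinase-inhibitor perturbation
phosphoproteomics study: a kinase/phosphatase-substrate resource with a loose
signalling hierarchy (kinases phosphorylate regulatory sites on downstream
kinases; cycles are permitted, as in real kinase networks), a panel of drugs
each inhibiting one upstream kinase, measured data sites on substrate
proteins, and a planted ground-truth logic model drawn with the package's own
sampler.  Simulating the true model under each drug yields the truly
perturbed sites; intensities are then drawn on the log2 scale with a
biological/technical replicate structure (biological variance twice the
technical, batch offsets shared across peptides per biological replicate)
and an inhibition shift of ``-delta`` log2 units on perturbed (site,
condition) pairs.

Emitted tables use exactly the schemas the scoring and network modules
consume, so the full pipeline runs on synthetic output unchanged.  The
generator reproduces the replicate design and effect-size regime of a
perturbation screen but not MS-specific missingness mechanisms (a uniform
missing-at-random rate is the only dropout model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phosflow import logic, network
from phosflow.logic import LogicModel
from phosflow.network import BackgroundNetwork, KpsEdge, PathLimits
from phosflow.scoring import IntensityTable
from phosflow.training import ComboKey, ConsensusNetwork

logger = logging.getLogger(__name__)

CONTROL = "DMSO"


@dataclass
class GroundTruth:
    """A planted network, logic model, drug panel and perturbation pattern."""

    kps_edges: list[KpsEdge]
    background: BackgroundNetwork
    true_model: LogicModel
    drug_panel: dict[str, frozenset[str]]
    perturbed: dict[str, set[str]]  # condition -> truly perturbed data sites
    delta: float
    sigma: float
    n_bio: int = 2
    n_tech: int = 3
    seed: int = 0

    @property
    def data_sites(self) -> set[str]:
        return self.background.data_sites

    def kps_table(self) -> pd.DataFrame:
        rows = [
            (e.enzyme, e.substrate, e.residue, e.position, e.evidence,
             e.motif_score, e.context_score, e.source)
            for e in self.kps_edges
        ]
        return pd.DataFrame(
            rows,
            columns=["enzyme", "substrate", "residue", "position", "evidence",
                     "motif_score", "context_score", "source"],
        )


def generate_truth(
    n_kp: int = 20,
    n_sites: int = 50,
    n_drugs: int = 4,
    density: float = 1.0,
    seed: int = 0,
    delta: float = 5.0,
    sigma: float = 0.3,
    n_bio: int = 2,
    n_tech: int = 3,
    limits: PathLimits | None = None,
    max_tries: int = 50,
) -> GroundTruth:
    """Generate a random K/P-S resource with a planted logic model.

    Kinases ``K01..`` form a loose hierarchy: each non-root kinase carries one
    regulatory site drawing 1-3 upstream kinases (mostly from earlier tiers,
    with occasional feedback edges, so cycles can occur).  ``n_sites``
    measured data sites sit on substrate proteins ``P01..`` and each draws
    1-5 candidate kinases (scaled by ``density``).  Drugs each target one
    upper-tier kinase.  The true model is drawn from the background's initial
    sampling weights; generation retries (bounded) until every drug perturbs
    at least one data site.
    """
    if n_kp < 2 or n_sites < 1 or n_drugs < 1:
        raise ValueError("need n_kp >= 2, n_sites >= 1, n_drugs >= 1")
    master = np.random.default_rng(seed)
    for attempt in range(max_tries):
        rng = np.random.default_rng(master.integers(2**31))
        truth = _try_generate(
            n_kp, n_sites, n_drugs, density, rng, delta, sigma, n_bio, n_tech, limits
        )
        if truth is not None:
            truth.seed = seed
            return truth
        logger.warning("ground-truth attempt %d left a drug without effect; regenerating", attempt)
    raise RuntimeError("could not generate a connected ground truth; increase density")


def _try_generate(
    n_kp, n_sites, n_drugs, density, rng, delta, sigma, n_bio, n_tech, limits
) -> GroundTruth | None:
    kinases = [f"K{i + 1:02d}" for i in range(n_kp)]
    residues = np.array(["S", "T", "Y"])
    edges: list[KpsEdge] = []

    n_roots = max(n_drugs, n_kp // 5)
    for i, kin in enumerate(kinases):
        if i < n_roots:
            continue  # top-tier kinases are unregulated entry points
        res = str(rng.choice(residues, p=[0.6, 0.3, 0.1]))
        pos = int(rng.integers(1, 999))
        n_up = int(rng.integers(1, 4))
        upstream = rng.choice(i, size=min(n_up, i), replace=False)
        ups = [kinases[int(u)] for u in upstream]
        if rng.random() < 0.10 and i < n_kp - 1:  # occasional feedback edge
            ups.append(kinases[int(rng.integers(i + 1, n_kp))])
        for u in ups:
            edges.append(_random_edge(u, kin, res, pos, rng))

    n_sub = max(1, n_sites // 3)
    substrates = [f"P{i + 1:02d}" for i in range(n_sub)]
    used: set[tuple[str, str, int]] = set()
    for _ in range(n_sites):
        sub = str(rng.choice(substrates))
        while True:
            res = str(rng.choice(residues, p=[0.6, 0.3, 0.1]))
            pos = int(rng.integers(1, 999))
            if (sub, res, pos) not in used:
                used.add((sub, res, pos))
                break
        k_cand = max(1, min(n_kp, int(round(rng.integers(1, 6) * density))))
        for u in rng.choice(n_kp, size=k_cand, replace=False):
            edges.append(_random_edge(kinases[int(u)], sub, res, pos, rng))

    drug_targets = rng.choice(n_roots, size=min(n_drugs, n_roots), replace=False)
    panel = {
        f"drug{d + 1}": frozenset({kinases[int(t)]}) for d, t in enumerate(drug_targets)
    }
    all_sites = {e.site_id for e in edges if e.substrate.startswith("P")}
    try:
        full_bg = network.build_background(
            edges, panel, all_sites, limits=limits, evidence_filter="all"
        )
    except ValueError:
        return None

    model = plant_model(logic.initial_weights(full_bg), rng)
    predictions, excluded = logic.predict_conditions(
        model, panel, set(full_bg.graph.nodes), full_bg.data_sites
    )
    if excluded or any(len(p) == 0 for p in predictions.values()):
        return None

    # rebuild the background from the truly perturbed sites (the form the
    # pipeline trains on) and keep only consistent draws: the planted model
    # restricted to that background must be sampleable from it and reproduce
    # the same perturbation pattern
    perturbed_union = set().union(*predictions.values())
    try:
        background = network.build_background(
            edges, panel, perturbed_union, limits=limits, evidence_filter="all"
        )
    except ValueError:
        return None
    weights = logic.initial_weights(background)
    restricted: LogicModel = {}
    for node, w in weights.items():
        comb = model.get(node)
        if comb is None:
            return None
        if w.role in ("sink", "integrator"):
            if not any(c.key == comb.key for c in w.combos):
                return None
        elif not set(comb.sources) <= set(w.edges):
            return None
        restricted[node] = comb
    re_pred, excluded = logic.predict_conditions(
        restricted, panel, set(background.graph.nodes), background.data_sites
    )
    if excluded or re_pred != predictions:
        return None
    return GroundTruth(edges, background, restricted, panel, re_pred, delta, sigma, n_bio, n_tech)


def plant_model(weights: dict, rng: np.random.Generator) -> LogicModel:
    """Draw a ground-truth model with no silent inputs.

    Samples each node's combination from the sampler's initial distribution
    conditioned on the gate not being NONE.  A planted truth in which a node
    ignores its documented inputs leaves no trace in any dataset, so nothing
    downstream of it could ever be recovered; benchmarking recovery requires
    the planted signal to traverse the network.  (Training itself still
    samples the full space, silent inputs included.)
    """
    model: LogicModel = {}
    for node in sorted(weights):
        w = weights[node]
        opts = logic.enumerate_combinations(
            node, w.role, list(w.edges),
            edge_p=0.5 if w.edge_p is None else float(w.edge_p[0]),
            p_and=w.p_and,
        )
        combos = [c for c, _ in opts if c.gate != "NONE"]
        probs = np.array([p for c, p in opts if c.gate != "NONE"], dtype=float)
        probs /= probs.sum()
        model[node] = combos[int(rng.choice(len(combos), p=probs))]
    return model


def _random_edge(enzyme: str, substrate: str, res: str, pos: int, rng) -> KpsEdge:
    if rng.random() < 0.7:
        return KpsEdge(enzyme, substrate, res, pos, "experimental", None, None, "synthetic")
    return KpsEdge(
        enzyme, substrate, res, pos, "predicted",
        float(rng.uniform(0.5, 1.0)), float(rng.uniform(0.5, 1.0)), "synthetic",
    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    truth: GroundTruth,
    delta: float | None = None,
    sigma: float | None = None,
    n_bio: int | None = None,
    n_tech: int | None = None,
    missing_rate: float = 0.0,
    inhibition_sign: float = -1.0,
    n_filler: int | None = None,
    seed: int | None = None,
) -> IntensityTable:
    """Draw a noisy phosphopeptide intensity matrix consistent with a truth.

    One peptide per measured data site, plus ``n_filler`` unaffected filler
    peptides (default: four per data site) on decoy proteins outside the
    K/P-S resource.  The fillers emulate the bulk of a discovery
    phosphoproteome that no inhibitor touches -- in a real screen most
    peptides are single-population -- and keep quantile normalization and
    variance shrinkage well behaved.

    Control log2 intensity per peptide is ``N(22, 1.5^2)``; total replicate
    noise ``sigma`` splits into biological and technical components with
    ``sigma_bio = 2 sigma_tech``; each biological replicate additionally
    carries a global batch offset ``N(0, 0.2^2)`` shared across peptides
    (removed downstream by the replicate factor of the linear model).  Sites
    perturbed under a condition in the planted truth are shifted by
    ``inhibition_sign * delta`` log2 units (negative: inhibition decreases
    phosphorylation).  Values return to the raw intensity scale via ``2**x``.
    """
    delta = truth.delta if delta is None else delta
    sigma = truth.sigma if sigma is None else sigma
    n_bio = truth.n_bio if n_bio is None else n_bio
    n_tech = truth.n_tech if n_tech is None else n_tech
    if delta <= 0 or sigma <= 0:
        raise ValueError("delta and sigma must be positive")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    data_sites = sorted(truth.data_sites)
    if n_filler is None:
        # keep the per-condition perturbed fraction in the few-percent regime
        # of discovery data; a small proteome with a large perturbed fraction
        # distorts quantile normalization
        n_filler = 12 * len(data_sites)
    filler = [
        f"F{i + 1:03d}.S{int(rng.integers(1, 999))}" for i in range(n_filler)
    ]
    sites = data_sites + filler
    peptides = [f"pep_{s}" for s in sites]
    conditions = [CONTROL] + sorted(truth.drug_panel)
    sample_rows = []
    for cond in conditions:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                sample_rows.append((f"{cond}_b{b}_t{t}", cond, f"b{b}", f"t{t}", cond == CONTROL))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "condition", "bio_rep", "tech_rep", "is_control"]
    ).set_index("sample")

    sigma_tech = sigma / np.sqrt(5.0)  # sigma_bio = 2 sigma_tech, quadrature sum = sigma
    sigma_bio = 2.0 * sigma_tech
    mu = rng.normal(22.0, 1.5, size=len(peptides))
    batch = {f"b{b}": rng.normal(0.0, 0.2) for b in range(1, n_bio + 1)}

    data = np.empty((len(peptides), len(samples)))
    col = 0
    for cond in conditions:
        perturbed = truth.perturbed.get(cond, set())
        shift = np.array([inhibition_sign * delta if s in perturbed else 0.0 for s in sites])
        for b in range(1, n_bio + 1):
            bio_dev = rng.normal(0.0, sigma_bio, size=len(peptides))
            for t in range(1, n_tech + 1):
                vals = mu + shift + batch[f"b{b}"] + bio_dev + rng.normal(
                    0.0, sigma_tech, size=len(peptides)
                )
                data[:, col] = 2.0**vals
                col += 1
    if missing_rate > 0:
        data[rng.random(data.shape) < missing_rate] = np.nan

    intensities = pd.DataFrame(data, index=peptides, columns=samples.index)
    pep_info = pd.DataFrame(
        {
            "protein": [s.split(".")[0] for s in sites],
            "sites": [s.split(".")[1] for s in sites],
        },
        index=pd.Index(peptides, name="peptide_id"),
    )
    return IntensityTable(intensities, pep_info, samples)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    """Agreement between a consensus network and the planted truth.

    ``node_accuracy`` is the fraction of trainable nodes whose
    maximum-frequency input *edge* is one of the planted edges -- the
    method's headline recovery property, since its result is edge
    frequencies and multi-edge gate combinations structurally stay at
    moderate frequency under the normalized weight correction.
    ``combination_accuracy`` is the stricter requirement that the
    maximum-frequency input combination (edges plus gate) equals the planted
    one exactly.
    """

    edge_precision: float
    edge_recall: float
    node_accuracy: float
    combination_accuracy: float
    n_nodes: int
    per_node: dict[str, bool] = field(default_factory=dict)
    per_node_combination: dict[str, bool] = field(default_factory=dict)


def recovery_metrics(
    consensus: ConsensusNetwork,
    truth: GroundTruth,
    frequencies: dict[str, dict[ComboKey, float]] | None = None,
) -> RecoveryMetrics:
    """Edge precision/recall and per-node top-input accuracy versus the truth.

    Per-node edge frequencies are aggregated from ``frequencies`` (combined
    run output; preferred) or, failing that, from the consensus' retained
    combinations: an edge's frequency at a node is the summed frequency of
    the input combinations containing it.  Edge precision/recall compare the
    union of retained consensus edges against the edges the planted model
    actually uses.
    """
    true_edges = {
        (s, node) for node, comb in truth.true_model.items() for s in comb.sources
    }
    got_edges = consensus.edges
    tp = len(got_edges & true_edges)
    precision = tp / len(got_edges) if got_edges else 0.0
    recall = tp / len(true_edges) if true_edges else 1.0

    per_node: dict[str, bool] = {}
    per_combo: dict[str, bool] = {}
    for node, comb in truth.true_model.items():
        top: ComboKey | None = consensus.top.get(node)
        per_combo[node] = top == comb.key
        table = (
            frequencies.get(node, {}) if frequencies is not None
            else dict(consensus.retained.get(node, []))
        )
        edge_freq: dict[str, float] = {}
        for (sources, _gate), f in table.items():
            for s in sources:
                edge_freq[s] = edge_freq.get(s, 0.0) + f
        if edge_freq:
            top_edge = sorted(edge_freq.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            per_node[node] = top_edge in comb.sources
        else:
            per_node[node] = False
    accuracy = float(np.mean(list(per_node.values()))) if per_node else 1.0
    combo_accuracy = float(np.mean(list(per_combo.values()))) if per_combo else 1.0
    return RecoveryMetrics(
        precision, recall, accuracy, combo_accuracy, len(per_node), per_node, per_combo
    )


def random_baseline_accuracy(truth: GroundTruth, level: str = "combination") -> float:
    """Expected top-input accuracy of a consensus drawn at initial weights.

    ``level="combination"``: probability that a fresh draw from the initial
    distribution lands on the planted combination, averaged over nodes --
    the mean of 1/k for categorical nodes with k combinations (and the exact
    outcome probability for intermediates).  ``level="edge"``: at initial
    weights every edge of a node has the same expected frequency, so the
    top-frequency edge is uniform over the node's m candidates and the
    per-node success probability is |true edges| / m.
    """
    weights = logic.initial_weights(truth.background)
    probs = []
    for node, w in weights.items():
        comb = truth.true_model[node]
        if level == "edge":
            probs.append(len(comb.sources) / len(w.edges))
            continue
        options = logic.enumerate_combinations(
            node, w.role, list(w.edges),
            edge_p=0.5 if w.edge_p is None else float(w.edge_p[0]),
            p_and=w.p_and,
        )
        p = next((p for c, p in options if c.key == comb.key), 0.0)
        probs.append(p)
    return float(np.mean(probs)) if probs else 1.0
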