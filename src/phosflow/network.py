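"""Background networks of kinase/phosphatase -> phosphosite paths.

A kinase/phosphatase-substrate (K/P-S) resource is a bipartite table of
directed interactions enzyme -> (substrate protein, residue, position), each
experimentally demonstrated or predicted.  From it, and a panel of drug
targets plus the set of perturbed measured sites, this module builds the
dataset-specific *background network*: the union of knowledge-compatible
paths through which the inhibitions can reach the perturbed sites.

Construction proceeds at two levels.  At the protein level, an edge K1 -> K2
exists when K1 phosphorylates any site on K2.  The background keeps (i)
protein-level paths among the drug targets up to ``max_target_path`` nodes,
and (ii) protein-level paths from that target network to the kinases that
directly target a perturbed data site, up to ``max_site_path`` nodes.
Retained protein paths are then re-expanded to the site level: each step
K1 -> K2 becomes K1 -> (site on K2) -> K2, the second hop being an artificial
*integrator edge* from the site to its host protein's activity node.
Finally the perturbed data sites are attached as sinks via their incoming
K/P-S edges.

"Paths of up to N nodes" counts protein-level nodes including both endpoints;
an edge is retained when it lies on some directed walk within the limit
(equivalently, when the shortest through-walk fits the budget).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESIDUES = {"S", "T", "Y"}

#: evidence classes, ordered weakest to strongest
EVIDENCE_LEVELS = ("predicted", "experimental")


@dataclass(frozen=True)
class KpsEdge:
    """One kinase/phosphatase -> site interaction."""

    enzyme: str
    substrate: str
    residue: str
    position: int
    evidence: str = "experimental"
    motif_score: float | None = None
    context_score: float | None = None
    source: str = ""

    @property
    def site_id(self) -> str:
        return f"{self.substrate}.{self.residue}{self.position}"


@dataclass
class PathLimits:
    """Node-count budgets for protein-level path search (endpoints included)."""

    max_target_path: int = 7
    max_site_path: int = 5

    def __post_init__(self) -> None:
        if self.max_target_path < 1 or self.max_site_path < 1:
            raise ValueError("path limits must be >= 1")


@dataclass
class BackgroundNetwork:
    """Directed graph of K/P, site and data-site nodes for one dataset.

    Node attribute ``kind`` is one of ``target_kp``, ``kp``, ``site``,
    ``data_site``; edge attribute ``kind`` is ``kps`` or ``integrator`` (kps
    edges additionally carry ``evidence``).  Integrator edges run from a site
    to its own host protein only.
    """

    graph: nx.DiGraph
    drug_panel: dict[str, frozenset[str]]
    unreachable_sites: list[str] = field(default_factory=list)
    limits: PathLimits = field(default_factory=PathLimits)

    @property
    def targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "target_kp"}

    @property
    def data_sites(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "data_site"}

    def node_role(self, node: str) -> str:
        """Sampling role: ``root``, ``sink``, ``intermediate`` or ``integrator``.

        Drug targets are roots (no sampled inputs).  A data site with no
        outgoing edges is a sink and receives exactly one K/P input.  Other
        site nodes are intermediates (free AND/OR logic over their incoming
        K/P edges).  Non-target protein nodes are integrators over the
        integrator edges from their own sites.
        """
        kind = self.graph.nodes[node]["kind"]
        if kind == "target_kp":
            return "root"
        if kind == "kp":
            return "integrator"
        if kind == "data_site" and self.graph.out_degree(node) == 0:
            return "sink"
        return "intermediate"

    def in_edges_of(self, node: str) -> list[str]:
        """Sources of the node's incoming edges, sorted for determinism."""
        return sorted(self.graph.predecessors(node))


# ---------------------------------------------------------------------------
# resource loading
# ---------------------------------------------------------------------------


def load_kps(
    table: pd.DataFrame,
    min_score: float = 0.5,
    enzyme_blocklist: set[str] | None = None,
) -> list[KpsEdge]:
    """Parse and filter a K/P-S interaction table.

    Predicted interactions with either a motif or context score below
    ``min_score`` are excluded, as are predicted interactions for enzymes on
    the blocklist (low-specificity predictors).  Rows with malformed
    positions or residue codes outside S/T/Y are skipped and counted.
    Duplicate (enzyme, substrate, residue, position) rows collapse to a
    single edge keeping the strongest evidence class.
    """
    enzyme_blocklist = enzyme_blocklist or set()
    kept: dict[tuple, KpsEdge] = {}
    n_bad = 0
    for row in table.itertuples(index=False):
        try:
            residue = str(row.residue).strip().upper()
            position = int(row.position)
            enzyme = str(row.enzyme).strip()
            substrate = str(row.substrate).strip()
            evidence = str(getattr(row, "evidence", "experimental")).strip()
        except (ValueError, TypeError):
            n_bad += 1
            continue
        if residue not in RESIDUES or position < 1 or not enzyme or not substrate:
            n_bad += 1
            continue
        motif = _opt_float(getattr(row, "motif_score", None))
        context = _opt_float(getattr(row, "context_score", None))
        if evidence == "predicted":
            if enzyme in enzyme_blocklist:
                continue
            if (motif is None or motif < min_score) or (context is None or context < min_score):
                continue
        edge = KpsEdge(
            enzyme, substrate, residue, position, evidence, motif, context,
            str(getattr(row, "source", "")),
        )
        key = (enzyme, substrate, residue, position)
        prev = kept.get(key)
        if prev is None or EVIDENCE_LEVELS.index(edge.evidence) > EVIDENCE_LEVELS.index(prev.evidence):
            kept[key] = edge
    if n_bad:
        logger.warning("skipped %d malformed K/P-S rows", n_bad)
    return list(kept.values())


def _opt_float(v) -> float | None:
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def randomize_kps(edges: list[KpsEdge], rng: np.random.Generator | int) -> list[KpsEdge]:
    """Shuffle the enzyme column of the bipartite K/P-S table.

    The substrate/site side is untouched, so the multiset of enzymes and all
    substrate-side degrees are preserved exactly.  Used as the randomized-
    network control: training on a shuffled resource measures how much of the
    fit is due to genuine enzyme-substrate specificity.
    """
    if len(edges) < 2:
        raise ValueError("need at least two edges to shuffle")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(len(edges))
    return [
        KpsEdge(
            edges[perm[i]].enzyme,
            e.substrate, e.residue, e.position, e.evidence,
            e.motif_score, e.context_score, e.source,
        )
        for i, e in enumerate(edges)
    ]


# ---------------------------------------------------------------------------
# projections and background construction
# ---------------------------------------------------------------------------


def protein_projection(edges: list[KpsEdge]) -> nx.DiGraph:
    """Directed protein-level graph: K1 -> K2 iff K1 targets any site on K2."""
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.enzyme, e.substrate)
    return g


def build_background(
    edges: list[KpsEdge],
    targets: dict[str, set[str]] | set[str],
    perturbed_sites: set[str],
    limits: PathLimits | None = None,
    evidence_filter: str = "all",
) -> BackgroundNetwork:
    """Construct the dataset-specific background network.

    Parameters
    ----------
    edges
        Filtered K/P-S interactions.
    targets
        Drug panel mapping condition -> target protein ids, or a plain set of
        targets (wrapped into a single-condition panel).
    perturbed_sites
        Site ids (``UPID.RESPOS``) called perturbed in at least one condition.
    limits
        Protein-level path-node budgets (defaults 7 among targets, 5 from the
        target network to site kinases).
    evidence_filter
        ``"all"`` or ``"experimental_only"``.
    """
    limits = limits or PathLimits()
    if isinstance(targets, (set, frozenset)):
        panel = {"perturbation": frozenset(targets)}
    else:
        panel = {c: frozenset(t) for c, t in targets.items()}
    all_targets = set().union(*panel.values()) if panel else set()
    if not all_targets:
        raise ValueError("no drug targets supplied")

    if evidence_filter == "experimental_only":
        edges = [e for e in edges if e.evidence == "experimental"]
    elif evidence_filter != "all":
        raise ValueError(f"unknown evidence_filter {evidence_filter!r}")

    prot = protein_projection(edges)
    # site-level index: (enzyme, host) -> edges, and site -> incoming edges
    by_pair: dict[tuple[str, str], list[KpsEdge]] = defaultdict(list)
    into_site: dict[str, list[KpsEdge]] = defaultdict(list)
    for e in edges:
        by_pair[(e.enzyme, e.substrate)].append(e)
        into_site[e.site_id].append(e)

    in_targets = all_targets & set(prot.nodes)

    # (i) protein-level paths among targets, up to max_target_path nodes
    target_net = _edges_on_walks(prot, in_targets, in_targets, limits.max_target_path)
    target_component = set(in_targets)
    for u, v in target_net:
        target_component.update((u, v))

    # (ii) kinases/phosphatases that directly target a perturbed data site
    site_kps = {e.enzyme for s in perturbed_sites for e in into_site.get(s, [])}

    # (iii) protein-level paths from the target network to those K/P,
    #       up to max_site_path nodes
    site_net = _edges_on_walks(prot, target_component, site_kps, limits.max_site_path)

    retained = target_net | site_net
    # restrict to what the targets can actually reach
    keep_graph = nx.DiGraph()
    keep_graph.add_nodes_from(in_targets)
    keep_graph.add_edges_from(retained)
    reachable: set[str] = set()
    for t in in_targets:
        if t in keep_graph:
            reachable |= {t} | nx.descendants(keep_graph, t)
    retained = {(u, v) for u, v in retained if u in reachable and v in reachable}

    # (iv) expand protein steps to site level with integrator edges
    g = nx.DiGraph()
    for t in in_targets:
        g.add_node(t, kind="target_kp")
    for u, v in sorted(retained):
        for e in by_pair[(u, v)]:
            site = e.site_id
            _ensure_protein(g, u, in_targets)
            _ensure_protein(g, v, in_targets)
            kind = "data_site" if site in perturbed_sites else "site"
            _ensure_site(g, site, kind)
            g.add_edge(u, site, kind="kps", evidence=e.evidence)
            g.add_edge(site, v, kind="integrator", evidence="")

    # (v) attach perturbed data sites as sinks via their K/P-S edges
    unreachable = []
    for s in sorted(perturbed_sites):
        attached = False
        for e in into_site.get(s, []):
            if e.enzyme in g and g.nodes[e.enzyme]["kind"] in ("kp", "target_kp"):
                _ensure_site(g, s, "data_site")
                g.nodes[s]["kind"] = "data_site"
                g.add_edge(e.enzyme, s, kind="kps", evidence=e.evidence)
                attached = True
        if not attached and not (s in g and g.nodes[s]["kind"] == "data_site"):
            unreachable.append(s)
    if unreachable:
        logger.warning("%d perturbed sites unreachable from any target", len(unreachable))

    # any site already in the graph that is measured+perturbed is a data site
    for s in perturbed_sites:
        if s in g:
            g.nodes[s]["kind"] = "data_site"

    _prune_unreachable(g, in_targets & set(g.nodes))
    _annotate_distance(g, in_targets & set(g.nodes))

    bg = BackgroundNetwork(g, panel, unreachable, limits)
    if not bg.data_sites:
        raise ValueError("no perturbed data site reachable from any target: empty trainable network")
    return bg


def _ensure_protein(g: nx.DiGraph, node: str, targets: set[str]) -> None:
    if node not in g:
        g.add_node(node, kind="target_kp" if node in targets else "kp")


def _ensure_site(g: nx.DiGraph, site: str, kind: str) -> None:
    if site not in g:
        g.add_node(site, kind=kind)
    elif kind == "data_site":
        g.nodes[site]["kind"] = "data_site"


def _edges_on_walks(
    g: nx.DiGraph, sources: set[str], sinks: set[str], max_nodes: int
) -> set[tuple[str, str]]:
    """Edges lying on a source->sink directed walk of at most ``max_nodes`` nodes.

    Edge (u, v) qualifies iff min over (s, k) of d(s, u) + d(v, k) + 2 fits
    the node budget, with d the BFS edge distance.
    """
    sources = sources & set(g.nodes)
    sinks = sinks & set(g.nodes)
    if not sources or not sinks or max_nodes < 2:
        return set()
    fwd = {s: nx.single_source_shortest_path_length(g, s, cutoff=max_nodes - 2) for s in sources}
    rg = g.reverse(copy=False)
    bwd = {k: nx.single_source_shortest_path_length(rg, k, cutoff=max_nodes - 2) for k in sinks}
    min_fwd: dict[str, int] = {}
    for dist in fwd.values():
        for n, d in dist.items():
            if d < min_fwd.get(n, np.inf):
                min_fwd[n] = d
    min_bwd: dict[str, int] = {}
    for dist in bwd.values():
        for n, d in dist.items():
            if d < min_bwd.get(n, np.inf):
                min_bwd[n] = d
    out = set()
    for u, v in g.edges:
        du = min_fwd.get(u)
        dv = min_bwd.get(v)
        if du is not None and dv is not None and du + dv + 2 <= max_nodes:
            out.add((u, v))
    return out


def _prune_unreachable(g: nx.DiGraph, targets: set[str]) -> None:
    reachable: set[str] = set(targets)
    for t in targets:
        reachable |= nx.descendants(g, t)
    g.remove_nodes_from([n for n in list(g.nodes) if n not in reachable])


def _annotate_distance(g: nx.DiGraph, targets: set[str]) -> None:
    """Store each node's BFS distance from the nearest drug target."""
    dist: dict[str, int] = {}
    for t in targets:
        for n, d in nx.single_source_shortest_path_length(g, t).items():
            if d < dist.get(n, np.inf):
                dist[n] = d
    for n in g.nodes:
        g.nodes[n]["distance"] = dist.get(n, -1)
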