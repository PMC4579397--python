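"""Shared fixtures: small hand-built networks and a session-scoped benchmark."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phosflow import pipeline, synthetic
from phosflow.network import BackgroundNetwork, KpsEdge, PathLimits
from phosflow.scoring import SMatrix

import networkx as nx


def make_background(
    edges: list[tuple[str, str, str]],
    kinds: dict[str, str],
    panel: dict[str, frozenset[str]],
) -> BackgroundNetwork:
    """Assemble a background graph directly from (source, kind, target) triples."""
    g = nx.DiGraph()
    for node, kind in kinds.items():
        g.add_node(node, kind=kind, distance=0)
    for u, kind, v in edges:
        g.add_edge(u, v, kind=kind, evidence="experimental" if kind == "kps" else "")
    return BackgroundNetwork(g, panel, [], PathLimits())


def make_smatrix(site_s: dict[str, dict[str, float]], control: str = "DMSO") -> SMatrix:
    """Site-level evidence matrix from {condition: {site: S}} (peptides 1:1)."""
    df = pd.DataFrame(site_s)
    s = df.copy()
    s.index = [f"pep_{i}" for i in s.index]
    labels = s.map(lambda v: "perturbed" if v < -0.5 else ("control" if v > 0.5 else "undetermined"))
    return SMatrix(s, labels, df, control)


@pytest.fixture(scope="session")
def truth():
    """The benchmark ground truth: 20 kinases, 50 sites, 4 drugs."""
    return synthetic.generate_truth(n_kp=20, n_sites=50, n_drugs=4, seed=1)


@pytest.fixture(scope="session")
def benchmark_evidence(truth):
    """Evidence matrix from one simulated dataset of the benchmark truth."""
    raw = synthetic.simulate_dataset(truth, seed=4)
    effects, fits, smatrix = pipeline.score_data(raw, seed=0)
    return raw, effects, fits, smatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
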