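"""Flat-file formats: TSV tables, SIF networks, YAML configuration.

All outputs are tab-separated text with deterministic row ordering (sorted by
node/edge ids) so reruns diff cleanly, and networks are written as SIF plus
sidecar attribute tables that Cytoscape's table import reads directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from phosflow.logic import InputCombination, LogicModel
from phosflow.network import BackgroundNetwork, KpsEdge, PathLimits
from phosflow.scoring import EffectTable, GmmFit, IntensityTable, SMatrix, classify
from phosflow.training import ComboKey, ConsensusNetwork, TrainingParams

# ---------------------------------------------------------------------------
# intensity matrix + sample annotation
# ---------------------------------------------------------------------------


def read_intensity_table(intensity_path: str | Path, samples_path: str | Path) -> IntensityTable:
    """Read an intensity TSV (peptide_id, protein, sites, <samples...>) and annotation."""
    df = pd.read_csv(intensity_path, sep="\t", dtype={"peptide_id": str})
    for col in ("peptide_id", "protein", "sites"):
        if col not in df.columns:
            raise ValueError(f"{intensity_path}: missing column {col!r}")
    df = df.set_index("peptide_id")
    peptides = df[["protein", "sites"]].copy()
    intensities = df.drop(columns=["protein", "sites"]).astype(float)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str).set_index("sample")
    samples["is_control"] = samples["is_control"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "yes")
    )
    missing = [s for s in intensities.columns if s not in samples.index]
    if missing:
        raise ValueError(f"{samples_path}: samples without annotation: {missing}")
    return IntensityTable(intensities, peptides, samples.loc[intensities.columns])


def write_intensity_table(table: IntensityTable, intensity_path: str | Path, samples_path: str | Path) -> None:
    out = pd.concat([table.peptides, table.intensities], axis=1)
    out.index.name = "peptide_id"
    out.to_csv(intensity_path, sep="\t")
    samples = table.samples.copy()
    samples["is_control"] = samples["is_control"].map(lambda b: "true" if b else "false")
    samples.to_csv(samples_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# K/P-S resource and drug panel
# ---------------------------------------------------------------------------

KPS_COLUMNS = ["enzyme", "substrate", "residue", "position", "evidence",
               "motif_score", "context_score", "source"]


def read_kps_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("enzyme", "substrate", "residue", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in KPS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col.endswith("_score") else ""
    return df[KPS_COLUMNS]


def write_kps_table(edges: list[KpsEdge] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(edges, pd.DataFrame):
        df = edges
    else:
        df = pd.DataFrame(
            [(e.enzyme, e.substrate, e.residue, e.position, e.evidence,
              e.motif_score, e.context_score, e.source) for e in edges],
            columns=KPS_COLUMNS,
        )
    df.sort_values(["enzyme", "substrate", "position"]).to_csv(path, sep="\t", index=False)


def read_drug_panel(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a drug panel TSV (condition, targets semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    panel = {}
    for row in df.itertuples(index=False):
        panel[row.condition] = frozenset(
            t.strip() for t in str(row.targets).split(";") if t.strip()
        )
    return panel


def write_drug_panel(panel: dict[str, frozenset[str]], path: str | Path) -> None:
    rows = [(c, ";".join(sorted(t))) for c, t in sorted(panel.items())]
    pd.DataFrame(rows, columns=["condition", "targets"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scoring outputs
# ---------------------------------------------------------------------------


def write_effect_table(effects: EffectTable, path: str | Path) -> None:
    effects.table.sort_values(["peptide_id", "condition"]).to_csv(path, sep="\t", index=False)


def write_gmm_summary(fits: dict[str, GmmFit], path: str | Path) -> None:
    rows = []
    for pid in sorted(fits):
        f = fits[pid]
        rows.append(
            (pid, f.n_components,
             ";".join(f"{m:.6g}" for m in f.means),
             ";".join(f"{s:.6g}" for s in f.sds),
             ";".join(f"{w:.6g}" for w in f.weights),
             f.bic, f.overlap, f.boolean_ok)
        )
    pd.DataFrame(
        rows, columns=["peptide_id", "K", "means", "sds", "weights", "BIC", "overlap", "boolean_ok"]
    ).to_csv(path, sep="\t", index=False)


def write_smatrix(smatrix: SMatrix, peptide_path: str | Path, site_path: str | Path) -> None:
    s = smatrix.s.sort_index()
    s.index.name = "peptide_id"
    s.to_csv(peptide_path, sep="\t")
    site = smatrix.site_s.sort_index()
    site.index.name = "site"
    site.to_csv(site_path, sep="\t")


def read_smatrix(
    peptide_path: str | Path, site_path: str | Path, control_condition: str, s_cut: float = 0.5
) -> SMatrix:
    s = pd.read_csv(peptide_path, sep="\t", index_col="peptide_id")
    site_s = pd.read_csv(site_path, sep="\t", index_col="site")
    labels = s.map(lambda v: classify(v, s_cut) if np.isfinite(v) else "")
    return SMatrix(s, labels, site_s, control_condition, s_cut)


# ---------------------------------------------------------------------------
# networks: SIF + attribute sidecars
# ---------------------------------------------------------------------------


def _relation(data: dict) -> str:
    kind = data.get("kind", "kps")
    if kind == "integrator":
        return "integrator"
    evidence = data.get("evidence") or "experimental"
    return f"kps-{evidence}"


def write_sif(graph: nx.DiGraph, path: str | Path) -> None:
    """Write a directed graph as ``source<TAB>relation<TAB>target`` lines."""
    lines = []
    for u, v, data in graph.edges(data=True):
        lines.append((u, _relation(data), v))
    lines.sort()
    with open(path, "w") as fh:
        for u, rel, v in lines:
            fh.write(f"{u}\t{rel}\t{v}\n")


def write_background(bg: BackgroundNetwork, outdir: str | Path, prefix: str = "background") -> None:
    outdir = Path(outdir)
    write_sif(bg.graph, outdir / f"{prefix}.sif")
    rows = [
        (n, d["kind"], d.get("distance", -1)) for n, d in sorted(bg.graph.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["node", "kind", "distance_from_target"]).to_csv(
        outdir / f"{prefix}_nodes.tsv", sep="\t", index=False
    )
    with open(outdir / f"{prefix}_unreachable.txt", "w") as fh:
        for s in bg.unreachable_sites:
            fh.write(s + "\n")


def read_background(
    sif_path: str | Path,
    nodes_path: str | Path,
    panel: dict[str, frozenset[str]],
    limits: PathLimits | None = None,
) -> BackgroundNetwork:
    g = nx.DiGraph()
    nodes = pd.read_csv(nodes_path, sep="\t")
    for row in nodes.itertuples(index=False):
        g.add_node(row.node, kind=row.kind, distance=int(row.distance_from_target))
    with open(sif_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{sif_path}: malformed SIF line {line!r}")
            u, rel, v = parts
            if rel == "integrator":
                g.add_edge(u, v, kind="integrator", evidence="")
            elif rel.startswith("kps-"):
                g.add_edge(u, v, kind="kps", evidence=rel[4:])
            else:
                raise ValueError(f"{sif_path}: unknown relation {rel!r}")
    return BackgroundNetwork(g, panel, [], limits or PathLimits())


# ---------------------------------------------------------------------------
# models, frequencies, consensus
# ---------------------------------------------------------------------------


def write_model(model: LogicModel, path: str | Path) -> None:
    rows = [(n, ";".join(c.sources), c.gate) for n, c in sorted(model.items())]
    pd.DataFrame(rows, columns=["node", "sources", "gate"]).to_csv(path, sep="\t", index=False)


def read_model(path: str | Path) -> LogicModel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    model: LogicModel = {}
    for row in df.itertuples(index=False):
        sources = tuple(s for s in row.sources.split(";") if s)
        model[row.node] = InputCombination(row.node, sources, row.gate)
    return model


def write_frequencies(freqs: dict[str, dict[ComboKey, float]], path: str | Path) -> None:
    rows = []
    for node in sorted(freqs):
        for (sources, gate), f in sorted(freqs[node].items()):
            rows.append((node, ";".join(sources), gate, f))
    pd.DataFrame(rows, columns=["node", "sources", "gate", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_frequencies(path: str | Path) -> dict[str, dict[ComboKey, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "sources": str, "gate": str})
    out: dict[str, dict[ComboKey, float]] = {}
    for row in df.itertuples(index=False):
        sources = tuple(s for s in str(row.sources).split(";") if s and s != "nan")
        out.setdefault(row.node, {})[(sources, row.gate)] = float(row.frequency)
    return out


def write_consensus(consensus: ConsensusNetwork, outdir: str | Path, prefix: str = "consensus") -> None:
    outdir = Path(outdir)
    write_sif(consensus.graph, outdir / f"{prefix}.sif")
    rows = [
        (u, _relation(d), v, d["frequency"], d.get("gate", ""))
        for u, v, d in sorted(consensus.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "relation", "target", "frequency", "gate"]).to_csv(
        outdir / f"{prefix}_edges.tsv", sep="\t", index=False
    )
    node_rows = []
    for node in sorted(consensus.retained):
        for (sources, gate), f in consensus.retained[node]:
            node_rows.append((node, ";".join(sources), gate, f, (sources, gate) == consensus.top[node]))
    pd.DataFrame(
        node_rows, columns=["node", "sources", "gate", "frequency", "is_top"]
    ).to_csv(outdir / f"{prefix}_nodes.tsv", sep="\t", index=False)


def write_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    trajectory.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    intensities: str = "intensities.tsv"
    samples: str = "samples.tsv"
    kps: str = "kps.tsv"
    panel: str = "panel.tsv"
    outdir: str = "results"
    control_condition: str = "DMSO"
    seed: int = 0
    s_cut: float = 0.5
    overlap_max: float = 0.10
    overlap_normalized: bool = False
    min_score: float = 0.5
    evidence_filter: str = "all"
    max_target_path: int = 7
    max_site_path: int = 5
    augmentation: str | None = None
    training: TrainingParams = dataclasses.field(default_factory=TrainingParams)

    @property
    def limits(self) -> PathLimits:
        return PathLimits(self.max_target_path, self.max_site_path)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    training = raw.pop("training", {})
    if not isinstance(training, dict):
        raise ValueError(f"{path}: 'training' must be a mapping")
    cfg = RunConfig(**raw)
    cfg.training = TrainingParams(**training)
    if cfg.training.seed == 0:
        cfg.training.seed = cfg.seed
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_runlog(outdir: str | Path, stage: str, info: dict) -> None:
    path = Path(outdir) / f"runlog_{stage}.json"
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True, default=str)
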