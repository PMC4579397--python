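"""High-level orchestration: raw intensities to consensus network in memory.

These functions chain the scoring, network and training modules without
touching the filesystem; the command-line interface wraps them with the
flat-file formats from :mod:`phosflow.io`.
"""

from __future__ import annotations

import logging

import numpy as np

from phosflow import network, scoring, training
from phosflow.network import BackgroundNetwork, KpsEdge, PathLimits
from phosflow.scoring import EffectTable, GmmFit, IntensityTable, SMatrix
from phosflow.synthetic import GroundTruth, RecoveryMetrics, recovery_metrics, simulate_dataset
from phosflow.training import ConsensusNetwork, TrainingParams, TrainingResult

logger = logging.getLogger(__name__)


def score_data(
    raw: IntensityTable,
    seed: int = 0,
    s_cut: float = scoring.S_CUT,
    overlap_normalized: bool = False,
) -> tuple[EffectTable, dict[str, GmmFit], SMatrix]:
    """Normalize, fit effects, fit per-peptide mixtures, and build the S matrix."""
    norm = scoring.normalize_intensities(raw)
    effects = scoring.fit_effects(norm)
    fits: dict[str, GmmFit] = {}
    for pid in effects.logfc.index:
        vec = effects.effects_vector(pid).dropna()
        if len(vec) < 3:
            continue
        fits[pid] = scoring.fit_gmm(
            vec, peptide_id=pid, seed=seed, overlap_normalized=overlap_normalized
        )
    site_map = {pid: raw.site_ids(pid) for pid in fits}
    smatrix = scoring.build_smatrix(effects, fits, site_map, s_cut)
    return effects, fits, smatrix


def build_network_from_smatrix(
    edges: list[KpsEdge],
    panel: dict[str, frozenset[str]],
    smatrix: SMatrix,
    limits: PathLimits | None = None,
    evidence_filter: str = "all",
) -> BackgroundNetwork:
    """Background network for the sites perturbed in at least one condition."""
    perturbed: set[str] = set()
    for cond in smatrix.data_conditions:
        perturbed |= smatrix.perturbed_sites(cond)
    if not perturbed:
        raise ValueError("no site is called perturbed in any condition")
    return network.build_background(edges, panel, perturbed, limits, evidence_filter)


def run_benchmark(
    truth: GroundTruth,
    params: TrainingParams,
    seed: int = 0,
    evidence_filter: str = "all",
) -> tuple[RecoveryMetrics, ConsensusNetwork, SMatrix, list[TrainingResult]]:
    """End-to-end parameter-recovery benchmark on a planted ground truth.

    Simulates a dataset from the truth, runs the scoring pipeline to an
    evidence matrix, trains on the truth's background against that evidence,
    and measures how well the consensus recovers the planted model.  Training
    runs on the truth's own background (built from the truly perturbed
    sites) so per-node recovery is well defined; sites the scoring stage
    fails to detect simply contribute no evidence.
    """
    raw = simulate_dataset(truth, seed=seed + 1)
    _, _, smatrix = score_data(raw, seed=seed)
    consensus, freqs, results = training.fit(truth.background, smatrix, params)
    return recovery_metrics(consensus, truth, freqs), consensus, smatrix, results


def target_discrimination(
    truth: GroundTruth,
    smatrix: SMatrix,
    params: TrainingParams,
    condition: str | None = None,
    n_shuffles: int = 3,
) -> dict[str, float]:
    """Randomized-network and wrong-target controls for one condition's data.

    Mirrors the design of the method's validity check: take the evidence of
    a single drug treatment and train three settings against it, returning
    each setting's final-generation population mean score (lower is a better
    fit):

    * ``true`` -- the true K/P-S resource with the drug's true target;
    * ``wrong_target`` -- the true resource with another drug's target;
    * ``shuffled`` -- enzyme-shuffled resources with the true target,
      averaged over ``n_shuffles`` shuffles that yield a trainable network.

    Prior knowledge at both levels is informative when
    true < shuffled < wrong_target.  Scores are comparable across settings
    because evidence at sites a background cannot reach still counts as
    missed predictions.
    """
    conds = sorted(c for c in smatrix.data_conditions if c in truth.drug_panel)
    condition = condition or conds[0]
    evidence = smatrix.subset([condition])
    perturbed = evidence.perturbed_sites(condition)
    true_target = truth.drug_panel[condition]

    def final_mean(background) -> float:
        _, _, results = training.fit(background, evidence, params)
        return float(np.mean([r.trajectory["mean_score"].iloc[-1] for r in results]))

    out: dict[str, float] = {
        "true": final_mean(
            network.build_background(
                truth.kps_edges, {condition: true_target}, perturbed, truth.background.limits
            )
        )
    }

    wrong_candidates = [t for c in conds for t in [truth.drug_panel[c]] if t != true_target]
    wrong_bg = None
    for wrong in wrong_candidates:
        try:
            wrong_bg = network.build_background(
                truth.kps_edges, {condition: wrong}, perturbed, truth.background.limits
            )
            break
        except ValueError:
            continue
    if wrong_bg is None:
        raise RuntimeError("no alternative drug target yields a trainable network")
    out["wrong_target"] = final_mean(wrong_bg)

    shuffle_scores = []
    rng = np.random.default_rng(params.seed)
    for _ in range(n_shuffles):
        shuffled = network.randomize_kps(truth.kps_edges, rng)
        try:
            shuf_bg = network.build_background(
                shuffled, {condition: true_target}, perturbed, truth.background.limits
            )
            shuffle_scores.append(final_mean(shuf_bg))
        except ValueError:
            logger.warning("a shuffled resource left no trainable network; skipped")
    if not shuffle_scores:
        raise RuntimeError("no shuffled resource yielded a trainable network")
    out["shuffled"] = float(np.mean(shuffle_scores))
    return out
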