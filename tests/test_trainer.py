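"""Model scoring, best-family selection, weight correction, training loop."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

from phosflow.logic import InputCombination, initial_weights, predict_conditions
from phosflow.training import (
    TrainingParams,
    combine_runs,
    consensus_network,
    score_model,
    select_best,
    train,
    update_weights,
)
from tests.conftest import make_background, make_smatrix


@pytest.fixture()
def two_site_smatrix():
    return make_smatrix({"drug": {"s1": -1.2, "s2": 0.8}})


class TestScoreModel:
    def test_predict_only_negative_site(self, two_site_smatrix):
        score = score_model({"drug": {"s1"}}, two_site_smatrix)
        assert score.score == pytest.approx(-1.2)

    def test_predict_both(self, two_site_smatrix):
        score = score_model({"drug": {"s1", "s2"}}, two_site_smatrix)
        assert score.score == pytest.approx(-0.4)

    def test_predict_none_pays_false_negative(self, two_site_smatrix):
        score = score_model({"drug": set()}, two_site_smatrix)
        assert score.score == pytest.approx(1.2)

    def test_true_negatives_contribute_nothing(self):
        # adding control-state (positive S) sites that are not predicted must
        # leave the score untouched
        base = make_smatrix({"drug": {"s1": -1.2, "s2": 0.8}})
        extended = make_smatrix({"drug": {"s1": -1.2, "s2": 0.8, "s3": 2.5, "s4": 0.1}})
        for pred in [set(), {"s1"}, {"s1", "s2"}]:
            assert score_model({"drug": pred}, base).score == pytest.approx(
                score_model({"drug": pred}, extended).score
            )

    def test_size_penalty_additive(self, two_site_smatrix):
        s0 = score_model({"drug": {"s1"}}, two_site_smatrix, sizeP=0.0, n_edges=7)
        s1 = score_model({"drug": {"s1"}}, two_site_smatrix, sizeP=1.0, n_edges=7)
        assert s1.score - s0.score == pytest.approx(7.0)

    def test_decomposition_adds_up(self):
        sm = make_smatrix({"d1": {"s1": -1.0, "s2": 0.5, "s3": -2.0},
                           "d2": {"s1": 0.3, "s2": -0.7, "s3": -0.1}})
        score = score_model({"d1": {"s1", "s2"}, "d2": {"s2", "s3"}}, sm, sizeP=1, n_edges=3)
        assert score.score == pytest.approx(
            score.tp_sum + score.fp_sum - score.fn_sum + score.size_penalty
        )
        assert score.score == pytest.approx(sum(score.per_condition.values()) + 3.0)

    def test_identical_target_drugs_accumulate(self):
        sm = make_smatrix({"d1": {"s1": -1.0}, "d2": {"s1": -1.0}})
        score = score_model({"d1": {"s1"}, "d2": {"s1"}}, sm)
        assert score.score == pytest.approx(-2.0)


class TestSelectBest:
    def test_zero_tolerance_gives_argmin(self):
        assert list(select_best(np.array([-3.0, -2.0, -3.0]), 0.0)) == [0, 2]

    def test_fifteen_percent_example(self):
        idx = select_best(np.array([-10.0, -9.0, -5.0]), 0.15)
        assert list(idx) == [0, 1]  # threshold -8.5

    def test_all_equal_selected(self):
        assert len(select_best(np.full(5, -1.0), 0.15)) == 5

    def test_absolute_offset_mode(self):
        idx = select_best(np.array([-10.0, -9.5, -5.0]), 1.0, absolute=True)
        assert list(idx) == [0, 1]


def integrator_weights():
    bg = make_background(
        edges=[("K1", "kps", "A.S1"), ("K2", "kps", "A.S2"),
               ("A.S1", "integrator", "A"), ("A.S2", "integrator", "A"),
               ("A", "kps", "P1.S9")],
        kinds={"K1": "target_kp", "K2": "target_kp", "A.S1": "site", "A.S2": "site",
               "A": "kp", "P1.S9": "data_site"},
        panel={"d": frozenset({"K1", "K2"})},
    )
    return initial_weights(bg)


class TestUpdateWeights:
    def test_integrator_worked_example(self):
        w = integrator_weights()
        a = w["A"]
        keys = [c.key for c in a.combos]
        single1 = keys.index((("A.S1",), "SINGLE"))
        both = keys.index((("A.S1", "A.S2"), "AND"))
        none = keys.index(((), "NONE"))
        single2 = keys.index((("A.S2",), "SINGLE"))
        new = update_weights({"A": a}, {"A": {single1: 0.5, both: 0.5}}, cap=2)
        got = new["A"].probs
        assert got[single1] == pytest.approx(2 / 6)
        assert got[single2] == pytest.approx(1 / 6)
        assert got[both] == pytest.approx(2 / 6)
        assert got[none] == pytest.approx(1 / 6)

    def test_sink_worked_example(self):
        w = integrator_weights()["P1.S9"]
        # a two-input sink: rebuild with two kinase inputs
        bg = make_background(
            edges=[("K1", "kps", "P1.S9"), ("K2", "kps", "P1.S9")],
            kinds={"K1": "target_kp", "K2": "target_kp", "P1.S9": "data_site"},
            panel={"d": frozenset({"K1"})},
        )
        sink = initial_weights(bg)["P1.S9"]
        first = [c.key for c in sink.combos].index((("K1",), "SINGLE"))
        new = update_weights({"P1.S9": sink}, {"P1.S9": {first: 1.0}}, cap=2)
        assert new["P1.S9"].probs[first] == pytest.approx(0.75)
        assert new["P1.S9"].probs[1 - first] == pytest.approx(0.25)

    def test_intermediate_worked_example(self):
        bg = make_background(
            edges=[("K1", "kps", "A.S1"), ("K2", "kps", "A.S1"),
                   ("A.S1", "integrator", "A"), ("A", "kps", "P1.S2")],
            kinds={"K1": "target_kp", "K2": "target_kp", "A.S1": "site",
                   "A": "kp", "P1.S2": "data_site"},
            panel={"d": frozenset({"K1"})},
        )
        inter = initial_weights(bg)["A.S1"]
        new = update_weights(
            {"A.S1": inter}, {"A.S1": {"K1": 1.0, "K2": 0.5, "AND": 0.5}}, cap=2
        )
        got = new["A.S1"]
        assert got.edge_p[got.edges.index("K1")] == pytest.approx(3 / 5)
        assert got.edge_p[got.edges.index("K2")] == pytest.approx(2 / 5)
        assert got.p_and == pytest.approx((0.5 + 0.5) / 2)

    def test_missing_and_frequency_leaves_gate_unchanged(self):
        bg = make_background(
            edges=[("K1", "kps", "A.S1"), ("K2", "kps", "A.S1"),
                   ("A.S1", "integrator", "A"), ("A", "kps", "P1.S2")],
            kinds={"K1": "target_kp", "K2": "target_kp", "A.S1": "site",
                   "A": "kp", "P1.S2": "data_site"},
            panel={"d": frozenset({"K1"})},
        )
        inter = initial_weights(bg)["A.S1"]
        new = update_weights({"A.S1": inter}, {"A.S1": {"K1": 1.0}}, cap=2)
        assert new["A.S1"].p_and == pytest.approx(0.5)

    def test_cap_zero_reproduces_uniform(self):
        w = integrator_weights()
        new = update_weights(w, {"A": {0: 1.0}}, cap=0)
        assert np.allclose(new["A"].probs, 0.25)

    def test_probabilities_conserved_and_cap_bounded(self, rng):
        w = integrator_weights()
        k = len(w["A"].combos)
        for cap in (1, 2, 5, 20):
            f = rng.dirichlet(np.ones(k))
            new = update_weights({"A": w["A"]}, {"A": dict(enumerate(f))}, cap=cap)
            probs = new["A"].probs
            assert probs.sum() == pytest.approx(1.0)
            assert probs.max() <= (1 + cap) / (k + cap) + 1e-12

    def test_negative_cap_rejected(self):
        with pytest.raises(ValueError):
            update_weights(integrator_weights(), {}, cap=-1)


def single_path_background():
    return make_background(
        edges=[("T", "kps", "A.S1"), ("A.S1", "integrator", "A"), ("A", "kps", "P1.S2")],
        kinds={"T": "target_kp", "A.S1": "site", "A": "kp", "P1.S2": "data_site"},
        panel={"drug": frozenset({"T"})},
    )


class TestTrain:
    def test_bookkeeping_rows_and_population_size(self):
        bg = single_path_background()
        sm = make_smatrix({"drug": {"P1.S2": -3.0}})
        params = TrainingParams(n=50, generations=5, cap=5, tol_best=0.3, sizeP=1, seed=0,
                                patience=10**9)
        res = train(bg, sm, params)
        assert len(res.trajectory) == 5
        assert (res.trajectory["family_size"] <= 50).all()
        assert (res.trajectory["family_size"] >= 1).all()

    def test_single_path_converges_to_unique_solution(self):
        bg = single_path_background()
        sm = make_smatrix({"drug": {"P1.S2": -3.0}})
        params = TrainingParams(n=200, generations=10, cap=5, tol_best=0.0, sizeP=0, seed=1)
        res = train(bg, sm, params)
        # the only consistent model uses every edge of the path
        assert res.frequencies["P1.S2"][(("A",), "SINGLE")] == pytest.approx(1.0, abs=0.02)
        assert res.frequencies["A"][(("A.S1",), "SINGLE")] == pytest.approx(1.0, abs=0.05)
        assert res.frequencies["A.S1"][(("T",), "SINGLE")] == pytest.approx(1.0, abs=0.05)

    def test_selection_pressure_reduces_mean_score(self, truth, benchmark_evidence):
        _, _, _, smatrix = benchmark_evidence
        params = TrainingParams(n=200, generations=8, cap=5, tol_best=0.3, sizeP=0, seed=3)
        res = train(truth.background, smatrix, params)
        assert res.trajectory["mean_score"].iloc[-1] <= res.trajectory["mean_score"].iloc[0]

    def test_refuses_without_reachable_evidence(self):
        bg = single_path_background()
        sm = make_smatrix({"drug": {"OTHER.S9": -3.0}})
        with pytest.raises(ValueError):
            train(bg, sm, TrainingParams(n=10, generations=2))

    def test_exhaustive_enumeration_matches_training_minimum(self):
        """Small-space oracle: training finds the globally optimal score."""
        bg = make_background(
            edges=[("T", "kps", "A.S1"), ("A.S1", "integrator", "A"),
                   ("A", "kps", "P1.S2"), ("T", "kps", "P1.S2"),
                   ("A", "kps", "P1.S3")],
            kinds={"T": "target_kp", "A.S1": "site", "A": "kp",
                   "P1.S2": "data_site", "P1.S3": "data_site"},
            panel={"drug": frozenset({"T"})},
        )
        sm = make_smatrix({"drug": {"P1.S2": -2.0, "P1.S3": 0.9}})
        weights = initial_weights(bg)
        sizeP = 1.0
        combos_per_node = {
            node: [c for c, _ in __import__("phosflow.logic", fromlist=["enumerate_combinations"])
                   .enumerate_combinations(node, w.role, list(w.edges))]
            for node, w in weights.items()
        }
        best = np.inf
        nodes = sorted(combos_per_node)
        for assignment in product(*(combos_per_node[n] for n in nodes)):
            model = dict(zip(nodes, assignment))
            preds, _ = predict_conditions(model, bg.drug_panel, set(bg.graph.nodes), bg.data_sites)
            n_edges = sum(len(c.sources) for c in model.values())
            best = min(best, score_model(preds, sm, sizeP, n_edges).score)
        params = TrainingParams(n=500, generations=10, cap=5, tol_best=0.3, sizeP=sizeP, seed=5)
        res = train(bg, sm, params)
        assert res.trajectory["min_score"].min() == pytest.approx(best)


class TestCombineAndConsensus:
    def test_single_run_identity(self):
        bg = single_path_background()
        sm = make_smatrix({"drug": {"P1.S2": -3.0}})
        res = train(bg, sm, TrainingParams(n=50, generations=3, seed=0))
        assert combine_runs([res]) == res.frequencies

    def test_mean_of_two_runs(self):
        f1 = {"n": {(("a",), "SINGLE"): 0.2}}
        f2 = {"n": {(("a",), "SINGLE"): 0.6}}
        r1 = _fake_result(f1)
        r2 = _fake_result(f2)
        assert combine_runs([r1, r2])["n"][(("a",), "SINGLE")] == pytest.approx(0.4)

    def test_mismatched_runs_rejected(self):
        r1 = _fake_result({"n": {}})
        r2 = _fake_result({"m": {}})
        with pytest.raises(ValueError):
            combine_runs([r1, r2])

    def test_majority_voting_argmax(self):
        freqs = {"n": {(("e1",), "SINGLE"): 0.7, (("e2",), "SINGLE"): 0.3}}
        cons = consensus_network(freqs, consensus_tol=0.0)
        assert cons.top["n"] == (("e1",), "SINGLE")
        assert cons.retained["n"] == [((("e1",), "SINGLE"), 0.7)]

    def test_twenty_percent_tolerance_keeps_near_best(self):
        freqs = {"n": {(("e1",), "SINGLE"): 0.5, (("e2",), "SINGLE"): 0.45,
                       (("e3",), "SINGLE"): 0.1}}
        cons = consensus_network(freqs, consensus_tol=0.20)
        kept = {k for k, _ in cons.retained["n"]}
        assert kept == {(("e1",), "SINGLE"), (("e2",), "SINGLE")}

    def test_full_tolerance_keeps_all_nonzero(self):
        freqs = {"n": {(("e1",), "SINGLE"): 0.5, (("e2",), "SINGLE"): 0.01,
                       (("e3",), "SINGLE"): 0.0}}
        cons = consensus_network(freqs, consensus_tol=1.0)
        kept = {k for k, _ in cons.retained["n"]}
        assert kept == {(("e1",), "SINGLE"), (("e2",), "SINGLE")}

    def test_all_zero_node_omitted(self):
        freqs = {"n": {(("e1",), "SINGLE"): 0.0}}
        cons = consensus_network(freqs, consensus_tol=0.2)
        assert "n" not in cons.retained


def _fake_result(freqs):
    from phosflow.training import TrainingResult

    return TrainingResult(pd.DataFrame(), freqs, {}, None, TrainingParams())


class TestWeightUpdateProperties:
    """Algebraic invariants of the correction rule, over arbitrary inputs."""

    from hypothesis import given, settings, strategies as st

    @given(
        freqs=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        cap=st.floats(0, 50),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_probabilities_stay_normalized_and_ordered(self, freqs, cap):
        w = integrator_weights()["A"]
        new = update_weights({"A": w}, {"A": dict(enumerate(freqs))}, cap=cap)
        probs = new["A"].probs
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()
        # a more frequent input never ends up with a smaller probability
        order = np.argsort(freqs)
        assert (np.diff(probs[order]) >= -1e-12).all()

    @given(scores=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           tol=st.floats(0, 1))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_best_family_always_contains_argmin(self, scores, tol):
        scores = np.array(scores)
        idx = select_best(scores, tol)
        assert scores.argmin() in idx
        assert (scores[idx] <= scores.min() + tol * abs(scores.min()) + 1e-9).all()
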