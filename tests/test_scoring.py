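"""Scoring stage: normalization, moderated effects, mixtures, evidence scores."""

from __future__ import annotations

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from phosflow import scoring
from phosflow.scoring import (
    GmmFit,
    IntensityTable,
    classify,
    compute_sij,
    fit_effects,
    fit_gmm,
    normalize_intensities,
    overlap_fraction,
)


def _table(values: np.ndarray, conditions, bio=None, tech=None, control="ctrl") -> IntensityTable:
    n_pep, n_samp = values.shape
    peptides = pd.DataFrame(
        {"protein": [f"P{i}" for i in range(n_pep)], "sites": [f"S{i + 1}" for i in range(n_pep)]},
        index=[f"pep{i}" for i in range(n_pep)],
    )
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "bio_rep": bio or ["b1"] * n_samp,
            "tech_rep": tech or [f"t{i}" for i in range(n_samp)],
            "is_control": [c == control for c in conditions],
        },
        index=[f"s{i}" for i in range(n_samp)],
    )
    ints = pd.DataFrame(values, index=peptides.index, columns=samples.index)
    return IntensityTable(ints, peptides, samples)


class TestNormalize:
    def test_identical_columns_reduce_to_log2(self):
        v = np.array([[4.0, 4.0], [16.0, 16.0], [2.0, 2.0]])
        t = _table(v, ["ctrl", "drug"])
        out = normalize_intensities(t).intensities.to_numpy()
        assert np.allclose(out, np.log2(v))

    def test_single_sample_is_log2_only(self):
        v = np.array([[5.0], [1.0], [9.0]])
        t = _table(v, ["ctrl"])
        out = normalize_intensities(t).intensities.to_numpy()
        assert np.allclose(out, np.log2(v))

    def test_toy_matrix_matches_rank_mean_oracle(self):
        # classic quantile normalization oracle: replace each column's k-th
        # order statistic by the mean of the k-th order statistics
        v = np.array([[2.0, 8.0], [4.0, 2.0], [8.0, 4.0]])
        lg = np.log2(v)
        ref = (np.sort(lg[:, 0]) + np.sort(lg[:, 1])) / 2
        expected = np.empty_like(lg)
        for j in range(2):
            expected[np.argsort(lg[:, j]), j] = ref
        out = normalize_intensities(_table(v, ["ctrl", "drug"])).intensities.to_numpy()
        assert np.allclose(out, expected)

    def test_sorted_columns_identical_after_normalization(self, rng):
        v = 2.0 ** rng.normal(20, 2, size=(40, 5))
        out = normalize_intensities(_table(v, ["ctrl", "a", "b", "c", "d"])).intensities.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_nonpositive_masked(self):
        v = np.array([[4.0, 0.0], [8.0, 2.0], [16.0, 4.0]])
        out = normalize_intensities(_table(v, ["ctrl", "drug"])).intensities
        assert np.isnan(out.iloc[0, 1])


class TestEffects:
    def _two_condition_table(self, rng, n_pep=30, shift=None):
        conds = ["ctrl"] * 4 + ["drug"] * 4
        bio = ["b1", "b1", "b2", "b2"] * 2
        tech = ["t1", "t2"] * 4
        base = rng.normal(20, 1, size=(n_pep, 1))
        noise = rng.normal(0, 0.2, size=(n_pep, 8))
        v = base + noise
        if shift is not None:
            v[:, 4:] += shift[:, None]
        return _table(2.0**v, conds, bio=bio, tech=tech)

    def test_identical_condition_gives_zero_logfc_and_t(self):
        v = np.tile(np.array([[16.0], [64.0], [4.0]]), (1, 4))
        t = _table(v, ["ctrl", "ctrl", "drug", "drug"], bio=["b1"] * 4)
        eff = fit_effects(normalize_intensities(t))
        assert np.allclose(eff.table["logFC"], 0.0, atol=1e-12)
        assert np.allclose(eff.table["t"], 0.0, atol=1e-12)

    def test_recovers_planted_shift(self, rng):
        # linear model in isolation: feed log-scale values directly
        shift = np.zeros(30)
        shift[:5] = -3.0
        t = self._two_condition_table(rng, shift=shift)
        logged = IntensityTable(np.log2(t.intensities), t.peptides, t.samples)
        got = fit_effects(logged).logfc["drug"].to_numpy()
        assert np.allclose(got[:5], -3.0, atol=0.5)
        assert np.allclose(got[5:], 0.0, atol=0.5)

    def test_bh_adjustment_matches_reference(self, rng):
        eff = fit_effects(normalize_intensities(self._two_condition_table(rng)))
        sub = eff.table[eff.table["condition"] == "drug"]
        p = sub["p"].to_numpy()
        # independent Benjamini-Hochberg reference
        m = len(p)
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(sub["p_adj"].to_numpy(), expected)
        assert (sub["p_adj"].to_numpy() >= p - 1e-12).all()

    def test_control_not_estimable_excluded(self, rng):
        t = self._two_condition_table(rng, n_pep=5)
        ints = t.intensities.copy()
        ints.iloc[0, :4] = np.nan  # no control observations for pep0
        t2 = IntensityTable(ints, t.peptides, t.samples)
        eff = fit_effects(normalize_intensities(t2))
        assert "pep0" not in set(eff.table["peptide_id"])
        assert eff.logfc.loc["pep0"].isna().all()

    def test_moderated_matches_limma_oracle(self, rng, tmp_path):
        """Cross-check logFC and moderated t against the reference R implementation."""
        t = self._two_condition_table(rng, n_pep=20)
        norm = normalize_intensities(t)
        eff = fit_effects(norm)
        # limma sees the technical-replicate-averaged matrix and same design
        avg = norm.intensities.T.groupby(
            [norm.samples["condition"], norm.samples["bio_rep"]]
        ).mean().T
        avg.columns = [f"{c}_{b}" for c, b in avg.columns]
        data_path = tmp_path / "y.tsv"
        avg.to_csv(data_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{data_path}", row.names=1))
            cond <- factor(sub("_.*", "", colnames(y)), levels=c("ctrl","drug"))
            bio <- factor(sub(".*_", "", colnames(y)))
            design <- model.matrix(~cond + bio)
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(logFC=fit$coefficients[,"conddrug"], t=fit$t[,"conddrug"])
            write.table(out, "{tmp_path}/out.tsv", sep="\t", quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        got = eff.table.set_index("peptide_id")
        assert np.allclose(got["logFC"], ref.loc[got.index, "logFC"], atol=1e-6)
        assert np.allclose(got["t"], ref.loc[got.index, "t"], atol=1e-4)


class TestGmm:
    def test_identical_values_give_single_component(self):
        fit = fit_gmm(np.zeros(21), "p")
        assert fit.n_components == 1 and not fit.boolean_ok

    def test_two_population_recovery(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 14), rng.normal(5, 0.1, 7)])
        fit = fit_gmm(x, "p", seed=0)
        assert fit.n_components == 2
        assert abs(fit.means[fit.control_component] - 0) < 0.2
        assert abs(fit.means[fit.perturbed_component] - 5) < 0.2
        assert fit.boolean_ok

    def test_bic_matches_closed_form(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 12), rng.normal(4, 0.3, 9)])
        fit = fit_gmm(x, "p", seed=0)
        # independent BIC oracle: -2 logL + p ln n with p = 3K - 1
        logl = np.sum(
            np.log(
                np.sum(
                    fit.weights * stats.norm.pdf(x[:, None], fit.means, fit.sds), axis=1
                )
            )
        )
        expected = -2 * logl + (3 * fit.n_components - 1) * np.log(len(x))
        assert fit.bic == pytest.approx(expected, abs=1e-6)

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            fit_gmm(np.array([0.0, 1.0]), "p")


def _fit(means, sds, weights, control=0):
    """Hand-built two-component fit, marked usable regardless of overlap."""
    f = GmmFit("p", 2, np.array(means, float), np.array(sds, float),
               np.array(weights, float), 0.0, control, 1 - control)
    f.overlap = overlap_fraction(f)
    f.boolean_ok = True
    return f


class TestOverlap:
    def test_identical_components_maximal(self):
        f = GmmFit("p", 2, np.zeros(2), np.ones(2), np.full(2, 0.5), 0.0, 0, 1)
        assert overlap_fraction(f, normalized=True) == pytest.approx(1.0, abs=1e-6)
        assert overlap_fraction(f, normalized=False) == pytest.approx(0.5, abs=1e-6)

    def test_separated_components_negligible(self):
        f = GmmFit("p", 2, np.array([0.0, 100.0]), np.ones(2), np.full(2, 0.5), 0.0, 0, 1)
        assert overlap_fraction(f) == pytest.approx(0.0, abs=1e-9)

    def test_matches_numeric_integration_oracle(self):
        f = GmmFit("p", 2, np.array([0.0, 2.0]), np.ones(2), np.full(2, 0.5), 0.0, 0, 1)
        oracle = integrate.quad(
            lambda x: min(0.5 * stats.norm.pdf(x, 0, 1), 0.5 * stats.norm.pdf(x, 2, 1)),
            -10, 12, limit=200,
        )[0]
        got = overlap_fraction(f)
        assert got == pytest.approx(oracle, abs=1e-6)
        # normalized convention equals 2 Phi(-1) for this symmetric case
        assert overlap_fraction(f, normalized=True) == pytest.approx(
            2 * stats.norm.cdf(-1), abs=1e-6
        )

    def test_wrong_component_count_rejected(self):
        f = GmmFit("p", 1, np.zeros(1), np.ones(1), np.ones(1), 0.0, 0, None)
        with pytest.raises(ValueError):
            overlap_fraction(f)


class TestSij:
    def test_closed_form_normal_ratio(self):
        f = _fit([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
        expected = np.log10(stats.norm.pdf(0, 0, 1) / stats.norm.pdf(0, 2, 1))
        assert compute_sij(f, 0.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8686, abs=1e-4)
        assert compute_sij(f, 2.0) == pytest.approx(-expected, abs=1e-9)

    def test_zero_at_symmetry_point(self):
        f = _fit([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
        assert compute_sij(f, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_clamped_on_underflow(self):
        f = _fit([0.0, 60.0], [0.5, 0.5], [0.5, 0.5])
        assert compute_sij(f, 0.0) == scoring.S_MAX
        assert compute_sij(f, 60.0) == -scoring.S_MAX

    def test_antisymmetric_under_label_swap(self):
        f = _fit([0.0, 2.0], [1.0, 0.7], [0.6, 0.4], control=0)
        g = _fit([0.0, 2.0], [1.0, 0.7], [0.6, 0.4], control=1)
        for x in (-1.0, 0.3, 1.7):
            assert compute_sij(f, x) == pytest.approx(-compute_sij(g, x), abs=1e-12)

    def test_well_separated_fit_classifies_draws_correctly(self, rng):
        f = _fit([0.0, 3.0], [0.5, 0.5], [0.5, 0.5])  # 6 sigma separation
        x0 = rng.normal(0, 0.5, 500)
        x1 = rng.normal(3, 0.5, 500)
        calls0 = [classify(compute_sij(f, x)) for x in x0]
        calls1 = [classify(compute_sij(f, x)) for x in x1]
        assert np.mean([c == "control" for c in calls0]) >= 0.95
        assert np.mean([c == "perturbed" for c in calls1]) >= 0.95


class TestClassify:
    @pytest.mark.parametrize(
        "s,label",
        [(-0.6, "perturbed"), (0.6, "control"), (0.0, "undetermined"),
         (-0.5, "undetermined"), (0.5, "undetermined")],
    )
    def test_thresholds(self, s, label):
        assert classify(s) == label

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            classify(np.nan)
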