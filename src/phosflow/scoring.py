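"""Per-site Boolean evidence scores from perturbation phosphoproteomics.

The pipeline implemented here converts a raw phosphopeptide intensity matrix
(peptides x samples, with a condition/replicate annotation) into, for every
peptide *i* and condition *j*, a single evidence score

    S_ij = log10( P_ij(C_i) / P_ij(P_i) )

where C_i and P_i are the control and perturbed components of a two-component
Gaussian mixture fitted to peptide *i*'s treatment-effect estimates across all
conditions.  S_ij is negative when the measurement is more likely to belong to
the perturbed population.  A peptide is called perturbed under a condition
when S_ij < -0.5, in the control state when S_ij > 0.5, and undetermined in
between.

Stages:

1. ``normalize_intensities`` -- log2 transform and quantile normalization.
2. ``fit_effects`` -- per-peptide linear model (condition + biological
   replicate factors, technical replicates averaged) giving log2 fold changes
   versus control, with empirical-Bayes moderated t-statistics and
   Benjamini-Hochberg correction per condition.
3. ``fit_gmm`` -- per-peptide Gaussian mixture (1-9 components, BIC
   selection); only peptides best described by exactly two populations whose
   densities overlap by at most 10% are Boolean-compliant.
4. ``compute_sij`` / ``classify`` / ``build_smatrix`` -- evidence scores,
   three-way calls, and site-level aggregation (multiple peptides mapping to
   one site sum their S_ij as independent pieces of evidence).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import polygamma
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: |S_ij| ceiling applied when one component's membership probability underflows.
S_MAX = 10.0

#: Default call thresholds: perturbed below -S_CUT, control above +S_CUT.
S_CUT = 0.5

#: Maximum density-overlap fraction for a Boolean-compliant two-component fit.
OVERLAP_MAX = 0.10

#: Variance floor for mixture components, in (log2 fold change)^2 units.
#: Set to the square of a plausible residual noise sd of a log2 fold-change
#: estimate (0.1): a numerically tiny floor lets singleton components collapse
#: into near-delta spikes that defeat BIC selection and the overlap filter
#: when the condition count is small.
VAR_FLOOR = 1e-2


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Phosphopeptide intensity matrix plus peptide and sample annotation.

    Parameters
    ----------
    intensities
        Peptides x samples; raw (non-negative) or log2 values.  Zeros and
        missing values are represented as NaN after :func:`normalize_intensities`.
    peptides
        Indexed by peptide id, columns ``protein`` (UniProt-style id) and
        ``sites`` (semicolon-separated residue/position strings, e.g.
        ``"S473;T308"``).
    samples
        Indexed by sample id, columns ``condition``, ``bio_rep``, ``tech_rep``,
        ``is_control`` (bool).  Exactly one condition is flagged as control.
    """

    intensities: pd.DataFrame
    peptides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.intensities.columns]
        ctrl = self.samples.loc[self.samples["is_control"], "condition"].unique()
        if len(ctrl) != 1:
            raise ValueError(f"exactly one control condition required, got {list(ctrl)}")

    @property
    def control_condition(self) -> str:
        return self.samples.loc[self.samples["is_control"], "condition"].iloc[0]

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    def site_ids(self, peptide_id: str) -> list[str]:
        """Site ids ``"UPID.RESPOS"`` covered by a peptide."""
        row = self.peptides.loc[peptide_id]
        sites = str(row["sites"])
        if not sites or sites == "nan":
            return []
        return [f"{row['protein']}.{s.strip()}" for s in sites.split(";") if s.strip()]


@dataclass
class EffectTable:
    """Per-(peptide, condition) treatment-effect estimates versus control.

    ``table`` is tidy with columns ``peptide_id, condition, logFC, se, t, p,
    p_adj, n_obs``; ``logfc`` is the same information as a wide peptides x
    conditions frame (control column fixed at 0 where estimable).
    """

    table: pd.DataFrame
    logfc: pd.DataFrame
    control_condition: str
    d0: float
    s0_sq: float

    def effects_vector(self, peptide_id: str) -> pd.Series:
        """Effect estimates for one peptide across all conditions (control included)."""
        return self.logfc.loc[peptide_id]


@dataclass
class GmmFit:
    """Gaussian mixture fitted to one peptide's effect estimates."""

    peptide_id: str
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    control_component: int | None
    perturbed_component: int | None
    overlap: float = np.nan
    boolean_ok: bool = False

    def component_log_density(self, x: float) -> np.ndarray:
        """log(pi_k * N(x; mu_k, sd_k)) for each component."""
        return np.log(self.weights) + stats.norm.logpdf(x, self.means, self.sds)


@dataclass
class SMatrix:
    """Peptide- and site-level Boolean evidence scores.

    ``s`` and ``labels`` are peptides x conditions; ``site_s`` sums S_ij over
    the peptides mapping to each site (independent pieces of evidence) and is
    sites x conditions.  A site is called perturbed under a condition when its
    summed S is below ``-s_cut``.
    """

    s: pd.DataFrame
    labels: pd.DataFrame
    site_s: pd.DataFrame
    control_condition: str
    s_cut: float = S_CUT

    def perturbed_sites(self, condition: str) -> set[str]:
        col = self.site_s[condition]
        return set(col.index[col < -self.s_cut])

    def subset(self, conditions: list[str]) -> "SMatrix":
        """Evidence restricted to the given data conditions (control retained)."""
        keep = [self.control_condition] + [c for c in conditions if c != self.control_condition]
        keep_s = [c for c in keep if c in self.s.columns]
        keep_site = [c for c in keep if c in self.site_s.columns]
        return SMatrix(
            self.s[keep_s], self.labels[keep_s], self.site_s[keep_site],
            self.control_condition, self.s_cut,
        )

    @property
    def data_conditions(self) -> list[str]:
        return [c for c in self.site_s.columns if c != self.control_condition]


# ---------------------------------------------------------------------------
# 1. normalization
# ---------------------------------------------------------------------------


def normalize_intensities(raw: IntensityTable) -> IntensityTable:
    """Log2 transform and quantile normalize an intensity matrix.

    Non-positive and missing intensities are masked to NaN (logged).  Quantile
    normalization maps, within each sample, the k-th smallest observed value
    to the mean of the k-th smallest values across samples; with missing data
    the reference distribution is interpolated at each sample's quantiles.
    With a single sample only the log2 transform is applied.
    """
    values = raw.intensities.to_numpy(dtype=float, copy=True)
    bad = ~(values > 0)
    n_bad = int(np.count_nonzero(bad & ~np.isnan(values)))
    if n_bad:
        logger.warning("masked %d non-positive intensities", n_bad)
    values[bad] = np.nan
    logv = np.log2(values)

    if logv.shape[1] > 1:
        logv = _quantile_normalize(logv)

    out = pd.DataFrame(logv, index=raw.intensities.index, columns=raw.intensities.columns)
    return IntensityTable(out, raw.peptides, raw.samples)


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Quantile normalization over columns, NaN-aware.

    On complete data this is the classic rank/row-mean scheme: every column's
    sorted vector becomes the across-column mean of sorted vectors.  Columns
    with missing entries are matched on quantiles of their observed values.
    """
    n_rows, n_cols = x.shape
    # reference: mean of per-column quantile curves on a common grid
    grid = np.linspace(0, 1, n_rows)
    curves = np.full((n_rows, n_cols), np.nan)
    for j in range(n_cols):
        col = x[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        q = np.linspace(0, 1, obs.size)
        curves[:, j] = np.interp(grid, q, obs)
    reference = np.nanmean(curves, axis=1)

    out = np.full_like(x, np.nan)
    for j in range(n_cols):
        col = x[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        if m == 0:
            continue
        order = np.argsort(col[mask], kind="mergesort")
        ranks = np.empty(m)
        ranks[order] = np.arange(m)
        # average the reference at the quantiles of tied observed values
        target = np.interp(np.linspace(0, 1, m), grid, reference)
        vals = col[mask]
        normed = np.empty(m)
        normed = target[ranks.astype(int)]
        # ties: assign the mean normalized value of the tied group
        srt = vals[order]
        tied_start = 0
        for k in range(1, m + 1):
            if k == m or srt[k] != srt[tied_start]:
                if k - tied_start > 1:
                    grp = order[tied_start:k]
                    normed[grp] = normed[grp].mean()
                tied_start = k
        out[mask, j] = normed
    return out


# ---------------------------------------------------------------------------
# 2. linear model with moderated t
# ---------------------------------------------------------------------------


def fit_effects(norm: IntensityTable) -> EffectTable:
    """Estimate per-condition log2 fold changes versus control, per peptide.

    Technical replicates are averaged within (condition, biological replicate)
    before fitting; the model then has one factor per non-control condition
    plus a biological-replicate factor, fitted by OLS per peptide with
    pairwise deletion of missing values.  Variances are shrunk across peptides
    by empirical Bayes (moment matching on log variances); p-values use the
    moderated t on ``d0 + d`` degrees of freedom and are Benjamini-Hochberg
    corrected within each condition.

    Peptides whose control intensity cannot be estimated (fewer than two raw
    control observations) get all effects undefined and are excluded
    downstream.
    """
    control = norm.control_condition
    samples = norm.samples
    # average technical replicates -> one observation per (condition, bio_rep)
    group_keys = samples.groupby(["condition", "bio_rep"], sort=False).groups
    groups = list(group_keys.items())
    y = np.column_stack(
        [norm.intensities[list(cols)].mean(axis=1, skipna=True).to_numpy() for _, cols in groups]
    )
    raw_counts = np.column_stack(
        [norm.intensities[list(cols)].notna().sum(axis=1).to_numpy() for _, cols in groups]
    )
    obs_conditions = np.array([cond for (cond, _), _ in groups])
    obs_bio = np.array([bio for (_, bio), _ in groups])

    conditions = [c for c in norm.conditions if c != control]
    bio_levels = list(pd.unique(obs_bio))

    # design: intercept (control mean) + condition effects + bio-replicate effects
    n_obs = len(groups)
    cond_cols = {c: k for k, c in enumerate(conditions)}
    X = np.zeros((n_obs, 1 + len(conditions) + max(len(bio_levels) - 1, 0)))
    X[:, 0] = 1.0
    for r in range(n_obs):
        c = obs_conditions[r]
        if c != control:
            X[r, 1 + cond_cols[c]] = 1.0
        b = bio_levels.index(obs_bio[r])
        if b > 0:
            X[r, 1 + len(conditions) + b - 1] = 1.0

    peptides = norm.intensities.index
    n_pep = len(peptides)
    beta = np.full((n_pep, len(conditions)), np.nan)
    unscaled_se = np.full((n_pep, len(conditions)), np.nan)
    s2 = np.full(n_pep, np.nan)
    dfs = np.zeros(n_pep)
    n_used = np.zeros((n_pep, len(conditions)), dtype=int)

    ctrl_mask = obs_conditions == control
    for g, pid in enumerate(peptides):
        yi = y[g]
        counts = raw_counts[g]
        ok = ~np.isnan(yi)
        # per-condition observation requirement: >=2 raw observations
        for c in conditions + [control]:
            sel = obs_conditions == c
            if counts[sel & ok].sum() < 2:
                ok &= ~sel
        if counts[ctrl_mask & ok].sum() < 2 or ok.sum() < 2:
            continue  # control not estimable; peptide excluded downstream
        Xi, yi_ok = X[ok], yi[ok]
        keep = Xi.any(axis=0)
        keep[0] = True
        coef, res, rank, _ = np.linalg.lstsq(Xi[:, keep], yi_ok, rcond=None)
        full = np.zeros(X.shape[1])
        full[keep] = coef
        resid = yi_ok - Xi[:, keep] @ coef
        df = int(ok.sum()) - rank
        dfs[g] = df
        if df > 0:
            s2[g] = float(resid @ resid) / df
        try:
            xtx_inv = np.linalg.pinv(Xi[:, keep].T @ Xi[:, keep])
        except np.linalg.LinAlgError:
            continue
        diag = np.zeros(X.shape[1])
        diag[keep] = np.diag(xtx_inv)
        for c, k in cond_cols.items():
            col = 1 + k
            sel = obs_conditions == c
            if keep[col] and (sel & ok).any():
                beta[g, k] = full[col]
                unscaled_se[g, k] = np.sqrt(diag[col])
                n_used[g, k] = int(counts[sel & ok].sum())

    d0, s0_sq = _squeeze_var(s2, dfs)
    with np.errstate(invalid="ignore"):
        s2_post = np.where(
            dfs > 0, (d0 * s0_sq + dfs * s2) / (d0 + dfs), np.nan
        ) if np.isfinite(d0) else np.full(n_pep, s0_sq)
    if not np.isfinite(d0):
        s2_post = np.where(dfs >= 0, s0_sq, np.nan)

    rows = []
    for g, pid in enumerate(peptides):
        for c, k in cond_cols.items():
            if np.isnan(beta[g, k]):
                continue
            se_mod = np.sqrt(s2_post[g]) * unscaled_se[g, k]
            df_total = (d0 + dfs[g]) if np.isfinite(d0) else np.inf
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta[g, k] / se_mod if se_mod > 0 else np.sign(beta[g, k]) * np.inf
            if se_mod == 0 and beta[g, k] == 0:
                t = 0.0
            p = 2 * stats.t.sf(abs(t), df_total) if np.isfinite(df_total) else 2 * stats.norm.sf(abs(t))
            rows.append((pid, c, beta[g, k], se_mod, t, p, n_used[g, k]))
    table = pd.DataFrame(
        rows, columns=["peptide_id", "condition", "logFC", "se", "t", "p", "n_obs"]
    )
    # BH within each condition
    table["p_adj"] = np.nan
    for c, idx in table.groupby("condition").groups.items():
        pvals = table.loc[idx, "p"].to_numpy()
        table.loc[idx, "p_adj"] = multipletests(pvals, method="fdr_bh")[1]

    logfc = table.pivot(index="peptide_id", columns="condition", values="logFC")
    logfc = logfc.reindex(index=peptides, columns=conditions)
    # control effect is zero by construction, where the control was estimable
    logfc[control] = np.where(dfs > 0, 0.0, np.nan)
    logfc = logfc[[control] + conditions]
    return EffectTable(table, logfc, control, d0, s0_sq)


def _squeeze_var(s2: np.ndarray, dfs: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) by moment matching.

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 chi^2_d / d and
    1/sigma^2 ~ chi^2_d0/(d0 s0^2), the statistic
    e = log(s^2) - digamma(d/2) + log(d/2) has
    E[e] = log(s0^2) + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(d/2) + trigamma(d0/2).  Matching the sample mean and
    variance of e gives d0 (via the inverse trigamma, Newton iteration) and
    s0^2.  An excess variance <= 0 yields d0 = inf (all variances equal).
    """
    ok = (dfs > 0) & np.isfinite(s2) & (s2 >= 0)
    if ok.sum() < 2:
        valid = s2[(dfs > 0) & np.isfinite(s2)]
        return np.inf, float(np.mean(valid)) if valid.size else 1.0
    d = dfs[ok]
    # numerically-zero residual variances would dominate the log moments;
    # offset them away from zero relative to the median
    x = s2[ok]
    med = np.median(x)
    if med == 0:
        logger.warning("more than half of residual variances are zero; shrinkage unreliable")
        med = 1.0
    x = np.maximum(x, 1e-5 * med)
    e = np.log(x) - polygamma(0, d / 2) + np.log(d / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, d / 2)))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + polygamma(0, d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


# ---------------------------------------------------------------------------
# 3. Gaussian mixture per peptide
# ---------------------------------------------------------------------------


def fit_gmm(
    effects: pd.Series | np.ndarray,
    peptide_id: str = "",
    control_value: float = 0.0,
    max_components: int = 9,
    seed: int = 0,
    overlap_normalized: bool = False,
) -> GmmFit:
    """Fit Gaussian mixtures with 1..9 components and select by BIC.

    ``effects`` are one peptide's per-condition effect estimates, with the
    control condition's effect (zero) included as a value.  EM uses k-means++
    initialization with 10 restarts, a variance floor (``VAR_FLOOR``) and a
    1e-8 log-likelihood tolerance.  The component count is additionally
    capped at n/2 so every component is supported by at least two
    observations.  BIC = -2 logL + p ln(n) with p = 3K - 1; ties break
    toward fewer components.  The control component is the component
    with maximum posterior responsibility at ``control_value``; for K = 2 the
    other component is the perturbed one, and ``boolean_ok`` requires the two
    densities to overlap by at most 10%.
    """
    x = np.asarray(effects, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError(f"need >=3 finite effect values, got {x.size}")
    X = x.reshape(-1, 1)

    best: GaussianMixture | None = None
    best_bic = np.inf
    best_k = 0
    # cap the component count at n/2 (but always allow the two-population
    # alternative): components averaging fewer than two observations collapse
    # onto the variance floor and defeat BIC selection at small condition
    # counts
    kmax = min(max_components, max(2, x.size // 2))
    for k in range(1, kmax + 1):
        if np.unique(x).size < k:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    reg_covar=VAR_FLOOR,
                    tol=1e-8,
                    max_iter=500,
                    n_init=10 if k > 1 else 1,
                    init_params="k-means++",
                    random_state=seed,
                ).fit(X)
        except Exception as exc:  # EM failure at this K: skip it
            logger.warning("GMM with K=%d failed for %s: %s", k, peptide_id, exc)
            continue
        bic = gm.bic(X)
        if bic < best_bic - 1e-12:  # strict improvement; ties favour smaller K
            best, best_bic, best_k = gm, bic, k
    if best is None:
        raise RuntimeError(f"no mixture could be fitted for {peptide_id}")

    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.reshape(-1))
    weights = best.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    log_resp = np.log(weights) + stats.norm.logpdf(control_value, means, sds)
    control_comp = int(np.argmax(log_resp))
    perturbed_comp = (1 - control_comp) if best_k == 2 else None

    fit = GmmFit(
        peptide_id=peptide_id,
        n_components=best_k,
        means=means,
        sds=sds,
        weights=weights,
        bic=float(best_bic),
        control_component=control_comp,
        perturbed_component=perturbed_comp,
    )
    if best_k == 2:
        fit.overlap = overlap_fraction(fit, normalized=overlap_normalized)
        fit.boolean_ok = fit.overlap <= OVERLAP_MAX
    return fit


def overlap_fraction(fit: GmmFit, normalized: bool = False) -> float:
    """Area shared by the two component densities of a two-component fit.

    Computes the unnormalized overlap integral min(pi1 f1, pi2 f2) by adaptive
    quadrature over the union of both components' mu +- 8 sigma ranges.  With
    ``normalized=True`` the integral is divided by min(pi1, pi2), measuring
    overlap relative to the smaller component's mass (the convention is
    configurable because either reading of a "10% overlap" rule is sensible).
    """
    if fit.n_components != 2:
        raise ValueError("overlap_fraction requires a two-component fit")
    lo = float(np.min(fit.means - 8 * fit.sds))
    hi = float(np.max(fit.means + 8 * fit.sds))
    w, mu, sd = fit.weights, fit.means, fit.sds

    def min_density(t: float) -> float:
        d = w * stats.norm.pdf(t, mu, sd)
        return float(np.min(d))

    # split at the component means so quad sees smooth pieces
    pts = sorted([lo, *np.clip(mu, lo, hi), hi])
    area = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if b > a:
            area += integrate.quad(min_density, a, b, limit=200)[0]
    if normalized:
        area /= float(np.min(w))
    return float(area)


# ---------------------------------------------------------------------------
# 4. S-scores and calls
# ---------------------------------------------------------------------------


def compute_sij(fit: GmmFit, x: float, s_max: float = S_MAX) -> float:
    """Evidence score S = log10 of control vs perturbed membership probability.

    Membership probabilities are posterior responsibilities (mixture-weight
    adjusted).  The score is clamped to ``[-s_max, s_max]`` so an underflowing
    component yields a finite, saturated score.
    """
    if not fit.boolean_ok:
        raise ValueError("S-scores are only defined for Boolean-compliant fits")
    log_d = fit.component_log_density(x)
    s = (log_d[fit.control_component] - log_d[fit.perturbed_component]) / np.log(10)
    if not np.isfinite(s):
        logger.warning("S underflow for %s at x=%g; clamped", fit.peptide_id, x)
        s = np.sign(s) * s_max if s != 0 else 0.0
    return float(np.clip(s, -s_max, s_max))


def classify(s: float, s_cut: float = S_CUT) -> str:
    """Three-way call: ``perturbed`` (S < -cut), ``control`` (S > cut), else ``undetermined``."""
    if not np.isfinite(s):
        raise ValueError("S must be finite")
    if s < -s_cut:
        return "perturbed"
    if s > s_cut:
        return "control"
    return "undetermined"


def build_smatrix(
    effects: EffectTable,
    fits: dict[str, GmmFit],
    site_map: dict[str, list[str]],
    s_cut: float = S_CUT,
) -> SMatrix:
    """Assemble the peptide- and site-level evidence-score matrix.

    Only Boolean-compliant peptides contribute.  ``site_map`` maps peptide ids
    to the site ids they cover; a multiply-phosphorylated peptide contributes
    its S_ij to each of its sites, and multiple peptides on one site sum their
    scores as independent evidence.
    """
    kept = [pid for pid, f in fits.items() if f.boolean_ok]
    conditions = effects.logfc.columns
    s = pd.DataFrame(np.nan, index=kept, columns=conditions)
    for pid in kept:
        fit = fits[pid]
        vec = effects.logfc.loc[pid]
        for cond, val in vec.items():
            if np.isfinite(val):
                s.loc[pid, cond] = compute_sij(fit, float(val))
    labels = s.map(lambda v: classify(v, s_cut) if np.isfinite(v) else "")

    site_rows: dict[str, np.ndarray] = {}
    for pid in kept:
        svals = s.loc[pid].to_numpy()
        for site in site_map.get(pid, []):
            acc = site_rows.setdefault(site, np.zeros(len(conditions)))
            acc += np.nan_to_num(svals, nan=0.0)
    site_s = pd.DataFrame(site_rows, index=conditions).T.sort_index()
    return SMatrix(s, labels, site_s, effects.control_condition, s_cut)
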