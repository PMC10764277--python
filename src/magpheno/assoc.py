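"""Longitudinal association modelling for MAG abundances and transcripts.

DNA side: MAG abundances (TPM) are filtered for abundance/prevalence
(> 5 TPM in > 40% of samples, strict), variance-stabilized, and related to
ponderal growth with per-MAG random-intercept linear mixed models

    WLZ ~ beta1 * MAG + beta2 * study_week + (1 | PID)

and treatment effects with

    MAG_i ~ beta1 * group + beta2 * week + beta3 * group x week + (1 | PID)

(the same interaction form serves WLZ-response-quartile contrasts, e.g.
for faecal glycosidic linkage levels). RNA side: transcript counts are
zeroed per sample for MAGs below a 0.5 TPM DNA floor, CPM/prevalence
filtered (>= 5 CPM in >= 35%, inclusive), TMM normalized, and tested with
per-transcript negative-binomial GLMs (trended dispersion, likelihood-ratio
tests). Transcripts are ranked by sign(fold change) x -log10(p) for
enrichment analysis, and p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateModelError,
    InvalidDesignError,
    InvalidInputError,
    RankDeficiencyError,
)

# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------

def filter_mags_tpm(
    dna_tpm: pd.DataFrame, min_tpm: float = 5.0, min_prev: float = 0.40
) -> list[str]:
    """MAGs with abundance strictly > ``min_tpm`` TPM in strictly more than
    ``min_prev`` of samples. Returns the surviving feature ids."""
    if dna_tpm.empty:
        return []
    prevalence = (dna_tpm > min_tpm).mean(axis=1)
    return list(dna_tpm.index[prevalence > min_prev])


def variance_stabilize(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing surrogate: median-of-ratios size factors, then
    a shifted log2.

    Size factors follow the median-of-ratios scheme (geometric mean
    reference over features detected everywhere; a positive-count fallback
    when no such feature exists). The transform is monotone per sample and
    finite on zeros.
    """
    counts = raw_counts.to_numpy(dtype=float)
    zero_samples = counts.sum(axis=0) == 0
    if zero_samples.any():
        bad = list(raw_counts.columns[zero_samples])
        raise InvalidInputError(f"all-zero sample(s): size factor undefined for {bad}")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_positive = np.all(counts > 0, axis=1)
    if all_positive.sum() >= 1:
        ref = logc[all_positive].mean(axis=1)
        ratios = logc[all_positive] - ref[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        # positive-counts fallback: per-feature geometric mean over samples
        # where the feature is detected
        masked = np.where(counts > 0, logc, np.nan)
        ref = np.nanmean(masked, axis=1)
        ratios = masked - ref[:, None]
        log_sf = np.nanmedian(ratios, axis=0)
    sf = np.exp(log_sf - np.mean(log_sf))
    vst = np.log2(counts / sf[None, :] + 1.0)
    return pd.DataFrame(vst, index=raw_counts.index, columns=raw_counts.columns)


def zero_low_dna_transcripts(
    transcript_counts: pd.DataFrame,
    dna_tpm: pd.DataFrame,
    gene_to_mag: Mapping[str, str] | pd.Series,
    floor: float = 0.5,
) -> pd.DataFrame:
    """Zero, per sample, the transcripts of MAGs with DNA abundance
    strictly below ``floor`` TPM in that sample."""
    mapping = pd.Series(dict(gene_to_mag)) if not isinstance(gene_to_mag, pd.Series) else gene_to_mag
    unknown = [g for g in transcript_counts.index if g not in mapping.index]
    if unknown:
        raise InvalidInputError(f"transcripts with unknown MAG of origin: {unknown[:5]}")
    mags = mapping.loc[transcript_counts.index]
    missing = sorted(set(mags) - set(dna_tpm.index))
    if missing:
        raise InvalidInputError(f"MAGs absent from the DNA table: {missing[:5]}")
    dna = dna_tpm.reindex(mags).to_numpy()
    dna = dna[:, [dna_tpm.columns.get_loc(c) for c in transcript_counts.columns]]
    out = transcript_counts.to_numpy().copy()
    out[dna < floor] = 0
    return pd.DataFrame(out, index=transcript_counts.index, columns=transcript_counts.columns)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise InvalidInputError(f"zero library size in sample(s): {list(zero.index)}")
    return counts * 1e6 / lib


def cpm_filter(
    transcript_counts: pd.DataFrame, min_cpm: float = 5.0, min_prev: float = 0.35
) -> list[str]:
    """Transcripts with >= ``min_cpm`` CPM in >= ``min_prev`` of samples
    (both thresholds inclusive). Returns surviving feature ids."""
    rates = cpm(transcript_counts)
    prevalence = (rates >= min_cpm).mean(axis=1)
    return list(transcript_counts.index[prevalence >= min_prev])


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile. M (log ratio) and A (mean log abundance)
    values over doubly-expressed genes are two-sidedly trimmed
    (``logratio_trim`` on M, ``abundance_trim`` on A); the factor is the
    precision-weighted mean M (delta-method weights, as in the standard
    TMM formulation).
    """
    if counts.shape[1] < 2:
        raise InvalidInputError("TMM needs at least two samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise InvalidInputError("zero library size")
    uq = np.array([np.quantile(X[:, i][X[:, i] > 0] / lib[i], 0.75) if (X[:, i] > 0).any() else 0
                   for i in range(X.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref, nref = X[:, ref_idx], lib[ref_idx]
    factors = np.ones(X.shape[1])
    for i in range(X.shape[1]):
        if i == ref_idx:
            continue
        obs, nobs = X[:, i], lib[i]
        both = (obs > 0) & (ref > 0)
        if both.sum() < 2:
            warnings.warn(f"TMM degenerate for sample {counts.columns[i]}; factor set to 1")
            continue
        o, r = obs[both], ref[both]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        w = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        n = len(m)
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * abundance_trim) + 1
        hi_s = n + 1 - lo_s
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if keep.sum() == 0 or not np.isfinite(m[keep]).any():
            factors[i] = 1.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[i] = 2.0 ** f if np.isfinite(f) and abs(f) > 1e-10 else 1.0
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# linear mixed models (random intercept per participant)
# ---------------------------------------------------------------------------

def fit_lmm(
    response: pd.Series,
    fixed: pd.DataFrame,
    groups: pd.Series,
) -> dict:
    """Random-intercept linear mixed model fitted by REML.

    Returns per-covariate estimates, t-statistics and p-values (residual-df
    t approximation) plus fit metadata. When the REML random-intercept
    variance collapses to the boundary the fixed effects are the ordinary
    least-squares solution, which is returned exactly in that case.
    """
    y = np.asarray(response, dtype=float)
    if np.ptp(y) < 1e-12:
        raise DegenerateModelError("constant response")
    X = sm.add_constant(fixed.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError("fixed-effect design is rank deficient")
    grp = pd.Series(groups).astype(str)
    if grp.nunique() < 2:
        raise DegenerateModelError("need at least 2 grouping levels")
    if len(y) < X.shape[1] + 2:
        raise DegenerateModelError("too few observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=grp)
        try:
            res = model.fit(reml=True, method="lbfgs")
            converged = bool(res.converged)
        except Exception:
            res, converged = None, False
    var_re = float(res.cov_re.iloc[0, 0]) if res is not None else np.nan
    scale = float(res.scale) if res is not None else np.nan
    if res is None or not np.isfinite(var_re) or var_re <= 1e-8 * max(scale, 1e-12):
        # variance profiled to the boundary: the REML solution is OLS
        ols = sm.OLS(y, X).fit()
        params, bse = ols.params, ols.bse
        var_re = 0.0
        scale = float(ols.scale)
        converged = True
    else:
        params, bse = res.fe_params, res.bse_fe
    dof = len(y) - X.shape[1]
    out = {"converged": converged, "var_random_intercept": var_re,
           "var_residual": scale, "df": dof}
    for name in X.columns:
        est = float(params[name])
        se = float(bse[name])
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
        out[name] = {"estimate": est, "se": se, "t": t, "p": p}
    return out


def fit_group_time_model(
    feature_values: pd.Series,
    meta: pd.DataFrame,
    group_col: str = "arm",
    week_col: str = "study_week",
    pid_col: str = "PID",
    group_levels: Sequence[str] | None = None,
) -> dict:
    """Interaction mixed model: value ~ group + week + group x week + (1|PID).

    The grouping factor must have exactly two observed levels; coding is
    0/1 by sorted level order (or by ``group_levels``), so swapping the
    labels negates the group and interaction coefficients. Returns
    coefficient rows under 'group', 'week' and 'interaction'.
    """
    levels = list(group_levels) if group_levels else sorted(meta[group_col].unique())
    observed = set(meta[group_col].unique())
    if len(observed) != 2 or observed != set(levels):
        raise InvalidDesignError(f"need exactly two group levels, got {sorted(observed)}")
    g = (meta[group_col] == levels[1]).astype(float)
    week = meta[week_col].astype(float)
    fixed = pd.DataFrame({"group": g, "week": week, "interaction": g * week},
                         index=meta.index)
    res = fit_lmm(feature_values.loc[meta.index], fixed, meta[pid_col])
    res["group_coding"] = {levels[0]: 0, levels[1]: 1}
    return res


def associate_features(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "wlz",
    group_col: str = "arm",
    response_col: str = "WLZ",
    group_levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature association models over a (features x samples) table.

    ``mode='wlz'`` fits ``WLZ ~ feature + week + (1|PID)`` and reports the
    feature coefficient as beta1. ``mode='group_time'`` fits the
    group/week/interaction model per feature. q-values are BH-adjusted
    within the returned table.
    """
    meta = meta.loc[table.columns]
    rows = []
    for feat in table.index:
        values = table.loc[feat]
        try:
            if mode == "wlz":
                fixed = pd.DataFrame(
                    {"feature": values.astype(float), "week": meta["study_week"].astype(float)},
                    index=meta.index,
                )
                fit = fit_lmm(meta[response_col], fixed, meta["PID"])
                rows.append({"feature": feat, "beta1": fit["feature"]["estimate"],
                             "t": fit["feature"]["t"], "p": fit["feature"]["p"],
                             "beta2": fit["week"]["estimate"], "converged": fit["converged"]})
            elif mode == "group_time":
                fit = fit_group_time_model(values, meta, group_col=group_col,
                                           group_levels=group_levels)
                rows.append({"feature": feat,
                             "beta1": fit["group"]["estimate"], "t1": fit["group"]["t"],
                             "p1": fit["group"]["p"],
                             "beta2": fit["week"]["estimate"],
                             "beta3": fit["interaction"]["estimate"],
                             "t3": fit["interaction"]["t"], "p3": fit["interaction"]["p"],
                             "converged": fit["converged"]})
            else:
                raise InvalidInputError(f"unknown mode {mode!r}")
        except (DegenerateModelError, RankDeficiencyError):
            continue
    out = pd.DataFrame(rows).set_index("feature")
    if mode == "wlz" and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    elif len(out):
        out["q1"] = bh_adjust(out["p1"].to_numpy())
        out["q3"] = bh_adjust(out["p3"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# negative-binomial differential expression
# ---------------------------------------------------------------------------

def _estimate_dispersions(
    counts: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Per-gene NB dispersions: Poisson-fit method of moments with a
    lowess trend on abundance and log-scale shrinkage toward the trend."""
    n, p = counts.shape[1], X.shape[1]
    raw = np.empty(counts.shape[0])
    mean_norm = np.empty(counts.shape[0])
    for gi in range(counts.shape[0]):
        y = counts[gi]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = np.clip(fit.fittedvalues, 1e-8, None)
        except Exception:
            mu = np.clip(np.full(n, y.mean()), 1e-8, None)
        raw[gi] = np.sum(((y - mu) ** 2 - mu) / mu**2) / max(n - p, 1)
        mean_norm[gi] = np.mean(y / np.exp(offset))
    raw = np.clip(raw, 1e-4, 10.0)
    order = np.argsort(mean_norm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_trend = lowess(np.log(raw[order]), np.log(mean_norm[order] + 1e-8),
                          frac=0.5, return_sorted=False)
    trend = np.empty_like(raw)
    trend[order] = np.exp(sm_trend)
    # shrink halfway toward the trend on the log scale
    return np.clip(np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend)), 1e-4, 10.0)


def nb_differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    group_col: str = "arm",
    week_col: str = "study_week",
    test: str = "group",
    group_levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-transcript NB GLM with design ~ group + week + group x week.

    Dispersion is estimated per gene and shrunk toward a fitted
    mean-dispersion trend; the requested coefficient ('group' or
    'interaction') is tested by likelihood ratio. log2 fold changes are the
    tested coefficient converted from the natural-log link. Non-converged
    genes are flagged with p = 1 (conservative).
    """
    if test not in ("group", "interaction"):
        raise InvalidInputError("test must be 'group' or 'interaction'")
    meta = meta.loc[counts.columns]
    levels = list(group_levels) if group_levels else sorted(meta[group_col].unique())
    if len(set(meta[group_col])) != 2:
        raise InvalidDesignError("need exactly two group levels")
    g = (meta[group_col] == levels[1]).to_numpy(float)
    week = meta[week_col].to_numpy(float)
    X = np.column_stack([np.ones_like(g), g, week, g * week])
    test_col = 1 if test == "group" else 3
    X0 = np.delete(X, test_col, axis=1)
    lib = counts.sum(axis=0).to_numpy(float)
    if norm_factors is not None:
        lib = lib * norm_factors.loc[counts.columns].to_numpy(float)
    offset = np.log(lib)
    Y = counts.to_numpy(float)
    alphas = _estimate_dispersions(Y, X, offset)
    rows = []
    for gi, gene in enumerate(counts.index):
        y = Y[gi]
        fam = sm.families.NegativeBinomial(alpha=float(alphas[gi]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, X0, family=fam, offset=offset).fit(maxiter=100)
            lr = max(0.0, 2.0 * (full.llf - red.llf))
            p = stats.chi2.sf(lr, df=1)
            logfc = float(full.params[test_col]) / np.log(2.0)
            converged = bool(full.converged and red.converged)
            if not converged:
                p = 1.0
        except Exception:
            logfc, p, converged = 0.0, 1.0, False
        rows.append({"feature": gene, "logFC": logfc, "p": float(p),
                     "dispersion": float(alphas[gi]), "converged": converged})
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# ranking and multiple testing
# ---------------------------------------------------------------------------

def ranking_metric(logfc, p) -> np.ndarray:
    """sign(fold change) x -log10(p), with p clipped at 1e-300."""
    logfc = np.asarray(logfc, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        if np.any(p > 1) or np.any(p < 0):
            raise InvalidInputError("p-values must lie in (0, 1]")
        warnings.warn("p = 0 clipped to 1e-300 in ranking metric")
    clipped = np.clip(p, 1e-300, 1.0)
    return np.sign(logfc) * (-np.log10(clipped))


def build_ranked_list(de_table: pd.DataFrame, metric_col: str | None = None) -> pd.Series:
    """Strictly ordered ranking (descending metric, ties by feature id)."""
    if metric_col is None:
        metric = pd.Series(
            ranking_metric(de_table["logFC"].to_numpy(), de_table["p"].to_numpy()),
            index=de_table.index,
        )
    else:
        metric = de_table[metric_col].astype(float)
    frame = metric.rename("metric").to_frame()
    frame["_feature"] = frame.index.astype(str)
    frame = frame.sort_values(["metric", "_feature"], ascending=[False, True], kind="mergesort")
    return frame["metric"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-matched to the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
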