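"""Statistical primitives used by all pipeline arms.

Contains between-sample normalization (cyclic LOESS on M-A pairs, robust
linear regression against a median reference), per-feature batch-effect
regression, paired and empirical-Bayes moderated t-tests, Benjamini-
Hochberg adjustment, Fisher-exact over-representation, complete-linkage
clustering on Spearman correlation distance, and the two left-censoring
imputation rules ("min" and "MinProp").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess
import statsmodels.api as sm

MatrixLike = Union[pd.DataFrame, "np.ndarray"]


@dataclass
class TestResult:
    """Result of a per-feature two-sample/paired test (log2 scale)."""

    estimate: float
    statistic: float
    df: float
    p_value: float
    q_value: float = np.nan
    n_valid: int = 0


def _as_frame(matrix: MatrixLike) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def cyclic_loess_normalize(
    matrix: MatrixLike, span: float = 0.7, n_cycles: int = 3
) -> pd.DataFrame:
    """Cyclic LOESS normalization on M-A pairs.

    For every ordered sample pair the difference M is regressed on the
    average A (locally weighted, ``span`` fraction of points) over features
    present in both samples, and half of the fitted trend is subtracted from
    one member and added to the other. The pair loop is repeated
    ``n_cycles`` times. Missing values are left untouched.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise ValueError("cyclic LOESS needs at least 2 samples")
    vals = df.to_numpy(dtype=float).copy()
    n_samples = vals.shape[1]
    for _ in range(n_cycles):
        for i in range(n_samples - 1):
            for j in range(i + 1, n_samples):
                x, y = vals[:, i], vals[:, j]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 10:
                    continue
                a = (x[ok] + y[ok]) / 2.0
                m = y[ok] - x[ok]
                if np.allclose(m, 0.0):
                    continue
                fit = lowess(m, a, frac=span, return_sorted=False)
                vals[ok, i] += fit / 2.0
                vals[ok, j] -= fit / 2.0
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def rlr_normalize(matrix: MatrixLike) -> pd.DataFrame:
    """Robust linear regression normalization against a median reference.

    Each sample is regressed on the feature-wise median profile with
    iteratively reweighted least squares (Huber weights); the fitted linear
    distortion is inverted, i.e. ``x_norm = (x - intercept) / slope``.
    """
    df = _as_frame(matrix)
    ref = df.median(axis=1, skipna=True)
    out = df.copy()
    for col in df.columns:
        y = df[col]
        ok = y.notna() & ref.notna()
        if ok.sum() < 3:
            raise ValueError(
                f"sample {col!r} shares fewer than 3 features with the reference"
            )
        X = sm.add_constant(ref[ok].to_numpy())
        with warnings.catch_warnings():
            # exact linear samples trigger a zero-scale "perfect fit" notice
            warnings.simplefilter("ignore")
            fit = sm.RLM(y[ok].to_numpy(), X, M=sm.robust.norms.HuberT()).fit()
        intercept, slope = fit.params
        if abs(slope) < 1e-12:
            raise ValueError(f"degenerate fit (zero slope) for sample {col!r}")
        out[col] = (y - intercept) / slope
    return out


def _batch_design(
    batch_labels: Sequence, group_labels: Sequence
) -> tuple[np.ndarray, np.ndarray, list]:
    """Group one-hot columns plus sum-to-zero batch contrast columns."""
    batch = pd.Categorical(batch_labels)
    group = pd.Categorical(group_labels)
    n = len(batch)
    G = pd.get_dummies(group).to_numpy(dtype=float)
    levels = list(batch.categories)
    B = np.zeros((n, len(levels) - 1))
    codes = batch.codes
    for k in range(len(levels) - 1):
        B[codes == k, k] = 1.0
        B[codes == len(levels) - 1, k] = -1.0
    X = np.hstack([G, B])
    expected_rank = G.shape[1] + B.shape[1]
    if np.linalg.matrix_rank(X) < expected_rank:
        raise ValueError(
            "batch is confounded with group (rank-deficient design); "
            f"batches {levels} cannot be separated from groups "
            f"{list(group.categories)}"
        )
    return X, B, levels


def remove_batch_effects(
    matrix: MatrixLike, batch_labels: Sequence, group_labels: Sequence
) -> pd.DataFrame:
    """Per-feature regression removal of additive batch offsets.

    For every feature, log2 intensity is modelled on group (time point)
    one-hot columns plus sum-to-zero batch contrasts; the fitted batch
    contribution is subtracted. Features with too few valid values for a
    full-rank fit pass through unchanged.
    """
    df = _as_frame(matrix)
    if len(batch_labels) != df.shape[1] or len(group_labels) != df.shape[1]:
        raise ValueError("batch/group labels must match the number of samples")
    X, B, _ = _batch_design(batch_labels, group_labels)
    p = X.shape[1]
    batch_cols = slice(p - B.shape[1], p)
    vals = df.to_numpy(dtype=float).copy()
    for idx in range(vals.shape[0]):
        y = vals[idx]
        ok = np.isfinite(y)
        if ok.sum() < p:
            continue
        Xo = X[ok]
        if np.linalg.matrix_rank(Xo) < p:
            continue
        beta, *_ = np.linalg.lstsq(Xo, y[ok], rcond=None)
        batch_effect = X[:, batch_cols] @ beta[batch_cols]
        vals[idx, ok] = y[ok] - batch_effect[ok]
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def estimate_batch_coefficients(
    matrix: MatrixLike, batch_labels: Sequence, group_labels: Sequence
) -> pd.DataFrame:
    """Per-feature batch contrast coefficients (diagnostic refit)."""
    df = _as_frame(matrix)
    X, B, levels = _batch_design(batch_labels, group_labels)
    p = X.shape[1]
    nb = B.shape[1]
    out = np.full((df.shape[0], nb), np.nan)
    vals = df.to_numpy(dtype=float)
    for idx in range(vals.shape[0]):
        y = vals[idx]
        ok = np.isfinite(y)
        if ok.sum() < p or np.linalg.matrix_rank(X[ok]) < p:
            continue
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        out[idx] = beta[p - nb :]
    return pd.DataFrame(out, index=df.index, columns=[f"batch_{l}" for l in levels[:-1]])


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def paired_t_test(x: Sequence, y: Sequence) -> Optional[TestResult]:
    """Two-sided paired t-test on complete pairs; estimate = mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        return None
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if est == 0.0:
            return TestResult(0.0, 0.0, df, 1.0, n_valid=n)
        warnings.warn(
            "zero variance of paired differences with nonzero mean; "
            "p-value reported as smallest positive float",
            RuntimeWarning,
        )
        t = np.inf if est > 0 else -np.inf
        return TestResult(est, t, df, float(np.nextafter(0.0, 1.0)), n_valid=n)
    t = est / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(est, float(t), float(df), float(p), n_valid=n)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def squeeze_variances(
    s2: np.ndarray,
    df_resid: np.ndarray,
    covariate: Optional[np.ndarray] = None,
    trend_span: float = 0.7,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Empirical-Bayes shrinkage of residual variances.

    Moment-matching on log residual variances against a scaled
    inverse-chi-square prior: with z = log(s2) and
    e = z - digamma(d/2) + log(d/2), the prior df d0 solves
    trigamma(d0/2) = var(e) - mean(trigamma(d/2)) and the prior variance is
    exp(mean(e) + digamma(d0/2) - log(d0/2)). With a covariate the location
    mean(e) is replaced by a LOESS fit of e on the covariate, giving an
    intensity-trended prior.

    Returns (posterior variances, prior df, prior variances per feature).
    """
    s2 = np.asarray(s2, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df_resid > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 finite positive variances")
    z = np.log(s2[ok])
    d = df_resid[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[ok]
        emean = lowess(e, cov, frac=trend_span, return_sorted=False)
    else:
        emean = np.full_like(e, e.mean())
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(
        np.mean(special.polygamma(1, d / 2.0))
    )
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior_ok = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        # degenerate case: variances fully consistent with a single scale;
        # the pooled mean variance is the MLE of that scale (flat prior),
        # with a trend the smoothed location is used instead
        df_prior = np.inf
        if covariate is None:
            s2_prior_ok = np.full_like(e, s2[ok].mean())
        else:
            s2_prior_ok = np.exp(emean)
    s2_prior = np.full_like(s2, np.nan)
    s2_prior[ok] = s2_prior_ok
    s2_post = np.where(
        np.isfinite(s2_prior),
        (np.where(np.isfinite(df_prior), df_prior, 0.0) * np.nan_to_num(s2_prior)
         + df_resid * np.nan_to_num(s2, nan=0.0))
        / np.where(np.isfinite(df_prior), df_prior + df_resid, 1.0),
        s2,
    )
    if not np.isfinite(df_prior):
        s2_post = np.where(np.isfinite(s2_prior), s2_prior, s2)
    return s2_post, df_prior, s2_prior


def moderated_t_test(
    matrix: MatrixLike,
    design: MatrixLike,
    contrast: Sequence,
    trend: bool = False,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Per-feature linear model with empirical-Bayes moderated t statistics.

    ``design`` is samples x coefficients, ``contrast`` a coefficient vector.
    With ``trend=True`` the variance prior is a smooth function of the
    feature's average log2 intensity. ``prior_df`` overrides the estimated
    prior df (0 = ordinary t-tests, ``np.inf`` = full shrinkage to the
    prior trend).

    Returns a DataFrame with estimate / statistic / df / p_value / q_value /
    n_valid per feature (NaN rows where the model cannot be fitted).
    """
    df = _as_frame(matrix)
    X_full = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n_coef = X_full.shape[1]
    if c.shape != (n_coef,):
        raise ValueError("contrast length must equal the number of design columns")
    if X_full.shape[0] != df.shape[1]:
        raise ValueError("design rows must equal the number of samples")
    if np.linalg.matrix_rank(X_full) < n_coef:
        raise ValueError("design matrix is rank deficient")
    if X_full.shape[0] <= n_coef:
        raise ValueError("saturated design: no residual degrees of freedom")

    vals = df.to_numpy(dtype=float)
    n_feat = vals.shape[0]
    est = np.full(n_feat, np.nan)
    se_unscaled = np.full(n_feat, np.nan)
    s2 = np.full(n_feat, np.nan)
    dfr = np.full(n_feat, np.nan)
    amean = np.full(n_feat, np.nan)
    for i in range(n_feat):
        y = vals[i]
        ok = np.isfinite(y)
        n_ok = int(ok.sum())
        if n_ok <= n_coef:
            continue
        Xo = X_full[ok]
        if np.linalg.matrix_rank(Xo) < n_coef:
            continue
        beta, rss, *_ = np.linalg.lstsq(Xo, y[ok], rcond=None)
        resid = y[ok] - Xo @ beta
        rss_val = float(resid @ resid)
        d = n_ok - n_coef
        xtx_inv = np.linalg.pinv(Xo.T @ Xo)
        est[i] = float(c @ beta)
        se_unscaled[i] = float(np.sqrt(c @ xtx_inv @ c))
        s2[i] = rss_val / d
        dfr[i] = d
        amean[i] = float(np.nanmean(y[ok]))

    fit_ok = np.isfinite(s2) & (dfr > 0)
    covariate = amean if trend else None
    if prior_df == 0:
        s2_post = s2.copy()
        df_prior = 0.0
    else:
        sub_cov = covariate[fit_ok] if covariate is not None else None
        s2_post_fit, df_prior_est, s2_prior_fit = squeeze_variances(
            s2[fit_ok], dfr[fit_ok], covariate=sub_cov
        )
        s2_post = s2.copy()
        if prior_df is not None and np.isinf(prior_df):
            s2_post[fit_ok] = s2_prior_fit
            df_prior = np.inf
        elif prior_df is not None:
            df_prior = float(prior_df)
            s2_post[fit_ok] = (
                df_prior * s2_prior_fit + dfr[fit_ok] * s2[fit_ok]
            ) / (df_prior + dfr[fit_ok])
        else:
            s2_post[fit_ok] = s2_post_fit
            df_prior = df_prior_est

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = est / (np.sqrt(s2_post) * se_unscaled)
    df_total = dfr + (df_prior if np.isfinite(df_prior) else 0.0)
    if np.isinf(df_prior):
        p = 2.0 * sps.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * sps.t.sf(np.abs(tstat), df_total)
    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "estimate": est,
            "statistic": tstat,
            "df": df_total,
            "p_value": p,
            "q_value": q,
            "n_valid": np.where(np.isfinite(dfr), dfr + n_coef, 0).astype(int),
            "s2_posterior": s2_post,
            "amean": amean,
        },
        index=df.index,
    )
    out.attrs["df_prior"] = df_prior
    return out


def benjamini_hochberg(p_values: Sequence) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (NaNs propagated)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum() == 0:
        return out
    pv = p[ok]
    n = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q = np.empty(n)
    q[order] = adj
    out[ok] = q
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    feature_set: Iterable,
    background: Iterable,
    annotation_map: Mapping,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher-exact term over-representation of ``feature_set`` vs background.

    ``annotation_map`` maps feature -> iterable of term ids; every feature
    counts once per term regardless of how many sites/rows it contributes
    upstream (callers collapse to features first). Returns one EnrichmentRow
    per term with BH-adjusted q-values.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    fs = set(feature_set)
    if not fs <= bg:
        raise ValueError("feature set must be a subset of the background")
    term_members: dict = {}
    for feat in bg:
        for term in annotation_map.get(feat, ()):
            term_members.setdefault(term, set()).add(feat)
    rows = []
    set_size, bg_size = len(fs), len(bg)
    for term in sorted(term_members):
        members = term_members[term]
        k = len(fs & members)
        K = len(members)
        table = [[k, set_size - k], [K - k, (bg_size - set_size) - (K - k)]]
        _, p = sps.fisher_exact(table, alternative=alternative)
        fold = (k / set_size) / (K / bg_size) if K > 0 and set_size > 0 else 0.0
        rows.append(
            {
                "term": term,
                "k_in_set": k,
                "set_size": set_size,
                "K_in_background": K,
                "background_size": bg_size,
                "fold_enrichment": fold if k > 0 else 0.0,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "k_in_set",
            "set_size",
            "K_in_background",
            "background_size",
            "fold_enrichment",
            "p_value",
        ],
    )
    if len(out):
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["q_value"] = []
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def spearman_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise d = 1 - Spearman rho between profile rows."""
    ranks = np.apply_along_axis(sps.rankdata, 1, profiles.to_numpy(dtype=float))
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norm, norm)
    np.clip(rho, -1.0, 1.0, out=rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist[dist < 0] = 0.0
    return dist

def hierarchical_cluster(profiles: pd.DataFrame, k: int) -> pd.Series:
    """Complete-linkage clustering on Spearman correlation distance.

    Profiles (rows) are clustered with d = 1 - Spearman rho and the tree cut
    into ``k`` flat clusters. Constant profiles, whose rank correlation is
    undefined, are assigned their own singleton clusters (with a warning)
    and do not enter the linkage.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    if profiles.shape[1] < 3:
        raise ValueError("profiles need at least 3 points for rank correlation")
    vals = profiles.to_numpy(dtype=float)
    constant = np.array([np.nanstd(row) == 0 or not np.isfinite(row).all() for row in vals])
    labels = pd.Series(0, index=profiles.index, dtype=int)
    n_const = int(constant.sum())
    if n_const:
        warnings.warn(
            f"{n_const} constant/non-finite profile(s) assigned to singleton clusters",
            RuntimeWarning,
        )
    k_main = max(1, k - n_const)
    main = profiles.loc[~constant]
    if len(main) == 1:
        labels.loc[main.index] = 1
    elif len(main):
        dist = spearman_distance_matrix(main)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        assign = hierarchy.fcluster(Z, t=min(k_main, len(main)), criterion="maxclust")
        labels.loc[main.index] = assign
    next_label = int(labels.max()) + 1
    for i, fid in enumerate(profiles.index[constant]):
        labels.loc[fid] = next_label + i
    return labels


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_min(matrix: MatrixLike) -> pd.DataFrame:
    """Replace every missing value with the global minimum observed value."""
    df = _as_frame(matrix).copy()
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).any():
        raise ValueError("all-missing matrix cannot be imputed")
    return df.fillna(np.nanmin(arr))


def impute_minprop(matrix: MatrixLike, proportion: float = 1.0) -> pd.DataFrame:
    """Replace missing values with ``proportion`` times the global minimum
    observed log2 intensity (left-censored imputation below the detection
    floor)."""
    df = _as_frame(matrix).copy()
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).any():
        raise ValueError("all-missing matrix cannot be imputed")
    return df.fillna(np.nanmin(arr) * proportion)
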