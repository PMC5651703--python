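"""PRE/NRE calling from region count matrices.

Counts per SNP region across input (plasmid) and output (reporter mRNA)
libraries are normalized with median-of-ratios size factors, then each
region's output-vs-input log2 fold change is estimated by a
negative-binomial log-linear model and tested with a Wald statistic.
Regions passing a mean-normalized-count filter are classified, after BH
adjustment at FDR < 0.01, as PREs (log2FC > 0) or NREs (log2FC < 0).

The testing stage is a self-contained reimplementation of the standard
count-based differential procedure: per-region method-of-moments
dispersions are smoothed toward a fitted mean-dispersion trend
(alpha(mu) = a1/mu + a0) with empirical-Bayes shrinkage in log space,
and the fold change is the unshrunk maximum-likelihood estimate from an
iteratively reweighted fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors_median_of_ratios",
    "estimate_dispersions",
    "nb_wald_lfc",
    "bh_adjust",
    "classify_elements",
    "call_activity",
]

_LN2 = np.log(2.0)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each library j, the factor is the median over regions r of
    ``counts[r, j] / geometric_mean_over_libraries(counts[r, :])``,
    using only regions whose geometric mean is positive (i.e. rows with
    all-positive counts).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a regions x libraries matrix")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no region has all-positive counts; cannot compute size factors")
    logmat = np.log(mat[positive])
    log_geo = logmat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logmat - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _design(columns, design: pd.Series | dict | list) -> np.ndarray:
    """Map library columns to 0 (input) / 1 (output)."""
    if isinstance(design, (pd.Series, dict)):
        labels = [design[c] for c in columns]
    else:
        labels = list(design)
    if len(labels) != len(columns):
        raise ValueError("design length does not match number of libraries")
    x = np.array([1.0 if str(l).lower().startswith("out") else 0.0 for l in labels])
    if x.min() == x.max():
        raise ValueError("design must contain both input and output libraries")
    return x


def estimate_dispersions(
    counts: np.ndarray,
    size_factors: np.ndarray,
    x: np.ndarray,
    prior_var: float = 0.25,
    min_disp: float = 1e-8,
    max_disp: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per-region NB dispersions: method of moments, trend, shrinkage.

    Method-of-moments raw estimates on normalized counts are fitted with
    a nonnegative trend ``alpha(mu) = a1/mu + a0`` by trimmed least
    squares, then shrunk toward the trend in log space with prior
    variance ``prior_var``; the raw estimate's sampling variance is
    approximated as 2/(m - p) for m libraries and p = 2 coefficients.
    """
    norm = counts / size_factors
    m = counts.shape[1]
    mu_bar = norm.mean(axis=1)

    # within-group variance (pooled over the two conditions)
    ss = np.zeros(counts.shape[0])
    for grp in (x == 0, x == 1):
        sub = norm[:, grp]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = max(m - 2, 1)
    var_w = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_w - mu_bar) / mu_bar**2
    usable = np.isfinite(alpha_mom) & (alpha_mom > min_disp) & (mu_bar > 0)

    # trend fit alpha = a0 + a1/mu, nonnegative coefficients, one trim pass
    a0, a1 = 0.01, 1.0
    if usable.sum() >= 10:
        from scipy.optimize import nnls

        sel = usable.copy()
        for _ in range(2):
            A = np.column_stack([np.ones(sel.sum()), 1.0 / mu_bar[sel]])
            coef, _ = nnls(A, alpha_mom[sel])
            a0, a1 = float(coef[0]), float(coef[1])
            resid = alpha_mom - (a0 + a1 / np.maximum(mu_bar, 1e-12))
            mad = np.median(np.abs(resid[sel] - np.median(resid[sel]))) + 1e-12
            new_sel = usable & (np.abs(resid) < 5 * 1.4826 * mad)
            if new_sel.sum() < 10 or new_sel.sum() == sel.sum():
                break
            sel = new_sel
    alpha_trend = np.clip(a0 + a1 / np.maximum(mu_bar, 1e-12), min_disp, max_disp)

    # empirical-Bayes shrinkage in log space: per-region MAP of the NB
    # likelihood (at the fitted group means) under a log-normal prior
    # centered on the trend. A grid over log-dispersion with parabolic
    # refinement is robust to the flat likelihoods of underdispersed
    # regions, where a point-estimate shrink would collapse toward zero.
    alpha_map = _map_dispersion(counts, size_factors, x, alpha_trend,
                                prior_var, min_disp, max_disp)
    return {
        "alpha_mom": np.where(usable, alpha_mom, np.nan),
        "alpha_trend": alpha_trend,
        "alpha_map": alpha_map,
        "trend_coef": np.array([a0, a1]),
    }


def _map_dispersion(
    counts: np.ndarray,
    size_factors: np.ndarray,
    x: np.ndarray,
    alpha_trend: np.ndarray,
    prior_var: float,
    min_disp: float,
    max_disp: float,
    n_grid: int = 60,
) -> np.ndarray:
    """MAP log-dispersion per region: NB likelihood x log-normal(trend) prior."""
    from scipy.special import gammaln

    norm = counts / size_factors
    # fitted means under the saturated two-group model
    mu = np.empty_like(counts, dtype=float)
    for grp in (x == 0, x == 1):
        q = norm[:, grp].mean(axis=1, keepdims=True)
        mu[:, grp] = np.maximum(q, 1e-8) * size_factors[None, grp]

    log_grid = np.linspace(np.log(min_disp), np.log(max_disp), n_grid)
    log_trend = np.log(alpha_trend)
    post = np.empty((counts.shape[0], n_grid))
    in_grp, out_grp = x == 0, x == 1
    for k, la in enumerate(log_grid):
        alpha = np.exp(la)
        r = 1.0 / alpha
        ll = (
            gammaln(counts + r) - gammaln(r) - gammaln(counts + 1.0)
            + r * np.log(r / (r + mu)) + counts * np.log(mu / (r + mu) + 1e-300)
        ).sum(axis=1)
        # Cox-Reid adjustment: -0.5 log det(X'WX); for the two-group
        # design this is the product of the per-group weight sums.
        w = mu / (1.0 + alpha * mu)
        cr = -0.5 * (np.log(w[:, in_grp].sum(axis=1) + 1e-300)
                     + np.log(w[:, out_grp].sum(axis=1) + 1e-300))
        post[:, k] = ll + cr - (la - log_trend) ** 2 / (2.0 * prior_var)

    best = np.argmax(post, axis=1)
    # parabolic refinement on the three points around the grid max
    la_hat = log_grid[best]
    interior = (best > 0) & (best < n_grid - 1)
    i = best[interior]
    y0 = post[interior, i - 1]
    y1 = post[interior, i]
    y2 = post[interior, i + 1]
    h = log_grid[1] - log_grid[0]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * h * (y0 - y2) / denom, 0.0)
    la_hat[interior] = log_grid[i] + np.clip(shift, -h, h)
    return np.clip(np.exp(la_hat), min_disp, max_disp)


def nb_wald_lfc(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.Series | dict | list,
    dispersion: float | np.ndarray | None = None,
    prior_var: float = 0.25,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Per-region NB Wald test of output vs input.

    Fits ``mu_ij = s_j * exp(b0_i + b1_i * x_j)`` (x_j = 1 for output
    libraries) by iteratively reweighted least squares with fixed
    per-region dispersion, and reports the fold change on the log2 scale
    with its Wald z statistic and two-sided normal p value.

    Parameters
    ----------
    counts
        Regions x libraries integer count matrix.
    size_factors
        Per-library size factors (see :func:`size_factors_median_of_ratios`).
    design
        Input/output label per library column.
    dispersion
        Fixed dispersion(s) overriding estimation; ``None`` estimates
        per-region dispersions (see :func:`estimate_dispersions`).

    Returns
    -------
    DataFrame indexed like ``counts`` with columns ``baseMean, log2FC,
    lfcSE, stat, pvalue, dispersion``. Regions with an all-zero condition
    get NaN statistics (they cannot support an estimate).
    """
    y = counts.to_numpy(dtype=float)
    s = np.asarray([size_factors[c] for c in counts.columns], dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("size factors must be finite and positive")
    x = _design(counts.columns, design)
    n_reg, m = y.shape

    norm = y / s
    base_mean = norm.mean(axis=1)

    if dispersion is None:
        disp = estimate_dispersions(y, s, x, prior_var=prior_var)["alpha_map"]
    else:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_reg,)).copy()

    in_tot = norm[:, x == 0].sum(axis=1)
    out_tot = norm[:, x == 1].sum(axis=1)
    estimable = (in_tot > 0) & (out_tot > 0)

    # IRLS, vectorized across regions (design shared by all regions)
    X = np.column_stack([np.ones(m), x])
    offs = np.log(s)
    n_in = (x == 0).sum()
    n_out = (x == 1).sum()
    b0 = np.log(np.maximum(in_tot / n_in, 1e-8))
    b1 = np.log(np.maximum(out_tot / n_out, 1e-8)) - b0
    b1 = np.clip(b1, -30, 30)
    beta = np.column_stack([b0, b1])

    alpha = disp[:, None]
    for _ in range(max_iter):
        eta = offs[None, :] + beta @ X.T
        mu = np.exp(np.clip(eta, -300, 300))
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + alpha * mu)  # NB working weights, log link
        z = eta - offs[None, :] + (y - mu) / mu
        # normal equations per region: (X' W X) beta = X' W z
        a11 = w.sum(axis=1)
        a12 = (w * x).sum(axis=1)
        a22 = (w * x * x).sum(axis=1)
        r1 = (w * z).sum(axis=1)
        r2 = (w * z * x).sum(axis=1)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (a22 * r1 - a12 * r2) / det
        new_b1 = (a11 * r2 - a12 * r1) / det
        new_beta = np.column_stack([new_b0, new_b1])
        new_beta = np.clip(new_beta, -30, 30)
        delta = np.nanmax(np.abs(new_beta - beta))
        beta = np.where(np.isfinite(new_beta), new_beta, beta)
        if not np.isfinite(delta) or delta < tol:
            break

    eta = offs[None, :] + beta @ X.T
    mu = np.maximum(np.exp(np.clip(eta, -300, 300)), 1e-10)
    w = mu / (1.0 + alpha * mu)
    a11 = w.sum(axis=1)
    a12 = (w * x).sum(axis=1)
    a22 = (w * x * x).sum(axis=1)
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = a11 / det
    se = np.sqrt(np.maximum(var_b1, 0))

    log2fc = beta[:, 1] / _LN2
    lfc_se = se / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta[:, 1] / se
    pval = 2.0 * stats.norm.sf(np.abs(stat))

    bad = ~estimable | ~np.isfinite(se) | (se == 0)
    for arr in (log2fc, lfc_se, stat, pval):
        arr[bad] = np.nan

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pval,
            "dispersion": disp,
        },
        index=counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, clipped at 1).

    NaN entries are passed through unadjusted and excluded from m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_elements(
    results: pd.DataFrame,
    fdr_alpha: float = 0.01,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Classify regions as PRE / NRE / inactive / filtered.

    Regions with ``baseMean < min_base_mean`` (or unestimable statistics)
    are ``filtered`` and excluded from the BH family; the rest are PRE if
    adjusted p < ``fdr_alpha`` with log2FC > 0, NRE if log2FC < 0, and
    inactive otherwise.
    """
    out = results.copy()
    testable = (out["baseMean"] >= min_base_mean) & out["pvalue"].notna()
    out["padj"] = np.nan
    out.loc[testable, "padj"] = bh_adjust(out.loc[testable, "pvalue"].to_numpy())
    cls = np.where(~testable, "filtered", "inactive").astype(object)
    sig = testable & (out["padj"] < fdr_alpha)
    cls[sig & (out["log2FC"] > 0)] = "PRE"
    cls[sig & (out["log2FC"] < 0)] = "NRE"
    out["class"] = cls
    return out


def call_activity(
    counts: pd.DataFrame,
    design: pd.Series | dict | list,
    fdr_alpha: float = 0.01,
    min_base_mean: float = 10.0,
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Full activity-calling stage: size factors -> NB Wald -> classification."""
    sf = size_factors_median_of_ratios(counts)
    res = nb_wald_lfc(counts, sf, design, dispersion=dispersion)
    return classify_elements(res, fdr_alpha=fdr_alpha, min_base_mean=min_base_mean)
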