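"""Regulatory-SNP detection from allelic imbalance.

A SNP covered by both alleles in the reporter library is tested for a
change in its allele ratio between the output (reporter mRNA) and input
(plasmid) libraries. Replicate allele counts are depth-normalized and
pooled per condition, sparse SNPs are dropped, the effect size is the
ratio of allele ratios (output over input, alt over ref), and the
two-sided Fisher exact test on the pooled 2x2 table supplies the p value.
BH adjustment controls the FDR at 10% by default.

The exact-test odds ratio reported throughout the package is the
conditional maximum-likelihood estimate (CMLE) under the noncentral
hypergeometric model given the table margins -- the estimate classical
Fisher-test implementations report -- with an exact-tail confidence
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .activity_calling import bh_adjust

__all__ = ["FisherResult", "fisher_exact_cmle", "pooled_allele_table", "allelic_test"]


@dataclass
class FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio."""

    p_value: float
    odds_ratio: float  # conditional MLE; nan when a margin is zero
    ci_low: float
    ci_high: float
    table: tuple[tuple[int, int], tuple[int, int]] = field(default=None)


def _cond_mean(log_psi: float, n: int, c1: int, r1: int) -> float:
    """E[X] under the Fisher noncentral hypergeometric with odds exp(log_psi)."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    # log pmf up to a constant: log C(c1, x) + log C(n-c1, r1-x) + x*log psi
    logw = (
        stats.binom._logpmf(x, c1, 0.5)  # log C(c1,x) - c1*log2
        + stats.binom._logpmf(r1 - x, n - c1, 0.5)
        + x * log_psi
    )
    logw -= logw.max()
    w = np.exp(logw)
    return float((x * w).sum() / w.sum())


def _cond_tail(log_psi: float, n: int, c1: int, r1: int, x_obs: int,
               upper: bool) -> float:
    """P(X >= x_obs) (upper) or P(X <= x_obs) under odds exp(log_psi)."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    logw = (
        stats.binom._logpmf(x, c1, 0.5)
        + stats.binom._logpmf(r1 - x, n - c1, 0.5)
        + x * log_psi
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return float(w[x >= x_obs].sum() if upper else w[x <= x_obs].sum())


_LOG_PSI_MAX = 50.0


def fisher_exact_cmle(table, conf_level: float = 0.95, ci: bool = True,
                      estimate: bool = True) -> FisherResult:
    """Two-sided Fisher exact test with the conditional-MLE odds ratio.

    Parameters
    ----------
    table
        2x2 array-like of non-negative integer counts ``[[a, b], [c, d]]``.
    conf_level
        Coverage of the exact-tail confidence interval.

    Returns
    -------
    FisherResult
        Two-sided p (sum of null-table probabilities not exceeding the
        observed table's), the odds ratio maximizing the noncentral
        hypergeometric likelihood conditional on the margins, and the
        exact conditional confidence interval. A zero margin yields
        ``p = 1`` and an undefined (nan) odds ratio.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    a, b = int(round(t[0, 0])), int(round(t[0, 1]))
    c, d = int(round(t[1, 0])), int(round(t[1, 1]))
    n = a + b + c + d
    r1, c1 = a + b, a + c

    if r1 == 0 or c1 == 0 or r1 == n or c1 == n or n == 0:
        return FisherResult(1.0, math.nan, math.nan, math.nan,
                            ((a, b), (c, d)))

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    lo_sup = max(0, r1 + c1 - n)
    hi_sup = min(r1, c1)

    if not estimate:
        return FisherResult(float(p), math.nan, math.nan, math.nan, ((a, b), (c, d)))

    # Conditional MLE: psi solving E_psi[X] = a; boundary -> 0 or inf.
    if a == lo_sup:
        or_hat = 0.0
    elif a == hi_sup:
        or_hat = math.inf
    else:
        f = lambda lp: _cond_mean(lp, n, c1, r1) - a
        or_hat = math.exp(optimize.brentq(f, -_LOG_PSI_MAX, _LOG_PSI_MAX,
                                          xtol=1e-12))

    if not ci:
        return FisherResult(float(p), or_hat, math.nan, math.nan, ((a, b), (c, d)))

    alpha = (1.0 - conf_level) / 2.0
    if a == lo_sup:
        ci_low = 0.0
    else:
        g = lambda lp: _cond_tail(lp, n, c1, r1, a, upper=True) - alpha
        ci_low = math.exp(optimize.brentq(g, -_LOG_PSI_MAX, _LOG_PSI_MAX))
    if a == hi_sup:
        ci_high = math.inf
    else:
        h = lambda lp: _cond_tail(lp, n, c1, r1, a, upper=False) - alpha
        ci_high = math.exp(optimize.brentq(h, -_LOG_PSI_MAX, _LOG_PSI_MAX))

    return FisherResult(float(p), or_hat, ci_low, ci_high, ((a, b), (c, d)))


def pooled_allele_table(
    allele_counts: pd.DataFrame,
    library_depths: pd.Series | dict | None = None,
    min_pooled: float = 10.0,
    mode: str = "depth",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize, pool, and filter per-SNP allele counts.

    Parameters
    ----------
    allele_counts
        Long table with columns ``snp_id, library, condition, replicate,
        ref_count, alt_count`` (``condition`` in {"input", "output"}).
    library_depths
        Total retained allele observations per library; computed from the
        table when omitted. A zero depth is an error.
    min_pooled
        A SNP is dropped when ANY of its four pooled normalized counts
        (input/output x ref/alt) is below this threshold.
    mode
        ``"depth"`` rescales each library so totals are equal across
        libraries (default). ``"snp_coverage"`` rescales each library by
        its median per-SNP coverage instead.

    Returns
    -------
    (kept, dropped)
        Wide tables indexed by snp_id with columns ``in_ref, in_alt,
        out_ref, out_alt`` (pooled normalized counts).
    """
    required = {"snp_id", "library", "condition", "replicate", "ref_count", "alt_count"}
    missing = required - set(allele_counts.columns)
    if missing:
        raise ValueError(f"allele_counts missing columns: {sorted(missing)}")
    ac = allele_counts.copy()
    ac["total"] = ac["ref_count"] + ac["alt_count"]

    if library_depths is None:
        if mode == "snp_coverage":
            depths = ac.groupby("library")["total"].median()
        else:
            depths = ac.groupby("library")["total"].sum()
    else:
        depths = pd.Series(library_depths, dtype=float)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0].tolist()
        raise ValueError(f"zero or negative depth for libraries: {bad}")

    scale = depths.mean() / depths
    ac["scale"] = ac["library"].map(scale)
    ac["ref_norm"] = ac["ref_count"] * ac["scale"]
    ac["alt_norm"] = ac["alt_count"] * ac["scale"]

    pooled = (
        ac.groupby(["snp_id", "condition"])[["ref_norm", "alt_norm"]]
        .sum()
        .unstack("condition")
    )
    wide = pd.DataFrame(
        {
            "in_ref": pooled.get(("ref_norm", "input"), 0.0),
            "in_alt": pooled.get(("alt_norm", "input"), 0.0),
            "out_ref": pooled.get(("ref_norm", "output"), 0.0),
            "out_alt": pooled.get(("alt_norm", "output"), 0.0),
        }
    ).fillna(0.0)
    keep = (wide >= min_pooled).all(axis=1)
    return wide[keep], wide[~keep]


def allelic_test(
    pooled: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Test each SNP for allelic imbalance between output and input.

    The effect size is the fold change of allele ratios,
    ``(out_alt/out_ref) / (in_alt/in_ref)``; its reciprocal is reported
    too. Pooled normalized counts are rounded half-to-even to form the
    integer 2x2 table (alleles x condition) for the exact test; BH
    adjustment across all tested SNPs flags regulatory SNPs at adjusted
    p < ``fdr_alpha``. ``activity`` (a classified per-region result table
    indexed by snp_id with a ``class`` column) annotates each SNP with its
    host element class; absent SNPs get ``"untested"``.
    """
    rows = []
    for snp_id, r in pooled.iterrows():
        in_ref, in_alt = float(r["in_ref"]), float(r["in_alt"])
        out_ref, out_alt = float(r["out_ref"]), float(r["out_alt"])
        if min(in_ref, out_ref) > 0 and min(in_alt, out_alt) >= 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                effect = (out_alt / out_ref) / (in_alt / in_ref) if in_alt > 0 else np.nan
        else:
            effect = np.nan
        # numpy round is half-to-even
        tbl = np.round([[in_ref, in_alt], [out_ref, out_alt]]).astype(int)
        res = fisher_exact_cmle(tbl, ci=False)
        rows.append(
            {
                "snp_id": snp_id,
                "in_ref": in_ref,
                "in_alt": in_alt,
                "out_ref": out_ref,
                "out_alt": out_alt,
                "effect_size": effect,
                "effect_size_recip": 1.0 / effect if effect and np.isfinite(effect) and effect > 0 else np.nan,
                "odds_ratio": res.odds_ratio,
                "pvalue": res.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("snp_id")
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out["regulatory"] = out["padj"] < fdr_alpha
    else:
        out["padj"] = pd.Series(dtype=float)
        out["regulatory"] = pd.Series(dtype=bool)

    if activity is not None and "class" in getattr(activity, "columns", []):
        host = activity["class"]
        out["host_class"] = [host.get(s, "untested") for s in out.index]
    else:
        out["host_class"] = "untested"
    return out
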