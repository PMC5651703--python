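"""Two-step eQTL regression with covariate residualization.

Per-gene expression E is first regressed on somatic copy number C and
promoter methylation M (step 1, OLS with intercept); the residuals are
then regressed on genotype dosage G (step 2, OLS with intercept), whose
coefficient, t statistic, and p value are the eQTL result. When G is
orthogonal in sample to (1, C, M), the two-step genotype estimate equals
the G coefficient of the joint regression E ~ C + M + G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["EqtlResult", "fit_two_step", "group_contrast"]


@dataclass
class EqtlResult:
    step1_coef: dict          # intercept, C, M coefficients
    residuals: np.ndarray     # step-1 residuals (sum to zero)
    genotype_effect: float
    stderr: float
    t_stat: float
    p_value: float
    n_used: int
    n_dropped_missing: int


def fit_two_step(data: pd.DataFrame, tail: str = "two-sided") -> EqtlResult:
    """Fit the two-step model E ~ C + M (residualize), then eps ~ G.

    Parameters
    ----------
    data
        Per-sample table with columns E (expression), C (copy number),
        M (promoter methylation), G (genotype dosage 0/1/2). Rows with
        missing values are dropped listwise (count reported).
    tail
        "two-sided" or "one-sided" (upper-tail) p for the genotype t.
    """
    required = {"E", "C", "M", "G"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    sub = data[["E", "C", "M", "G"]].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    n = len(complete)
    if n < 4:
        raise ValueError(f"need at least 4 complete samples, have {n}")
    g = complete["G"].to_numpy(float)
    if np.ptp(g) == 0:
        raise ValueError("no genotype variance: G is constant")

    X1 = sm.add_constant(complete[["C", "M"]].to_numpy(float))
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("step-1 design is rank deficient")
    fit1 = sm.OLS(complete["E"].to_numpy(float), X1).fit()
    resid = fit1.resid

    X2 = sm.add_constant(g)
    fit2 = sm.OLS(resid, X2).fit()
    beta = float(fit2.params[1])
    se = float(fit2.bse[1])
    t = float(fit2.tvalues[1])
    if tail == "two-sided":
        p = float(fit2.pvalues[1])
    elif tail == "one-sided":
        from scipy import stats

        p = float(stats.t.sf(t, df=fit2.df_resid))
    else:
        raise ValueError("tail must be 'two-sided' or 'one-sided'")
    return EqtlResult(
        step1_coef={"intercept": float(fit1.params[0]), "C": float(fit1.params[1]),
                    "M": float(fit1.params[2])},
        residuals=np.asarray(resid),
        genotype_effect=beta,
        stderr=se,
        t_stat=t,
        p_value=p,
        n_used=n,
        n_dropped_missing=n_dropped,
    )


def group_contrast(data: pd.DataFrame, carrier_dosages=(1, 2), tail: str = "one-sided") -> dict:
    """Group-mean contrast of step-1 residuals: carrier vs non-carrier genotypes.

    Residualizes as in :func:`fit_two_step`, then compares residual means
    between samples whose dosage is in ``carrier_dosages`` and the rest
    with Welch's t-test (upper tail by default).
    """
    from scipy import stats

    res = fit_two_step(data, tail="two-sided")
    sub = data[["E", "C", "M", "G"]].apply(pd.to_numeric, errors="coerce").dropna()
    carrier = sub["G"].isin(carrier_dosages).to_numpy()
    if carrier.all() or not carrier.any():
        raise ValueError("both genotype groups must be non-empty")
    a, b = res.residuals[carrier], res.residuals[~carrier]
    t, p2 = stats.ttest_ind(a, b, equal_var=False)
    p = p2 / 2 if (tail == "one-sided" and t > 0) else (1 - p2 / 2 if tail == "one-sided" else p2)
    return {"mean_carrier": float(a.mean()), "mean_noncarrier": float(b.mean()),
            "t_stat": float(t), "p_value": float(p), "n_carrier": int(carrier.sum()),
            "n_noncarrier": int((~carrier).sum())}
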