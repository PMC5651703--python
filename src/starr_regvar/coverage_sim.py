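"""Both-allele SNP coverage versus number of pooled individuals.

Design-stage question: if genomic DNA from i individuals is pooled and
captured, what fraction of the panel's SNPs have BOTH alleles present in
the pool? The simulation samples i individuals without replacement from
a genotype pool and reports P_i = N_i / panel_size over repeats; the
closed form 1 - (1-f)^(2i) - f^(2i) is the with-replacement HWE
counterpart used for validation on large pools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["analytic_coverage", "coverage_curve"]


def analytic_coverage(maf, i: int):
    """P(both alleles among 2i chromosomes) under HWE: 1-(1-f)^2i - f^2i."""
    f = np.asarray(maf, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("maf must lie in [0, 1]")
    if i < 1:
        raise ValueError("i must be >= 1")
    out = 1.0 - (1.0 - f) ** (2 * i) - f ** (2 * i)
    return float(out) if np.isscalar(maf) else out


def coverage_curve(
    pool: pd.DataFrame,
    sizes,
    repeats: int = 5,
    seed: int = 0,
    panel_size: int | None = None,
) -> pd.DataFrame:
    """Simulated both-allele coverage for each pool size.

    Parameters
    ----------
    pool
        Individuals x SNPs alt-dosage matrix (0/1/2).
    sizes
        Numbers of individuals i to draw (each <= pool size).
    repeats
        Random draws per size; mean and sd reported over them.
    panel_size
        Denominator for P_i (defaults to the number of pool columns;
        the designed panel may exceed the polymorphic SNP count).

    Returns
    -------
    DataFrame (i, mean_P, sd, repeats), one row per requested size.
    """
    geno = pool.to_numpy()
    n_ind, n_snp = geno.shape
    denom = n_snp if panel_size is None else int(panel_size)
    rng = np.random.default_rng(seed)
    rows = []
    for i in sizes:
        i = int(i)
        if i < 1 or i > n_ind:
            raise ValueError(f"sample size {i} outside [1, {n_ind}]")
        ps = []
        for _ in range(repeats):
            pick = rng.choice(n_ind, size=i, replace=False)
            dosage = geno[pick].sum(axis=0)
            both = (dosage > 0) & (dosage < 2 * i)
            ps.append(both.sum() / denom)
        ps = np.asarray(ps)
        rows.append({"i": i, "mean_P": ps.mean(), "sd": ps.std(ddof=1) if repeats > 1 else 0.0,
                     "repeats": repeats})
    return pd.DataFrame(rows)
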