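"""Annotation-peak enrichment and PWM allele delta scoring.

Two downstream analyses of a called screen:

* overlap enrichment — is one class of SNPs (e.g. PRE/NRE members, or
  regulatory SNPs) found inside annotation peaks more often than a
  reference class? A SNP overlaps a peak iff its position is covered by
  the peak interval; the 2x2 table goes to the conditional-MLE Fisher
  exact test.

* motif delta scores — for each SNP x PWM, the best log2 likelihood-ratio
  window score over all windows covering the SNP (both strands by
  default), for the reference and the alternative allele; the delta is
  alt minus ref, and |delta| >= 3 marks a putative motif disruption.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .allelic_analysis import FisherResult, fisher_exact_cmle

logger = logging.getLogger(__name__)

__all__ = [
    "snps_in_peaks",
    "overlap_enrichment",
    "score_sequence",
    "pwm_delta_scores",
    "delta_enrichment",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# peak overlap


def _merged_intervals(peaks: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in peaks.groupby("chrom"):
        iv = sub[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def snps_in_peaks(positions: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean mask: SNP position (1-based ``pos``) covered by any peak.

    Sorted-sweep membership over merged peak intervals (0-based
    half-open); equivalent to naive interval membership.
    """
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peaks must satisfy start < end")
    merged = _merged_intervals(peaks)
    mask = np.zeros(len(positions), dtype=bool)
    for chrom, sub in positions.groupby("chrom"):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos0 = sub["pos"].to_numpy() - 1
        k = np.searchsorted(starts, pos0, side="right") - 1
        hit = (k >= 0) & (pos0 < ends[np.clip(k, 0, None)])
        mask[sub.index.to_numpy()] = hit
    return mask


def overlap_enrichment(
    snps_by_class: dict[str, pd.DataFrame],
    peaks: pd.DataFrame,
    test_class: str,
    reference_class: str,
) -> dict:
    """Peak-overlap enrichment of ``test_class`` SNPs vs ``reference_class``.

    ``snps_by_class`` maps class name -> DataFrame with columns
    ``chrom, pos`` (1-based). Builds the in-peak/not x test/reference 2x2
    table and reports the conditional-MLE odds ratio, exact CI, and
    two-sided Fisher p.
    """
    for name in (test_class, reference_class):
        if name not in snps_by_class or len(snps_by_class[name]) == 0:
            raise ValueError(f"class {name!r} is empty or missing")
    cells = {}
    for name in (test_class, reference_class):
        df = snps_by_class[name].reset_index(drop=True)
        inside = int(snps_in_peaks(df, peaks).sum()) if len(peaks) else 0
        cells[name] = (inside, len(df) - inside)
    table = [list(cells[test_class]), list(cells[reference_class])]
    res = fisher_exact_cmle(table)
    return {
        "test_class": test_class,
        "reference_class": reference_class,
        "table": table,
        "odds_ratio": res.odds_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.p_value,
    }


# ---------------------------------------------------------------------------
# PWM scoring


def _log_odds(pwm: np.ndarray, pseudocount: float, background: np.ndarray) -> np.ndarray:
    p = (np.asarray(pwm, float) + pseudocount)
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / background[None, :])


def score_sequence(seq: str, logodds: np.ndarray) -> float:
    """Sum of per-position log2 odds of ``seq`` (len == motif width)."""
    if len(seq) != logodds.shape[0]:
        raise ValueError("sequence length must equal motif width")
    total = 0.0
    for i, b in enumerate(seq.upper()):
        j = _BASE_IDX.get(b)
        if j is None:
            return -np.inf
        total += logodds[i, j]
    return float(total)


def _best_window(seq: str, snp_off: int, logodds: np.ndarray, both_strands: bool) -> float:
    """Max window score over windows covering offset ``snp_off`` in ``seq``."""
    w = logodds.shape[0]
    best = -np.inf
    lo = max(0, snp_off - w + 1)
    hi = min(len(seq) - w, snp_off)
    for s in range(lo, hi + 1):
        window = seq[s:s + w]
        best = max(best, score_sequence(window, logodds))
        if both_strands:
            rc = window.translate(_COMPLEMENT)[::-1]
            best = max(best, score_sequence(rc, logodds))
    return best


def pwm_delta_scores(
    panel: pd.DataFrame,
    sequences: dict[str, str],
    pwms: dict[str, np.ndarray],
    flank: int = 0,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Allele binding-score deltas for every SNP x PWM pair.

    For each allele, the score is the maximum over all motif windows
    covering the SNP position (both strands unless disabled) of the
    summed per-base log2(p/background). ``delta = alt_score - ref_score``.
    SNPs whose sequence context (motif width - 1 + ``flank`` either side)
    is unavailable are skipped with a warning.

    ``sequences`` maps chrom -> full chromosome/contig sequence.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rows = []
    for motif_id, pwm in pwms.items():
        lo = _log_odds(pwm, pseudocount, bg)
        w = lo.shape[0]
        ctx = w - 1 + flank
        for snp in panel.itertuples(index=False):
            seq = sequences.get(snp.chrom)
            if seq is None:
                continue
            pos0 = snp.pos - 1
            lo_b, hi_b = pos0 - ctx, pos0 + ctx + 1
            if lo_b < 0 or hi_b > len(seq) or not (0 <= pos0 < len(seq)):
                logger.warning("SNP %s outside sequence bounds; skipped", snp.snp_id)
                continue
            context = seq[lo_b:hi_b].upper()
            off = pos0 - lo_b
            ref_ctx = context[:off] + snp.ref + context[off + 1:]
            alt_ctx = context[:off] + snp.alt + context[off + 1:]
            ref_s = _best_window(ref_ctx, off, lo, both_strands)
            alt_s = _best_window(alt_ctx, off, lo, both_strands)
            if not (np.isfinite(ref_s) or np.isfinite(alt_s)):
                continue
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "motif_id": motif_id,
                    "ref_score": ref_s,
                    "alt_score": alt_s,
                    "delta": alt_s - ref_s,
                }
            )
    return pd.DataFrame(rows, columns=["snp_id", "motif_id", "ref_score", "alt_score", "delta"])


def delta_enrichment(
    deltas: pd.DataFrame,
    classes: pd.Series | dict,
    threshold: float = 3.0,
    peak_support: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    factor_map: dict | None = None,
) -> pd.DataFrame:
    """Enrichment of motif-disrupting alleles across SNP classes.

    A SNP is motif-disrupting when max |delta| over PWMs >= ``threshold``
    (and, when ``peak_support``/``panel`` are given, the SNP lies in a
    peak of the motif's mapped track per ``factor_map``). Tests
    "regulatory" against each other class present (e.g.
    "active_nonregulatory", "inactive") with the conditional-MLE Fisher
    test; one row per comparison.
    """
    classes = pd.Series(classes)
    if len(deltas) == 0:
        raise ValueError("no delta scores provided")
    d = deltas.copy()
    if peak_support is not None and panel is not None:
        from_peaks = _motif_peak_support(d, peak_support, panel, factor_map)
        d = d[from_peaks]
    agg = d.groupby("snp_id")["delta"].agg(lambda v: float(np.max(np.abs(v))))
    disrupting = agg[agg >= threshold].index

    rows = []
    test_class = "regulatory"
    others = [c for c in pd.unique(classes) if c != test_class]
    if test_class not in set(classes):
        raise ValueError("no SNPs labelled 'regulatory'")
    for other in others:
        cells = []
        for name in (test_class, other):
            ids = classes.index[classes == name]
            if len(ids) == 0:
                raise ValueError(f"class {name!r} is empty")
            n_dis = int(pd.Index(ids).isin(disrupting).sum())
            cells.append([n_dis, len(ids) - n_dis])
        res = fisher_exact_cmle(cells)
        rows.append(
            {
                "test_class": test_class,
                "reference_class": other,
                "n_disrupting_test": cells[0][0],
                "n_test": sum(cells[0]),
                "n_disrupting_ref": cells[1][0],
                "n_ref": sum(cells[1]),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pvalue": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _motif_peak_support(deltas, peaks, panel, factor_map) -> np.ndarray:
    """Mask of delta rows whose SNP lies in a peak of the motif's track."""
    pos_of = panel.set_index("snp_id")[["chrom", "pos"]]
    mask = np.zeros(len(deltas), dtype=bool)
    for i, row in enumerate(deltas.itertuples(index=False)):
        track = (factor_map or {}).get(row.motif_id, row.motif_id)
        sub = peaks[peaks["name"] == track] if "name" in peaks.columns else peaks
        if len(sub) == 0 or row.snp_id not in pos_of.index:
            continue
        snp = pos_of.loc[[row.snp_id]].reset_index(drop=True)
        mask[i] = bool(snps_in_peaks(snp, sub)[0])
    return mask
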