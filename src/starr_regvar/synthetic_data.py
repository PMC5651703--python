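"""Synthetic reporter-screen datasets with known ground truth.

Emulates the structure of a capture-based STARR-seq screen over a panel
of tag + linked SNPs: a diploid genotype pool drawn under Hardy-Weinberg
equilibrium, ~465-bp fragments tiling each SNP's +/-250 bp region and
carrying one allele per covered SNP, input/output count libraries with
planted per-region activities and planted allelic effects, and
annotation peaks with planted enrichment. Every stage downstream of
alignment can therefore be exercised against a truth table without any
external data.

Counts are generated at the resolution the statistics consume
(region x allele x replicate): the input-library count for each
region/allele cell is negative-binomial around the expected allele share
of the region's fragment budget, and the output mean multiplies in the
region activity and, for alt-allele fragments, the planted allelic
effect. Individual fragment records (and optionally a minimal SAM of
proper pairs) are materialized consistently with those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _io

__all__ = ["SimulationConfig", "SimulatedScreen", "simulate_dataset", "simulate_annotations"]

_BASES = np.array(list("ACGT"))
_SNP_SPACING = 1000  # bp between panel SNPs; > max fragment length, so one SNP per fragment
_REGION_FLANK = 250  # capture design: 250 bp either side of the SNP


@dataclass
class SimulationConfig:
    """Parameters of a synthetic screen.

    Defaults mirror the screen being emulated: ~465-bp fragments
    (truncated to the 400-600 bp retention window), a 10-individual
    diploid pool, two replicates per library, and planted activities in
    the 0.5-16 fold range.
    """

    n_tag_snps: int = 10
    linked_per_tag: int = 9
    n_individuals: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    fragments_per_region: float = 200.0
    fragment_length_mean: float = 465.0
    fragment_length_sd: float = 40.0
    pre_fraction: float = 0.1
    nre_fraction: float = 0.1
    activity_fold_range: tuple[float, float] = (0.5, 16.0)
    fixed_activity_folds: tuple[float, float] | None = None  # (PRE fold, NRE fold)
    regsnp_fraction: float = 0.05
    allelic_effect_range: tuple[float, float] = (1.5, 3.0)
    nb_dispersion: float = 0.02
    replicates: int = 2
    seed: int = 0
    materialize_fragments: bool = True

    @property
    def n_snps(self) -> int:
        return self.n_tag_snps * (1 + self.linked_per_tag)

    def validate(self) -> None:
        if self.n_tag_snps <= 0 or self.linked_per_tag < 0:
            raise ValueError("panel sizes must be positive")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.fragments_per_region <= 0:
            raise ValueError("fragments_per_region must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")
        if not (0 <= self.pre_fraction and 0 <= self.nre_fraction):
            raise ValueError("class fractions must be non-negative")
        if self.pre_fraction + self.nre_fraction > 1:
            raise ValueError("pre_fraction + nre_fraction must not exceed 1")
        if not (0 <= self.regsnp_fraction <= 1):
            raise ValueError("regsnp_fraction must lie in [0, 1]")
        lo, hi = self.activity_fold_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("activity_fold_range must be a positive interval")
        lo, hi = self.allelic_effect_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("allelic_effect_range must be a positive interval")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie inside (0, 1)")


class SimulatedScreen(NamedTuple):
    """All artifacts of one simulated screen, cross-consistent by construction."""

    panel: pd.DataFrame          # chrom, pos (1-based), snp_id, ref, alt, maf
    pool: pd.DataFrame           # individuals x snp_id, alt dosage 0/1/2
    fragments: pd.DataFrame      # chrom, start, end, library, snp_alleles (may be empty)
    region_counts: pd.DataFrame  # snp_id x library
    allele_counts: pd.DataFrame  # long: snp_id, library, condition, replicate, ref/alt counts
    truth: pd.DataFrame          # snp_id: class, log2fc, allelic_effect, alt_freq_pool
    metadata: dict


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = m + dispersion * m^2 (zeros where mean is zero)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _library_names(replicates: int) -> list[str]:
    return [f"{cond}_rep{k}" for cond in ("input", "output") for k in range(1, replicates + 1)]


def simulate_dataset(config: SimulationConfig) -> SimulatedScreen:
    """Generate one complete synthetic screen.

    Returns a :class:`SimulatedScreen`; all outputs are deterministic
    functions of the config (identical config => byte-identical tables).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    # --- panel ----------------------------------------------------------
    pos = _SNP_SPACING * (np.arange(n) + 1)  # 1-based positions
    maf = rng.uniform(*config.maf_range, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    snp_ids = np.array([f"rs{100000 + i}" for i in range(n)])
    tag = np.repeat([f"tag{j}" for j in range(config.n_tag_snps)], 1 + config.linked_per_tag)
    panel = pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": pos,
            "snp_id": snp_ids,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "maf": maf,
            "tag_group": tag,
        }
    )

    # --- genotype pool (HWE, independent SNPs) --------------------------
    geno = rng.binomial(2, maf[None, :].repeat(config.n_individuals, axis=0))
    pool = pd.DataFrame(
        geno,
        index=[f"ind{k}" for k in range(config.n_individuals)],
        columns=snp_ids,
    )
    alt_freq = geno.sum(axis=0) / (2.0 * config.n_individuals)

    # --- truth: region classes and allelic effects ----------------------
    n_pre = int(round(config.pre_fraction * n))
    n_nre = int(round(config.nre_fraction * n))
    order = rng.permutation(n)
    cls = np.full(n, "inactive", dtype=object)
    cls[order[:n_pre]] = "PRE"
    cls[order[n_pre:n_pre + n_nre]] = "NRE"

    lo, hi = config.activity_fold_range
    fold = np.ones(n)
    is_pre, is_nre = cls == "PRE", cls == "NRE"
    if config.fixed_activity_folds is not None:
        pre_fold, nre_fold = config.fixed_activity_folds
        fold[is_pre] = pre_fold
        fold[is_nre] = nre_fold
    else:
        pre_hi = max(hi, 1.0)
        nre_lo = min(lo, 1.0)
        if is_pre.any():
            fold[is_pre] = np.exp(rng.uniform(np.log(max(1.0, lo)), np.log(pre_hi),
                                              is_pre.sum())) if pre_hi > 1.0 else 1.0
        if is_nre.any():
            fold[is_nre] = np.exp(rng.uniform(np.log(nre_lo), np.log(min(1.0, hi)),
                                              is_nre.sum())) if nre_lo < 1.0 else 1.0
    log2fc = np.where(cls == "inactive", 0.0, np.log2(fold))

    polymorphic = (alt_freq > 0) & (alt_freq < 1)
    n_reg = int(round(config.regsnp_fraction * n))
    effect = np.ones(n)
    reg_candidates = np.flatnonzero(polymorphic)
    if n_reg > 0 and len(reg_candidates):
        chosen = rng.choice(reg_candidates, size=min(n_reg, len(reg_candidates)), replace=False)
        e_lo, e_hi = config.allelic_effect_range
        e = np.exp(rng.uniform(np.log(e_lo), np.log(e_hi), len(chosen)))
        flip = rng.random(len(chosen)) < 0.5
        e[flip] = 1.0 / e[flip]
        effect[chosen] = e

    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "class": cls,
            "log2fc": log2fc,
            "allelic_effect": effect,
            "alt_freq_pool": alt_freq,
        }
    ).set_index("snp_id")

    # --- counts at region x allele x replicate resolution --------------
    libs = _library_names(config.replicates)
    lam = config.fragments_per_region
    activity = 2.0 ** log2fc
    ref_share = lam * (1.0 - alt_freq)
    alt_share = lam * alt_freq

    allele_rows = []
    ref_mat = np.zeros((n, len(libs)), dtype=int)
    alt_mat = np.zeros((n, len(libs)), dtype=int)
    for j, lib in enumerate(libs):
        is_output = lib.startswith("output")
        rep = int(lib.rsplit("rep", 1)[1])
        if is_output:
            ref_mean = ref_share * activity
            alt_mean = alt_share * activity * effect
        else:
            ref_mean, alt_mean = ref_share, alt_share
        # region-level overdispersion (transfection/PCR noise shared by a
        # region's fragments), then a binomial allele split of the total:
        # allele-ratio noise is sampling noise within the fragment pool.
        tot_mean = ref_mean + alt_mean
        total = _nb_draws(rng, tot_mean, config.nb_dispersion)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(tot_mean > 0, alt_mean / np.maximum(tot_mean, 1e-300), 0.0)
        alt_c = rng.binomial(total, p_alt)
        ref_c = total - alt_c
        ref_mat[:, j], alt_mat[:, j] = ref_c, alt_c
        allele_rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "library": lib,
                    "condition": "output" if is_output else "input",
                    "replicate": rep,
                    "ref_count": ref_c,
                    "alt_count": alt_c,
                }
            )
        )
    allele_counts = pd.concat(allele_rows, ignore_index=True)
    region_counts = pd.DataFrame(ref_mat + alt_mat, index=pd.Index(snp_ids, name="snp_id"),
                                 columns=libs)

    # --- fragment materialization --------------------------------------
    if config.materialize_fragments:
        fragments = _materialize_fragments(config, panel, ref_mat, alt_mat, libs, rng)
    else:
        fragments = pd.DataFrame(columns=_io.FRAGMENT_COLUMNS)

    metadata = {
        "nb_dispersion": config.nb_dispersion,
        "fragments_per_region": config.fragments_per_region,
        "replicates": config.replicates,
        "seed": config.seed,
        "n_snps": n,
        "libraries": libs,
    }
    return SimulatedScreen(panel, pool, fragments, region_counts, allele_counts, truth, metadata)


def _materialize_fragments(config, panel, ref_mat, alt_mat, libs, rng) -> pd.DataFrame:
    """Emit one fragment record per counted unit, consistent with the counts."""
    pos0 = panel["pos"].to_numpy() - 1  # 0-based SNP coordinate
    refb = panel["ref"].to_numpy()
    altb = panel["alt"].to_numpy()
    sid = panel["snp_id"].to_numpy()
    chunks = []
    for j, lib in enumerate(libs):
        n_frag = ref_mat[:, j] + alt_mat[:, j]
        total = int(n_frag.sum())
        if total == 0:
            continue
        region = np.repeat(np.arange(len(sid)), n_frag)
        # first ref_mat fragments of each region carry ref, rest alt
        offset = np.concatenate([np.arange(k) for k in n_frag]) if total else np.array([], int)
        is_alt = offset >= np.repeat(ref_mat[:, j], n_frag)
        length = np.clip(
            np.round(rng.normal(config.fragment_length_mean, config.fragment_length_sd, total)),
            400, 600,
        ).astype(int)
        # fragment must cover the SNP: start in (pos0 - length, pos0]
        start = pos0[region] - rng.integers(0, length)
        start = np.maximum(start, 0)
        end = start + length
        base = np.where(is_alt, altb[region], refb[region])
        alleles = [f"{s}:{b}:40" for s, b in zip(sid[region], base)]
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": "chrS",
                    "start": start,
                    "end": end,
                    "library": lib,
                    "snp_alleles": alleles,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=_io.FRAGMENT_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


def simulate_annotations(
    panel: pd.DataFrame,
    truth: pd.DataFrame,
    target_or: float,
    baseline_rate: float,
    seed: int,
    track: str = "synthetic_mark",
) -> pd.DataFrame:
    """Plant annotation peaks with a target odds ratio for active SNPs.

    Inactive-region SNPs fall in a peak with probability ``baseline_rate``;
    PRE/NRE SNPs with probability corresponding to ``target_or`` times the
    baseline odds. Returns a BED-style peak table (0-based half-open).
    """
    if not (0 < baseline_rate < 1):
        raise ValueError("baseline_rate must lie strictly inside (0, 1)")
    if target_or <= 0:
        raise ValueError("target_or must be positive")
    rng = np.random.default_rng(seed)
    active = truth.loc[panel["snp_id"], "class"].isin(["PRE", "NRE"]).to_numpy()
    base_odds = baseline_rate / (1 - baseline_rate)
    p_active = target_or * base_odds / (1 + target_or * base_odds)
    p_in = np.where(active, p_active, baseline_rate)
    in_peak = rng.random(len(panel)) < p_in
    pos0 = panel["pos"].to_numpy() - 1
    left = rng.integers(20, 400, size=len(panel))
    right = rng.integers(20, 400, size=len(panel))
    peaks = pd.DataFrame(
        {
            "chrom": panel["chrom"].to_numpy()[in_peak],
            "start": np.maximum(pos0[in_peak] - left[in_peak], 0),
            "end": pos0[in_peak] + right[in_peak] + 1,
            "name": track,
        }
    )
    return peaks.reset_index(drop=True)


def write_sam(fragments: pd.DataFrame, panel: pd.DataFrame, path, read_len: int = 250,
              chrom_len: int | None = None) -> None:
    """Write fragments as a minimal SAM of synthetic proper pairs.

    Each fragment becomes a forward/reverse mate pair of ``read_len``-bp
    perfect matches at its two ends; read sequences are filler bases with
    the fragment's observed allele substituted at each covered SNP.
    """
    snp_pos0 = dict(zip(panel["snp_id"], panel["pos"] - 1))
    if chrom_len is None:
        chrom_len = int(max(fragments["end"].max() if len(fragments) else 1000,
                            panel["pos"].max() + 600))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:chrS\tLN:{chrom_len}\n")
        for i, row in fragments.reset_index(drop=True).iterrows():
            start, end = int(row["start"]), int(row["end"])
            flen = end - start
            rl = min(read_len, flen)
            obs = _io.decode_snp_alleles(str(row["snp_alleles"]))
            r1_start, r2_start = start, end - rl

            def read_seq(rstart: int) -> str:
                seq = ["A"] * rl
                for snp_id, base, _q in obs:
                    p0 = snp_pos0.get(snp_id)
                    if p0 is not None and rstart <= p0 < rstart + rl:
                        seq[p0 - rstart] = base
                return "".join(seq)

            qual = "I" * rl  # phred 40
            qname = f"frag{i}"
            fh.write("\t".join([qname, "99", "chrS", str(r1_start + 1), "60",
                                f"{rl}M", "=", str(r2_start + 1), str(flen),
                                read_seq(r1_start), qual]) + "\n")
            fh.write("\t".join([qname, "147", "chrS", str(r2_start + 1), "60",
                                f"{rl}M", "=", str(r1_start + 1), str(-flen),
                                read_seq(r2_start), qual]) + "\n")


def write_screen(screen: SimulatedScreen, out_dir) -> dict[str, str]:
    """Write all screen artifacts as plain-text tables; returns the paths."""
    from pathlib import Path
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.tsv",
        "pool": out / "genotype_pool.tsv",
        "fragments": out / "fragments.tsv",
        "region_counts": out / "region_counts.tsv",
        "allele_counts": out / "allele_counts.tsv",
        "truth": out / "truth.tsv",
        "metadata": out / "metadata.json",
    }
    _io.write_panel(screen.panel, paths["panel"])
    _io.write_table(screen.pool, paths["pool"], index=True)
    _io.write_fragments(screen.fragments, paths["fragments"])
    _io.write_counts(screen.region_counts, paths["region_counts"])
    _io.write_table(screen.allele_counts, paths["allele_counts"])
    _io.write_table(screen.truth, paths["truth"], index=True)
    with open(paths["metadata"], "w") as fh:
        json.dump(screen.metadata, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
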