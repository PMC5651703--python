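"""Fragment reconstruction, filtering, and counting.

Aligned proper read pairs (SAM) or a pre-made fragment table are turned
into filtered fragment records, then into the two matrices downstream
stages consume: a per-SNP-region count matrix (one count per retained
fragment per covered region) and a per-SNP ref/alt allele count table.

Retention rule: a fragment is kept iff its outer span is 400-600 bp and
it covers at least one panel SNP. The observed base at a covered SNP is
masked to "unknown" when below the base-quality floor or when
overlapping mates disagree; unknown/other bases stay in region counts
but are excluded from the allele table (tracked separately).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _io

logger = logging.getLogger(__name__)

__all__ = ["FragmentFilterStats", "load_fragments", "count_matrices"]


@dataclass
class FragmentFilterStats:
    """Bookkeeping of what the loader kept and why it dropped the rest."""

    total_pairs: int = 0
    kept: int = 0
    bad_length: int = 0
    no_panel_snp: int = 0
    improper_or_unmapped: int = 0
    malformed: int = 0
    duplicates_removed: int = 0


def _panel_index(panel: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome sorted (pos0, snp_id, ref, alt) arrays."""
    out = {}
    for chrom, sub in panel.groupby("chrom"):
        sub = sub.sort_values("pos")
        out[chrom] = (
            sub["pos"].to_numpy() - 1,
            sub["snp_id"].to_numpy(),
            sub["ref"].to_numpy(),
            sub["alt"].to_numpy(),
        )
    return out


def _covered_snps(idx, chrom: str, start: int, end: int):
    """(positions0, snp_ids) of panel SNPs inside [start, end)."""
    if chrom not in idx:
        return np.array([], int), np.array([], object)
    pos0, sid, _, _ = idx[chrom]
    lo = np.searchsorted(pos0, start, side="left")
    hi = np.searchsorted(pos0, end, side="left")
    return pos0[lo:hi], sid[lo:hi]


def _base_at(read, pos0: int) -> tuple[str | None, int]:
    """Observed (base, qual) of `read` at reference position pos0, or (None, -1)."""
    seq = read.query_sequence
    if seq is None:
        return None, -1
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            q = read.query_qualities[qpos] if read.query_qualities is not None else 40
            return seq[qpos], int(q)
    return None, -1


def load_fragments(
    source,
    panel: pd.DataFrame,
    min_len: int = 400,
    max_len: int = 600,
    min_base_quality: int = 20,
    dedup: bool = False,
    stats: FragmentFilterStats | None = None,
) -> pd.DataFrame:
    """Load and filter fragments from a SAM file or fragment table.

    Parameters
    ----------
    source
        Path to a SAM file (``.sam``), a fragment-table TSV, or a
        DataFrame in the fragment-table dialect
        (chrom, start, end, library, snp_alleles).
    panel
        Variant panel (chrom, pos 1-based, snp_id, ref, alt).
    min_len, max_len
        Retained fragment outer-span range in bp (inclusive).
    min_base_quality
        Bases below this phred score are masked to "unknown".
    dedup
        Drop fragments with identical (library, chrom, start, end);
        off by default.
    stats
        Optional mutable counter object to receive filter bookkeeping.

    Returns
    -------
    DataFrame with columns chrom, start, end, library, snp_alleles, where
    ``snp_alleles`` serializes (snp_id, observed base, qual) per covered
    panel SNP ("unknown" bases encoded with base ``N``).
    """
    if stats is None:
        stats = FragmentFilterStats()
    if isinstance(source, pd.DataFrame):
        frags = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() == ".sam":
            frags = _fragments_from_sam(path, panel, min_base_quality, stats)
        else:
            frags = _io.read_fragments(path)

    if "library" not in frags.columns:
        frags["library"] = "lib1"
    frags["snp_alleles"] = frags["snp_alleles"].fillna("").astype(str)
    frags["start"] = frags["start"].astype(int)
    frags["end"] = frags["end"].astype(int)
    stats.total_pairs = max(stats.total_pairs, len(frags))

    idx = _panel_index(panel)
    length = frags["end"] - frags["start"]
    ok_len = (length >= min_len) & (length <= max_len)
    stats.bad_length += int((~ok_len).sum())

    kept_rows = []
    for row in frags[ok_len].itertuples(index=False):
        pos0s, sids = _covered_snps(idx, row.chrom, row.start, row.end)
        if len(sids) == 0:
            stats.no_panel_snp += 1
            continue
        observed = {s: (b, q) for s, b, q in _io.decode_snp_alleles(row.snp_alleles)}
        entries = []
        for s in sids:
            base, q = observed.get(s, ("N", 0))
            if q < min_base_quality:
                base = "N"
            entries.append((s, base, q))
        kept_rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "library": row.library,
                "snp_alleles": _io.encode_snp_alleles(entries),
            }
        )
    out = pd.DataFrame(kept_rows, columns=_io.FRAGMENT_COLUMNS)
    if dedup and len(out):
        before = len(out)
        out = out.drop_duplicates(subset=["library", "chrom", "start", "end"])
        stats.duplicates_removed = before - len(out)
    stats.kept = len(out)
    return out.reset_index(drop=True)


def _fragments_from_sam(path: Path, panel: pd.DataFrame, min_base_quality: int,
                        stats: FragmentFilterStats) -> pd.DataFrame:
    """Reconstruct fragment spans + observed SNP bases from proper pairs."""
    import tempfile

    import pysam

    text, malformed = _io.sam_text_triage(path)
    if malformed:
        logger.warning("skipped %d malformed SAM line(s) in %s", malformed, path)
    stats.malformed = malformed
    idx = _panel_index(panel)

    pairs: dict[str, list] = {}
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tmp:
        tmp.write(text)
        clean_path = tmp.name
    try:
        with pysam.AlignmentFile(clean_path, "r", check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    stats.improper_or_unmapped += 1
                    continue
                if not read.is_proper_pair:
                    stats.improper_or_unmapped += 1
                    continue
                pairs.setdefault(read.query_name, []).append(read)
    finally:
        os.unlink(clean_path)

    rows = []
    for qname, reads in pairs.items():
        if len(reads) != 2 or reads[0].reference_name != reads[1].reference_name:
            stats.improper_or_unmapped += len(reads)
            continue
        stats.total_pairs += 1
        chrom = reads[0].reference_name
        start = min(r.reference_start for r in reads)
        end = max(r.reference_end for r in reads)
        pos0s, sids = _covered_snps(idx, chrom, start, end)
        entries = []
        for p0, s in zip(pos0s, sids):
            calls = [(b, q) for b, q in (_base_at(r, p0) for r in reads) if b is not None]
            calls = [(b, q) for b, q in calls if q >= min_base_quality]
            if not calls:
                base, q = "N", 0
            elif len({b for b, _ in calls}) > 1:
                base, q = "N", 0  # overlapping mates disagree
            else:
                base, q = max(calls, key=lambda bq: bq[1])
            entries.append((s, base, q))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "library": "lib1",
                "snp_alleles": _io.encode_snp_alleles(entries),
            }
        )
    return pd.DataFrame(rows, columns=_io.FRAGMENT_COLUMNS)


def count_matrices(
    fragments: pd.DataFrame,
    panel: pd.DataFrame,
    libraries: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally fragments into region counts and per-SNP allele counts.

    A fragment covering k panel SNPs contributes one count to each of the
    k SNP regions and one allele observation per covered SNP. Bases
    matching neither ref nor alt (or masked "N") are tallied in an
    ``other_count`` column and excluded from ref/alt.

    Returns
    -------
    (region_counts, allele_counts)
        ``region_counts``: snp_id x library fragment counts with the full
        panel index (zeros where uncovered). ``allele_counts``: long table
        snp_id, library, condition, replicate, ref_count, alt_count,
        other_count. Condition/replicate are parsed from library names of
        the form ``input_rep1`` / ``output_rep2`` when possible.
    """
    panel_ids = pd.Index(panel["snp_id"], name="snp_id")
    ref_of = dict(zip(panel["snp_id"], panel["ref"]))
    alt_of = dict(zip(panel["snp_id"], panel["alt"]))

    if libraries is None:
        libraries = sorted(fragments["library"].unique()) if len(fragments) else ["lib1"]
    region = pd.DataFrame(0, index=panel_ids, columns=libraries, dtype=int)
    tall: dict[tuple[str, str], list[int]] = {}

    for row in fragments.itertuples(index=False):
        for snp_id, base, _q in _io.decode_snp_alleles(str(row.snp_alleles)):
            if snp_id not in ref_of:
                raise ValueError(f"fragment covers SNP {snp_id!r} absent from panel")
            key = (snp_id, row.library)
            cell = tall.setdefault(key, [0, 0, 0])
            if base == ref_of[snp_id]:
                cell[0] += 1
            elif base == alt_of[snp_id]:
                cell[1] += 1
            else:
                cell[2] += 1
            region.at[snp_id, row.library] += 1

    rows = []
    for (snp_id, lib), (r, a, o) in tall.items():
        cond = "output" if str(lib).lower().startswith("out") else "input"
        rep = 1
        if "rep" in str(lib):
            try:
                rep = int(str(lib).rsplit("rep", 1)[1])
            except ValueError:
                rep = 1
        rows.append(
            {
                "snp_id": snp_id,
                "library": lib,
                "condition": cond,
                "replicate": rep,
                "ref_count": r,
                "alt_count": a,
                "other_count": o,
            }
        )
    allele = pd.DataFrame(
        rows,
        columns=["snp_id", "library", "condition", "replicate",
                 "ref_count", "alt_count", "other_count"],
    )
    return region, allele
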