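"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular outputs are TSV with a single header line beginning ``#``.
Coordinate conventions are centralized here: panel tables carry 1-based
SNP positions (VCF-like), BED intervals are 0-based half-open, and all
in-memory fragment intervals are 0-based half-open.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

PANEL_COLUMNS = ["chrom", "pos", "snp_id", "ref", "alt", "maf"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "library", "snp_alleles"]


def pos_1based_to_0based(pos: int) -> int:
    """Convert a 1-based SNP position to a 0-based coordinate."""
    return int(pos) - 1


def pos_0based_to_1based(pos0: int) -> int:
    return int(pos0) + 1


def write_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """Write a TSV whose header line starts with ``#``."""
    out = df.reset_index() if index else df
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (or a plain headered TSV)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    names = header.lstrip("#").split("\t")
    return pd.read_csv(path, sep="\t", skiprows=1, names=names, **kwargs)


def write_panel(panel: pd.DataFrame, path: PathLike) -> None:
    write_table(panel[PANEL_COLUMNS], path)


def read_panel(path: PathLike) -> pd.DataFrame:
    panel = read_table(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns: {sorted(missing)}")
    panel["pos"] = panel["pos"].astype(int)
    return panel


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    write_table(counts, path, index=True)


def read_counts(path: PathLike) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0])


def write_bed(peaks: pd.DataFrame, path: PathLike) -> None:
    """Write peaks (chrom, start, end[, name]) as BED (0-based half-open)."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in peaks.columns else [])
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"invalid BED intervals (start >= end) in {path}")
    return df


def encode_snp_alleles(observations: list[tuple[str, str, int]]) -> str:
    """Serialize [(snp_id, base, qual), ...] as 'rs1:A:40,rs2:C:38'."""
    return ",".join(f"{s}:{b}:{int(q)}" for s, b, q in observations)


def decode_snp_alleles(field: str) -> list[tuple[str, str, int]]:
    if not field or field in (".", "nan"):
        return []
    out = []
    for token in field.split(","):
        snp_id, base, qual = token.rsplit(":", 2)
        out.append((snp_id, base, int(qual)))
    return out


def write_fragments(fragments: pd.DataFrame, path: PathLike) -> None:
    write_table(fragments[FRAGMENT_COLUMNS], path)


def read_fragments(path: PathLike) -> pd.DataFrame:
    df = read_table(path, dtype={"snp_alleles": str})
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fragment table {path} missing columns: {sorted(missing)}")
    return df


def read_meme_motifs(path: PathLike) -> dict[str, np.ndarray]:
    """Read a MEME-style minimal motif text file.

    Returns {motif_id: (width, 4) probability matrix over A, C, G, T}.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out: dict[str, np.ndarray] = {}
    for m in records:
        mat = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in "ACGT"])
        out[m.name or m.consensus] = mat
    return out


def write_meme_motifs(pwms: dict[str, np.ndarray], path: PathLike,
                      background: np.ndarray | None = None) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for name, mat in pwms.items():
            mat = np.asarray(mat, float)
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                     f"nsites= 20 E= 0\n")
            for row in mat:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA into {name: sequence} via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def sam_text_triage(path: PathLike) -> tuple[str, int]:
    """Pre-filter SAM text, dropping malformed alignment lines.

    Returns (cleaned SAM text, number of malformed lines skipped). A line is
    malformed if it has fewer than 11 fields or non-integer FLAG/POS/MAPQ.
    Alignment semantics are left to pysam; this only keeps a bad line from
    aborting iteration.
    """
    kept: list[str] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                kept.append(line)
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                skipped += 1
                continue
            try:
                int(fields[1]); int(fields[3]); int(fields[4])
            except ValueError:
                skipped += 1
                continue
            kept.append(line)
    return "".join(kept), skipped
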