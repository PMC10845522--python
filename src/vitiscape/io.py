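"""File-format helpers: FASTA/FASTQ via Biopython, BED/TSV via pandas.

All interval files are BED-style 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import ReferenceGenome


def read_fasta(path: str | Path, mask_bed: str | Path | None = None) -> ReferenceGenome:
    from Bio import SeqIO

    chromosomes = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    mask: dict[str, list[tuple[int, int]]] = {}
    if mask_bed is not None:
        bed = read_bed(mask_bed)
        for r in bed.itertuples():
            mask.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        mask = {c: sorted(v) for c, v in mask.items()}
    return ReferenceGenome(chromosomes=chromosomes, mask=mask)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def write_read_starts(starts: dict[str, np.ndarray], path: str | Path) -> None:
    """Sparse per-position read-start counts as TSV (chrom, pos, count)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcount\n")
        for chrom, counts in starts.items():
            for pos in np.flatnonzero(counts):
                fh.write(f"{chrom}\t{pos}\t{counts[pos]}\n")


def read_read_starts(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {c: np.zeros(n, dtype=np.int32) for c, n in lengths.items()}
    for r in df.itertuples():
        if r.chrom not in out:
            raise ValueError(f"read starts reference unknown chromosome {r.chrom!r}")
        if not 0 <= r.pos < lengths[r.chrom]:
            raise ValueError(f"position {r.pos} beyond chromosome {r.chrom}")
        out[r.chrom][r.pos] = r.count
    return out


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    regions.to_csv(path, sep="\t", index=False)
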