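"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED is consumed and emitted natively (0-based half-open).  GTF is 1-based
closed and converted to the internal convention on read.  FASTA access goes
through pyfaidx so whole genomes are never loaded eagerly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, ValidationError

__all__ = [
    "NarrowPeak",
    "open_fasta",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gtf_genes",
    "read_count_matrix",
    "write_count_matrix",
]


@dataclass(frozen=True)
class NarrowPeak:
    """One row of an ENCODE narrowPeak file (10 columns)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    pvalue: float = -1.0
    qvalue: float = -1.0
    summit_offset: int = -1  # column 10; -1 = not provided

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when column 10 is absent."""
        if self.summit_offset < 0:
            return None
        return self.interval.start + self.summit_offset


def open_fasta(path: str | Path) -> Fasta:
    return Fasta(str(path), sequence_always_upper=True)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; extra columns are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    path: str | Path,
    intervals: list[GenomicInterval],
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write BED6 when names/scores/strands are informative, else BED3."""
    six = names is not None or scores is not None or any(
        iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names else "."
                score = scores[i] if scores else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: str | Path) -> list[NarrowPeak]:
    out: list[NarrowPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 columns")
            iv = GenomicInterval(
                f[0], int(f[1]), int(f[2]),
                f[5] if len(f) >= 6 and f[5] in ("+", "-") else ".",
            )
            out.append(
                NarrowPeak(
                    interval=iv,
                    name=f[3] if len(f) >= 4 else ".",
                    score=float(f[4]) if len(f) >= 5 else 0.0,
                    signal=float(f[6]) if len(f) >= 7 else 0.0,
                    pvalue=float(f[7]) if len(f) >= 8 else -1.0,
                    qvalue=float(f[8]) if len(f) >= 9 else -1.0,
                    summit_offset=int(f[9]) if len(f) >= 10 else -1,
                )
            )
    return out


def write_narrowpeak(path: str | Path, peaks: list[NarrowPeak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t"
                f"{iv.strand}\t{p.signal:g}\t{p.pvalue:g}\t{p.qvalue:g}\t"
                f"{p.summit_offset}\n"
            )


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene records from a GTF.

    Uses ``gene`` feature rows; falls back to the union of ``transcript``
    rows per gene_id when no gene rows exist.  Returns a DataFrame with
    columns gene_id, chrom, start, end, strand in 0-based half-open
    coordinates (GTF's 1-based closed start is shifted by one on read).
    """
    genes: dict[str, list] = {}
    have_gene_rows = False
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "transcript"):
                continue
            gid = _gtf_attr(f[8], "gene_id")
            if gid is None:
                raise ValidationError(f"GTF row without gene_id: {line.strip()[:80]}")
            start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            rec = [f[0], start, end, f[6]]
            if f[2] == "gene":
                have_gene_rows = True
                genes[gid] = rec
            elif not have_gene_rows:
                if gid in genes:
                    prev = genes[gid]
                    prev[1] = min(prev[1], start)
                    prev[2] = max(prev[2], end)
                else:
                    genes[gid] = rec
    rows = [
        {"gene_id": gid, "chrom": r[0], "start": r[1], "end": r[2], "strand": r[3]}
        for gid, r in genes.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_count_matrix(path: str | Path | _io.TextIOBase) -> pd.DataFrame:
    """Tab-delimited count matrix: first column origin ids, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValidationError("count matrix contains negative values")
    return df.astype(np.int64) if (df.dtypes == object).any() else df


def write_count_matrix(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="origin_id")
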