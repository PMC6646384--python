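"""Coordinate system and interval algebra shared by the whole pipeline.

All coordinates are 0-based half-open ``[start, end)`` on a named chromosome,
the BED convention.  GTF input (1-based closed) is converted on read by the
``io`` module so that nothing downstream ever sees another convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeModel",
    "ValidationError",
    "PlacementError",
    "merge_intervals",
    "overlap_query",
    "shuffle_intervals",
    "shuffle_positions",
    "count_reads_in_intervals",
]


class ValidationError(ValueError):
    """A record violates an interval invariant; the message names the record."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place an interval outside the gap track."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be nonempty.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"empty chromosome name in {self!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r} in {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeModel:
    """Chromosome lengths plus an assembly-gap track.

    Gaps mark unplaceable regions (assembly N-stretches); shuffles avoid
    them.  Gaps are normalized (merged, sorted, clipped to bounds) on
    construction.
    """

    chrom_lengths: dict[str, int]
    gaps: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.gaps:
            if g.chrom not in self.chrom_lengths:
                raise ValidationError(f"gap {g!r} on unknown chromosome")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValidationError(f"gap {g!r} exceeds chromosome length")
        self.gaps = merge_intervals(self.gaps)
        self._gap_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chrom_lengths:
            gs = [g for g in self.gaps if g.chrom == chrom]
            self._gap_arrays[chrom] = (
                np.array([g.start for g in gs], dtype=np.int64),
                np.array([g.end for g in gs], dtype=np.int64),
            )

    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def in_gap(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any gap on chrom."""
        starts, ends = self._gap_arrays.get(chrom, (None, None))
        if starts is None or len(starts) == 0:
            return False
        # gaps are disjoint and sorted; any gap with gap.start < end and gap.end > start
        i = int(np.searchsorted(starts, end, side="left"))
        return bool(i > 0 and ends[i - 1] > start)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into a sorted disjoint set.

    Strand is dropped (merged intervals are unstranded); the union of
    covered bases is preserved exactly.
    """
    if not intervals:
        return []
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = by_pos[0].chrom, by_pos[0].start, by_pos[0].end
    for iv in by_pos[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def overlap_query(
    query: GenomicInterval,
    subject: list[GenomicInterval],
    min_bp: int = 1,
) -> list[GenomicInterval]:
    """Subject intervals sharing at least ``min_bp`` bases with ``query``.

    Original subject order is preserved.
    """
    if min_bp < 1:
        raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
    return [iv for iv in subject if query.overlap_bp(iv) >= min_bp]


_MAX_ATTEMPTS = 1000


def shuffle_intervals(
    intervals: list[GenomicInterval],
    genome: GenomeModel,
    n_shuffles: int,
    seed: int,
) -> list[list[GenomicInterval]]:
    """Randomly relocate intervals, preserving chromosome and length.

    Each shuffled set keeps the per-chromosome interval count and the exact
    length multiset of the input; placements avoid the genome's gap track by
    rejection sampling (at most 1000 attempts per interval, then a hard
    error naming the chromosome).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    for iv in intervals:
        if iv.chrom not in genome.chrom_lengths:
            raise ValidationError(f"interval {iv!r} on unknown chromosome")
        if len(iv) > genome.chrom_lengths[iv.chrom]:
            raise ValidationError(f"interval {iv!r} longer than its chromosome")
    out: list[list[GenomicInterval]] = []
    for _ in range(n_shuffles):
        shuffled: list[GenomicInterval] = []
        for iv in intervals:
            clen = genome.chrom_lengths[iv.chrom]
            span = len(iv)
            hi = clen - span  # inclusive max start
            placed = False
            for _attempt in range(_MAX_ATTEMPTS):
                s = int(rng.integers(0, hi + 1))
                if not genome.in_gap(iv.chrom, s, s + span):
                    shuffled.append(GenomicInterval(iv.chrom, s, s + span, iv.strand))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place a {span} bp interval on {iv.chrom} "
                    f"outside gaps after {_MAX_ATTEMPTS} attempts"
                )
        out.append(shuffled)
    return out


def shuffle_positions(
    positions: dict[str, np.ndarray],
    genome: GenomeModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Redraw point coordinates uniformly per chromosome, avoiding gaps.

    Used for initiation-site shuffles: keeps the per-chromosome count of
    points while randomizing their positions.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        clen = genome.chrom_lengths[chrom]
        n = len(pos)
        new = np.empty(n, dtype=np.int64)
        for i in range(n):
            for _attempt in range(_MAX_ATTEMPTS):
                p = int(rng.integers(0, clen))
                if not genome.in_gap(chrom, p, p + 1):
                    new[i] = p
                    break
            else:
                raise PlacementError(f"could not place a point on {chrom} outside gaps")
        out[chrom] = new
    return out


def count_reads_in_intervals(
    reads: list[GenomicInterval],
    targets: list[GenomicInterval],
) -> np.ndarray:
    """Count reads per target by read midpoint (half-open: end excluded).

    A read whose midpoint falls in several overlapping targets is counted
    in each of them.
    """
    counts = np.zeros(len(targets), dtype=np.int64)
    if not reads or not targets:
        return counts
    mids: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in reads}:
        m = np.array(sorted(r.midpoint for r in reads if r.chrom == chrom), dtype=np.int64)
        mids[chrom] = m
    for i, t in enumerate(targets):
        m = mids.get(t.chrom)
        if m is None:
            continue
        lo = np.searchsorted(m, t.start, side="left")
        hi = np.searchsorted(m, t.end, side="left")  # end exclusive
        counts[i] = hi - lo
    return counts


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
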