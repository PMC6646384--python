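"""Consensus replication-origin calling from per-replicate peak sets.

SNS-seq origin mapping produces, per replicate, narrow peaks (candidate
initiation sites) and broad enriched regions.  A narrow peak is retained
only when it overlaps a broad region; retained peaks are clustered across
replicates by single-linkage overlap, and clusters supported by at least
``min_reps`` distinct replicates become consensus origins.  The initiation
site (IS) of an origin is the position of maximal nascent-strand coverage
over its span (leftmost on ties), falling back to a reported peak summit
or, lacking both, the span midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, ValidationError

__all__ = [
    "OriginRecord",
    "intersect_narrow_broad",
    "consensus_reproducible",
    "define_is",
    "condition_presence",
]


@dataclass
class OriginRecord:
    """A consensus origin: span, initiation site, and replicate support."""

    interval: GenomicInterval
    is_pos: int | None = None
    replicates: frozenset = field(default_factory=frozenset)
    origin_id: str = ""

    def __post_init__(self) -> None:
        if self.is_pos is not None and not (
            self.interval.start <= self.is_pos < self.interval.end
        ):
            raise ValidationError(
                f"IS {self.is_pos} outside span "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


def intersect_narrow_broad(
    narrow: list[GenomicInterval],
    broad: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Narrow peaks overlapping (>=1 bp) any broad region, coordinates unchanged."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in broad}:
        bs = sorted((b for b in broad if b.chrom == chrom), key=lambda b: b.start)
        starts = np.array([b.start for b in bs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([b.end for b in bs], dtype=np.int64))
        by_chrom[chrom] = (starts, ends)
    out = []
    for p in narrow:
        arrs = by_chrom.get(p.chrom)
        if arrs is None:
            continue
        starts, cummax_ends = arrs
        i = int(np.searchsorted(starts, p.end, side="left"))
        if i > 0 and cummax_ends[i - 1] > p.start:
            out.append(p)
    return out


def consensus_reproducible(
    replicate_peaks: dict[str, list[GenomicInterval]],
    min_reps: int = 2,
    summits: dict[str, list[int]] | None = None,
) -> list[OriginRecord]:
    """Cluster peaks across replicates and keep reproducible clusters.

    Single-linkage clustering with >=1 bp overlap; a cluster supported by
    peaks from at least ``min_reps`` distinct replicates becomes one
    consensus origin spanning the cluster union.  ``summits`` optionally
    maps replicate name to per-peak absolute summit positions; the origin
    IS is then seeded with the summit of the first contributing peak (in
    sorted order) and can be refined later with coverage via
    :func:`define_is`.

    The result is invariant to the order replicates are supplied in:
    clusters are built from position-sorted peaks only.
    """
    if min_reps > len(replicate_peaks):
        raise ValidationError(
            f"min_reps={min_reps} exceeds the {len(replicate_peaks)} replicates supplied"
        )
    records = []  # (chrom, start, end, rep, summit)
    for rep in sorted(replicate_peaks):
        peaks = replicate_peaks[rep]
        reps_summits = (summits or {}).get(rep, [None] * len(peaks))
        for p, sm in zip(peaks, reps_summits):
            records.append((p.chrom, p.start, p.end, rep, sm))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    origins: list[OriginRecord] = []
    cluster: list[tuple] = []

    def flush() -> None:
        if not cluster:
            return
        reps = frozenset(r[3] for r in cluster)
        if len(reps) >= min_reps:
            chrom = cluster[0][0]
            start = min(r[1] for r in cluster)
            end = max(r[2] for r in cluster)
            summit = next((r[4] for r in cluster if r[4] is not None), None)
            if summit is not None and not (start <= summit < end):
                summit = None
            origins.append(
                OriginRecord(GenomicInterval(chrom, start, end), summit, reps)
            )

    cur_chrom, cur_end = None, -1
    for rec in records:
        chrom, start, end = rec[0], rec[1], rec[2]
        if chrom == cur_chrom and start < cur_end:  # >=1 bp overlap chains the cluster
            cluster.append(rec)
            cur_end = max(cur_end, end)
        else:
            flush()
            cluster = [rec]
            cur_chrom, cur_end = chrom, end
    flush()
    for i, o in enumerate(origins):
        o.origin_id = f"origin_{i + 1}"
    return origins


def define_is(
    origin: OriginRecord,
    coverage: np.ndarray | None = None,
    summit: int | None = None,
) -> int:
    """Locate the initiation site within an origin span.

    With per-bp ``coverage`` over the span, the IS is the leftmost position
    of maximal coverage.  Without coverage, a provided narrow-peak
    ``summit`` is used; with neither (or all-zero coverage) the span
    midpoint is returned with a warning.
    """
    span = origin.interval
    if coverage is not None:
        coverage = np.asarray(coverage)
        if len(coverage) != len(span):
            raise ValidationError(
                f"coverage length {len(coverage)} != span length {len(span)}"
            )
        if not coverage.any():
            warnings.warn(
                f"all-zero coverage over {span.chrom}:{span.start}-{span.end}; "
                "IS set to span midpoint"
            )
            return span.midpoint
        return span.start + int(np.argmax(coverage))  # argmax is leftmost on ties
    if summit is not None:
        if not (span.start <= summit < span.end):
            raise ValidationError(f"summit {summit} outside span {span!r}")
        return summit
    warnings.warn(
        f"no coverage or summit for {span.chrom}:{span.start}-{span.end}; "
        "IS set to span midpoint"
    )
    return span.midpoint


def condition_presence(
    origin: OriginRecord,
    condition_map: dict[str, str],
    min_reps: int = 2,
) -> dict[str, bool]:
    """Per-condition presence: reproducible in >= min_reps replicates of it.

    For a two-replicate condition this means both replicates.
    """
    by_cond: dict[str, int] = {}
    for rep in origin.replicates:
        cond = condition_map.get(rep)
        if cond is None:
            raise ValidationError(f"replicate {rep!r} missing from condition map")
        by_cond[cond] = by_cond.get(cond, 0) + 1
    conditions = set(condition_map.values())
    n_reps_per_cond = {
        c: sum(1 for v in condition_map.values() if v == c) for c in conditions
    }
    return {
        c: by_cond.get(c, 0) >= min(min_reps, n_reps_per_cond[c])
        for c in conditions
    }
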