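"""G-quadruplex prediction from sequence.

Two predictors are implemented:

* a run-capped sliding-window scorer: every base inside a G-run of length
  *n* scores ``+min(n, 4)``, every base in a C-run ``-min(n, 4)``, all other
  bases 0; windows of 25 nt are averaged and a region is called wherever the
  absolute window mean reaches the threshold (default 2).  A mean of +2
  reports a quadruplex on the plus (G-rich) strand, -2 on the minus strand.
* a pattern scanner requiring four G-tracts of a minimum length (default 3)
  separated by loops of 1-7 nt; the mirror C-tract pattern reports the
  minus strand.  Matches are taken leftmost, greedy, non-overlapping per
  strand.

The window scorer's score is a structural propensity: sequences reaching a
window mean of 2 fold into quadruplexes essentially without exception in
physiological-salt conditions, which is why 2 is the default threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, ValidationError

__all__ = [
    "BaseScoreTrack",
    "G4Region",
    "base_scores",
    "window_scores",
    "call_g4_regions",
    "quadparser_scan",
    "reverse_complement",
    "scan_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BaseScoreTrack:
    """Per-base integer scores in [-4, +4] for one sequence."""

    seq_id: str
    scores: np.ndarray  # int8

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class G4Region:
    """A predicted quadruplex-forming interval.

    ``strand`` is the strand of the G-rich face.  ``score`` is the maximum
    absolute window mean for the window scorer, or the G-tract count for
    the pattern scanner.
    """

    interval: GenomicInterval
    method: str  # "window_scorer" | "pattern"
    score: float

    @property
    def strand(self) -> str:
        return self.interval.strand


def base_scores(seq: str, seq_id: str = "seq") -> BaseScoreTrack:
    """Score each base by its G-run/C-run membership, capped at +/-4.

    N breaks runs and scores 0.  Case-insensitive; characters outside
    {A,C,G,T,N} raise a validation error naming the offending position.
    """
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise ValidationError(
            f"invalid character {s[pos]!r} at position {pos} in {seq_id}"
        )
    arr = np.frombuffer(s.encode("ascii"), dtype="S1")
    scores = np.zeros(len(s), dtype=np.int8)
    for base, sign in ((b"G", 1), (b"C", -1)):
        mask = arr == base
        if not mask.any():
            continue
        m = mask.astype(np.int8)
        dm = np.diff(np.concatenate(([0], m, [0])))
        starts = np.flatnonzero(dm == 1)
        ends = np.flatnonzero(dm == -1)
        for st, en in zip(starts, ends):
            scores[st:en] = sign * min(en - st, 4)
    return BaseScoreTrack(seq_id, scores)


def window_scores(track: BaseScoreTrack, window: int = 25) -> np.ndarray:
    """Sliding-window arithmetic means of the base-score track, step 1.

    Returns ``len(track) - window + 1`` means; an empty array (with a
    warning) when the sequence is shorter than the window.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    n = len(track.scores)
    if n < window:
        warnings.warn(
            f"sequence {track.seq_id} shorter than window ({n} < {window}); "
            "no windows scored"
        )
        return np.empty(0, dtype=np.float64)
    cs = np.concatenate(([0.0], np.cumsum(track.scores, dtype=np.float64)))
    return (cs[window:] - cs[:-window]) / window


def call_g4_regions(
    seq: str,
    threshold: float = 2.0,
    window: int = 25,
    seq_id: str = "seq",
    offset: int = 0,
) -> list[G4Region]:
    """Call quadruplex regions as per-sign unions of qualifying windows.

    A window qualifies when ``|mean| >= threshold``; overlapping qualifying
    windows of the same sign are merged into one region spanning their
    union.  Region strand is ``+`` for positive means (G-rich plus strand)
    and ``-`` for negative; the region score is the maximum absolute window
    mean inside it.  ``offset`` shifts reported coordinates (for scanning a
    sub-sequence of a chromosome).
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    track = base_scores(seq, seq_id)
    means = window_scores(track, window)
    if means.size == 0:
        return []
    out: list[G4Region] = []
    for sign, strand in ((1, "+"), (-1, "-")):
        qual = np.flatnonzero(sign * means >= threshold)
        if qual.size == 0:
            continue
        # windows step 1: indices i, j overlap iff |i - j| < window
        breaks = np.flatnonzero(np.diff(qual) >= window)
        group_starts = np.concatenate(([0], breaks + 1))
        group_ends = np.concatenate((breaks, [qual.size - 1]))
        for gs, ge in zip(group_starts, group_ends):
            first, last = int(qual[gs]), int(qual[ge])
            score = float(np.max(sign * means[qual[gs] : qual[ge] + 1]))
            out.append(
                G4Region(
                    GenomicInterval(seq_id, offset + first, offset + last + window, strand),
                    "window_scorer",
                    score,
                )
            )
    out.sort(key=lambda r: (r.interval.start, r.interval.strand))
    return out


def _greedy_match(
    s: str, start: int, track_char: str, min_track: int,
    loop_min: int, loop_max: int, loop_chars: frozenset,
) -> int | None:
    """End of the leftmost-greedy four-tract match anchored at ``start``.

    Mirrors regex backtracking for ``T{min,}(L{lmin,lmax}T{min,}){3}`` with
    greedy quantifiers: each tract takes as many tract characters as
    possible, each loop as many loop characters as possible, backtracking
    on failure.  Returns the end index (exclusive) of the first successful
    parse, or None.
    """
    n = len(s)

    def run_len(i: int) -> int:
        j = i
        while j < n and s[j] == track_char:
            j += 1
        return j - i

    def loop_run(i: int) -> int:
        j = i
        while j < n and j - i < loop_max and s[j] in loop_chars:
            j += 1
        return j - i

    def rec(i: int, tracts_left: int) -> int | None:
        r = run_len(i)
        if r < min_track:
            return None
        if tracts_left == 1:
            return i + r  # greedy: take the whole run
        for take in range(r, min_track - 1, -1):
            lmax_here = loop_run(i + take)
            for lp in range(lmax_here, loop_min - 1, -1):
                end = rec(i + take + lp, tracts_left - 1)
                if end is not None:
                    return end
        return None

    return rec(start, 4)


def quadparser_scan(
    seq: str,
    min_track: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    gs_in_loop: bool = True,
    seq_id: str = "seq",
    offset: int = 0,
) -> list[G4Region]:
    """Pattern-match four G-tracts (and the C-tract mirror) in a sequence.

    Plus-strand pattern: ``G{>=min_track}(L{loop_min,loop_max}G{>=min_track}){3}``
    where the loop alphabet is {A,C,G,T} when ``gs_in_loop`` else the three
    non-tract bases.  Minus strand uses C tracts.  Matches are leftmost,
    greedy and non-overlapping per strand; the score is the tract count (4).
    """
    if not (1 <= loop_min <= loop_max):
        raise ValidationError("need 1 <= loop_min <= loop_max")
    if min_track < 2:
        raise ValidationError("min_track must be >= 2")
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(f"invalid characters {sorted(bad)} in {seq_id}")
    out: list[G4Region] = []
    for track_char, strand in (("G", "+"), ("C", "-")):
        loop_chars = set("ACGT")
        if not gs_in_loop:
            loop_chars.discard(track_char)
        loop_chars = frozenset(loop_chars)
        i = 0
        n = len(s)
        while i < n:
            if s[i] != track_char:
                i += 1
                continue
            end = _greedy_match(s, i, track_char, min_track, loop_min, loop_max, loop_chars)
            if end is None:
                # no match anchored here; skip past this tract character
                i += 1
            else:
                out.append(
                    G4Region(
                        GenomicInterval(seq_id, offset + i, offset + end, strand),
                        "pattern",
                        4.0,
                    )
                )
                i = end
    out.sort(key=lambda r: (r.interval.start, r.interval.strand))
    return out


def scan_fasta(
    fasta,
    method: str = "window_scorer",
    threshold: float = 2.0,
    window: int = 25,
    min_track: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    chunk: int = 1_000_000,
    overlap: int = 200,
) -> list[G4Region]:
    """Scan every sequence of a pyfaidx Fasta (or dict of strings).

    Long chromosomes are scanned in overlapping chunks; duplicate calls in
    the overlap are de-duplicated by coordinates.
    """
    if method not in ("window_scorer", "pattern"):
        raise ValidationError(f"unknown method {method!r}")
    names = fasta.keys() if hasattr(fasta, "keys") else []
    out: list[G4Region] = []
    for name in names:
        seq = str(fasta[name][:]) if not isinstance(fasta[name], str) else fasta[name]
        seen: set[tuple[int, int, str]] = set()
        for cstart in range(0, max(len(seq) - overlap, 1), chunk):
            sub = seq[cstart : cstart + chunk + overlap]
            if method == "window_scorer":
                regions = call_g4_regions(sub, threshold, window, name, cstart)
            else:
                regions = quadparser_scan(
                    sub, min_track, loop_min, loop_max, True, name, cstart
                )
            for r in regions:
                key = (r.interval.start, r.interval.end, r.interval.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(r)
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out
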