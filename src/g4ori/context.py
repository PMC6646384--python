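"""Genomic-context annotation of origins and the class-expression link.

Origins are labelled promoter / transcribed / intergenic from their IS
position against strand-aware gene models (promoter = 2 kb upstream of the
TSS; precedence promoter > transcribed > intergenic).  Origin classes are
tied to expression changes by a permutation gene-set enrichment test: genes
are ranked from upregulated to downregulated by adjusted p-value and fold
change sign, the class's associated genes form the set, and the classic
unweighted running-sum enrichment score is compared with random same-size
gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomeModel, GenomicInterval, ValidationError
from .origins import OriginRecord

__all__ = [
    "GeneModel",
    "genes_from_frame",
    "annotate_location",
    "mark_correlation",
    "build_gene_sets",
    "rank_genes",
    "run_gsea",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id} must be stranded")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    def promoter(self, upstream: int = 2000) -> GenomicInterval | None:
        """The ``upstream`` bp immediately 5' of the TSS, strand-aware.

        None for a plus-strand gene starting at position 0 (no upstream
        room).
        """
        iv = self.interval
        if iv.strand == "+":
            if self.tss == 0:
                return None
            return GenomicInterval(iv.chrom, max(0, self.tss - upstream), self.tss)
        return GenomicInterval(iv.chrom, self.tss + 1, self.tss + 1 + upstream)


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    """Build GeneModels from a frame with gene_id, chrom, start, end, strand."""
    return [
        GeneModel(
            r.gene_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        )
        for r in df.itertuples(index=False)
    ]


def annotate_location(
    origins: list[OriginRecord],
    genes: list[GeneModel],
    promoter_up: int = 2000,
) -> pd.Series:
    """Label each origin promoter / transcribed / intergenic by its IS.

    Promoter = the ``promoter_up`` bp upstream of any TSS (strand-aware,
    TSS itself excluded); transcribed = inside any gene span; promoter
    takes precedence over transcribed.
    """
    promoters = [p for p in (g.promoter(promoter_up) for g in genes) if p is not None]
    spans = [g.interval for g in genes]

    def _hits(point_chrom: str, p: int, ivs: list[GenomicInterval]) -> bool:
        return any(
            iv.chrom == point_chrom and iv.start <= p < iv.end for iv in ivs
        )

    labels = []
    index = []
    for i, o in enumerate(origins):
        if o.is_pos is None:
            raise ValidationError(f"origin {o.origin_id or i} has no IS")
        index.append(o.origin_id or f"origin_{i + 1}")
        chrom, p = o.interval.chrom, o.is_pos
        if _hits(chrom, p, promoters):
            labels.append("promoter")
        elif _hits(chrom, p, spans):
            labels.append("transcribed")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=index, name="location")


def mark_correlation(
    origin_class_sets: dict[str, list[GenomicInterval]],
    mark_sets: dict[str, list[GenomicInterval]],
    genome: GenomeModel,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Pearson correlation of binary bin occupancy: origin classes x marks.

    The genome is tiled with ``bin_size`` bins; a bin is occupied by a set
    when any of its intervals overlaps the bin.  Constant occupancy
    vectors give an undefined correlation, reported as 0 and logged.
    """
    if not mark_sets:
        raise ValidationError("need at least one mark set")
    chroms = genome.chroms()
    offsets = {}
    total_bins = 0
    for c in chroms:
        offsets[c] = total_bins
        total_bins += -(-genome.chrom_lengths[c] // bin_size)

    def occupancy(ivs: list[GenomicInterval]) -> np.ndarray:
        v = np.zeros(total_bins, dtype=np.float64)
        for iv in ivs:
            if iv.chrom not in offsets:
                continue
            b0 = iv.start // bin_size
            b1 = (iv.end - 1) // bin_size
            v[offsets[iv.chrom] + b0 : offsets[iv.chrom] + b1 + 1] = 1.0
        return v

    out = pd.DataFrame(
        index=list(origin_class_sets), columns=list(mark_sets), dtype=float
    )
    cls_vecs = {k: occupancy(v) for k, v in origin_class_sets.items()}
    mark_vecs = {k: occupancy(v) for k, v in mark_sets.items()}
    for cname, cv in cls_vecs.items():
        for mname, mv in mark_vecs.items():
            if cv.std() == 0 or mv.std() == 0:
                logger.warning(
                    "constant occupancy vector for %s/%s; r reported as 0",
                    cname, mname,
                )
                out.loc[cname, mname] = 0.0
            else:
                out.loc[cname, mname] = float(np.corrcoef(cv, mv)[0, 1])
    return out


def build_gene_sets(
    origin_classes: pd.Series,
    origins: list[OriginRecord],
    genes: list[GeneModel],
    mode: str = "promoter",
    promoter_halfwidth: int = 2000,
    body_extent: int = 10000,
) -> dict[str, set[str]]:
    """Genes associated with each origin class.

    ``promoter`` mode includes a gene when at least one class-member IS
    lies within TSS +/- ``promoter_halfwidth`` (inclusive).  ``body`` mode
    requires the IS within the first ``body_extent`` bp of the gene body
    downstream of the TSS — i.e. a strand-aware TSS offset in
    ``(0, body_extent]`` that stays inside the gene span.  Sets may
    overlap between classes.
    """
    if mode not in ("promoter", "body"):
        raise ValidationError(f"unknown mode {mode!r}")
    by_id = {o.origin_id: o for o in origins}
    sets: dict[str, set[str]] = {c: set() for c in origin_classes.unique()}
    for gene in genes:
        tss = gene.tss
        iv = gene.interval
        for oid, label in origin_classes.items():
            o = by_id.get(oid)
            if o is None or o.is_pos is None or o.interval.chrom != iv.chrom:
                continue
            p = o.is_pos
            if mode == "promoter":
                hit = abs(p - tss) <= promoter_halfwidth
            else:
                off = p - tss if iv.strand == "+" else tss - p
                inside = iv.start <= p < iv.end
                hit = inside and 0 < off <= body_extent
            if hit:
                sets[label].add(gene.gene_id)
    return sets


def rank_genes(de_table: pd.DataFrame) -> list[str]:
    """Rank genes from upregulated to downregulated.

    Ordering key: signed significance ``sign(log2FC) * -log10(padj)``
    descending, so strongly significant upregulated genes come first and
    strongly significant downregulated last.  Ties break by |log2FC|
    descending, then gene id.  Expects columns gene_id, log2FC, padj.
    """
    for col in ("gene_id", "log2FC", "padj"):
        if col not in de_table.columns:
            raise ValidationError(f"DE table lacks column {col!r}")
    if de_table["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in DE table")
    df = de_table.copy()
    padj = df["padj"].clip(lower=1e-300)
    df["_key"] = np.sign(df["log2FC"]) * -np.log10(padj)
    df["_abs"] = df["log2FC"].abs()
    df = df.sort_values(
        ["_key", "_abs", "gene_id"], ascending=[False, False, True], kind="mergesort"
    )
    return df["gene_id"].tolist()


def _es_from_hits(hit_pos: np.ndarray, n_genes: int, set_size: int) -> float:
    """Signed classic KS enrichment score from sorted 0-based hit ranks."""
    k = set_size
    miss_dec = 1.0 / (n_genes - k)
    hit_inc = 1.0 / k
    i = np.arange(1, k + 1)
    after = i * hit_inc - (hit_pos + 1 - i) * miss_dec   # running sum just after hit i
    before = (i - 1) * hit_inc - (hit_pos - (i - 1)) * miss_dec  # just before hit i
    cands = np.concatenate([after, before, [0.0]])
    return float(cands[np.argmax(np.abs(cands))])


def run_gsea(
    ranked: list[str],
    gene_set: set[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Permutation gene-set enrichment on a ranked list.

    The enrichment score is the maximal deviation of the unweighted
    running sum (hit +1/|set|, miss -1/(N-|set|)); positive scores mean
    the set concentrates among upregulated (top-ranked) genes.  The null
    distribution comes from random same-size gene sets; the p-value is
    ``(1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)`` and is deterministic
    for a given seed.
    """
    n = len(ranked)
    idx = {g: i for i, g in enumerate(ranked)}
    if len(idx) != n:
        raise ValidationError("ranked list contains duplicates")
    missing = gene_set - idx.keys()
    if missing:
        raise ValidationError(f"gene set members missing from ranking: {sorted(missing)[:5]}")
    k = len(gene_set)
    if k == 0 or k >= n:
        raise ValidationError(f"gene set size {k} must satisfy 0 < size < {n}")
    hit_pos = np.sort(np.array([idx[g] for g in gene_set], dtype=np.int64))
    es_obs = _es_from_hits(hit_pos, n, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_hits = np.sort(rng.choice(n, size=k, replace=False))
        if abs(_es_from_hits(perm_hits, n, k)) >= abs(es_obs):
            exceed += 1
    return {
        "es": es_obs,
        "pvalue": (1 + exceed) / (1 + n_perm),
        "set_size": k,
        "n_genes": n,
        "n_perm": n_perm,
    }
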