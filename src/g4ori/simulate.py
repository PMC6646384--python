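"""Synthetic SNS-seq study generator with known ground truth.

Every pipeline stage gets a recovery test without downloads: the generator
emits a random genome with origins whose initiation sites carry planted
quadruplex motifs at a controlled offset distribution, a two-condition
replicate experiment (3 control + 2 treated, the standard design for a
G4-ligand SNS-seq study) with negative-binomial counts and planted per-class fold
changes, and a differential-expression table with a planted
class-expression association.  A TruthTable records every planted value;
regeneration from the same parameters and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import CLASS_LABELS
from .g4 import call_g4_regions, quadparser_scan, reverse_complement
from .intervals import GenomeModel, GenomicInterval, ValidationError
from .io import NarrowPeak, write_bed, write_narrowpeak
from .origins import OriginRecord

__all__ = [
    "TruthTable",
    "SimulatedGenome",
    "SimulatedExperiment",
    "G4_MOTIF",
    "simulate_genome_with_g4",
    "simulate_origin_experiment",
    "simulate_expression_table",
    "genes_for_origins",
]

# four G-tracts of 4 with 1 nt loops: every 25 nt window containing the
# full 19-mer has a run-capped mean >= 64/25 = 2.56, and the pattern
# scanner matches it with tract >= 3 / loops 1-7
G4_MOTIF = "GGGGTGGGGTGGGGTGGGG"

# realistic outcome mix for a G4-ligand origin experiment: most origins
# unaffected, new origins dominating the affected set
DEFAULT_CLASS_MIX = {
    "insensitive": 0.779,
    "new": 0.157,
    "reinforced": 0.006,
    "reduced": 0.007,
    "suppressed": 0.051,
}


@dataclass
class TruthTable:
    """Planted ground truth serialized alongside every synthetic dataset."""

    seed: int
    params: dict
    origins: pd.DataFrame | None = None   # per-origin truth
    genes: pd.DataFrame | None = None     # per-gene truth

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "params": self.params}
        if self.origins is not None:
            payload["origins"] = self.origins.to_dict(orient="list")
        if self.genes is not None:
            payload["genes"] = self.genes.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            params=d["params"],
            origins=pd.DataFrame(d["origins"]) if "origins" in d else None,
            genes=pd.DataFrame(d["genes"]) if "genes" in d else None,
        )


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genome: GenomeModel
    origins: list[OriginRecord]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_bed(outdir / "gaps.bed", self.genome.gaps)
        write_bed(
            outdir / "origins.bed",
            [o.interval for o in self.origins],
            names=[o.origin_id for o in self.origins],
            scores=[float(o.is_pos) for o in self.origins],
        )
        self.truth.to_json(outdir / "truth_genome.json")


@dataclass
class SimulatedExperiment:
    counts: pd.DataFrame                      # origins x samples
    conditions: dict[str, str]                # sample -> control/treated
    peaks: dict[str, list[NarrowPeak]]        # per-replicate narrow peaks
    presence: pd.DataFrame                    # truth present_ctrl/present_trt
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="origin_id")
        pd.Series(self.conditions, name="condition").rename_axis("sample").to_csv(
            outdir / "design.tsv", sep="\t"
        )
        for rep, pk in self.peaks.items():
            write_narrowpeak(outdir / f"{rep}.narrowPeak", pk)
        self.truth.to_json(outdir / "truth_experiment.json")


_FLANK = 1000  # scrubbed / profiled window half-width around each IS


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2
    return rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"), size=n, p=[at, gc / 2, gc / 2, at]
    )


def _has_g4(seq: str) -> bool:
    return bool(call_g4_regions(seq)) or bool(quadparser_scan(seq))


def simulate_genome_with_g4(
    n_chrom: int = 2,
    chrom_len: int = 600_000,
    gc: float = 0.42,
    origin_count: int = 200,
    g4_offset_mean: float = -250.0,
    g4_offset_sd: float = 50.0,
    g4_fraction: float = 0.8,
    origin_halfwidth: int = 150,
    min_spacing: int = 6000,
    gap_len: int = 2000,
    seed: int = 0,
) -> SimulatedGenome:
    """Random genome with origins and planted quadruplex motifs.

    Background bases are i.i.d. at the given GC content; each chromosome
    starts with an assembly gap of ``gap_len`` N bases.  Origins are laid
    out on a jittered grid with at least ``min_spacing`` bp between
    initiation sites.  For ``g4_fraction`` of the origins a motif whose
    window score exceeds 2 is inserted with its midpoint at a
    Normal(mean, sd) offset from the IS, on a random strand (a negative
    offset is upstream on the motif's strand; minus-strand motifs are
    placed mirrored so oriented profiles peak at the offset mean).  All
    other origins are scrubbed of accidental G4 signals within +/-1 kb of
    the IS, as is the background around planted motifs.
    """
    if not 0 <= g4_fraction <= 1:
        raise ValidationError("g4_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    params = dict(
        n_chrom=n_chrom, chrom_len=chrom_len, gc=gc, origin_count=origin_count,
        g4_offset_mean=g4_offset_mean, g4_offset_sd=g4_offset_sd,
        g4_fraction=g4_fraction, origin_halfwidth=origin_halfwidth,
        min_spacing=min_spacing, gap_len=gap_len,
    )
    edge = gap_len + _FLANK + 200
    usable = chrom_len - 2 * edge
    per_chrom = [origin_count // n_chrom] * n_chrom
    for i in range(origin_count % n_chrom):
        per_chrom[i] += 1
    if max(per_chrom) * min_spacing > usable:
        raise ValidationError(
            "origin spacing does not fit: "
            f"{max(per_chrom)} origins x {min_spacing} bp > {usable} usable bp"
        )

    sequences: dict[str, np.ndarray] = {}
    gaps: list[GenomicInterval] = []
    origins: list[OriginRecord] = []
    truth_rows = []
    motif_arr = np.frombuffer(G4_MOTIF.encode(), dtype="S1")
    motif_rc_arr = np.frombuffer(reverse_complement(G4_MOTIF).encode(), dtype="S1")
    half_m = len(G4_MOTIF) // 2

    oid = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, chrom_len, gc)
        seq[:gap_len] = b"N"
        gaps.append(GenomicInterval(chrom, 0, gap_len))

        n_here = per_chrom[ci]
        slot = usable // n_here
        jitter_room = slot - min_spacing
        is_positions = [
            edge + j * slot + min_spacing // 2 + int(rng.integers(0, jitter_room + 1))
            for j in range(n_here)
        ]
        for p in is_positions:
            oid += 1
            origin_id = f"origin_{oid}"
            span = GenomicInterval(chrom, p - origin_halfwidth, p + origin_halfwidth)
            origins.append(OriginRecord(span, p, frozenset(), origin_id))

            # scrub accidental G4 signal in the profiled window
            w0, w1 = p - _FLANK - 25, p + _FLANK + 25
            for _attempt in range(100):
                window = seq[w0:w1].tobytes().decode()
                if not _has_g4(window):
                    break
                seq[w0:w1] = _random_sequence(rng, w1 - w0, gc)
            else:
                raise ValidationError(f"could not scrub G4 signal near {origin_id}")

            planted = bool(rng.random() < g4_fraction)
            offset = None
            strand = None
            if planted:
                for _attempt in range(100):
                    off = int(round(rng.normal(g4_offset_mean, g4_offset_sd)))
                    if abs(off) + half_m + 1 <= _FLANK:
                        offset = off
                        break
                else:
                    raise ValidationError(
                        f"could not draw an in-window G4 offset for {origin_id}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                mid = p + offset if strand == "+" else p - offset
                m0 = mid - half_m
                seq[m0 : m0 + len(G4_MOTIF)] = (
                    motif_arr if strand == "+" else motif_rc_arr
                )
            truth_rows.append(
                {
                    "origin_id": origin_id,
                    "chrom": chrom,
                    "start": span.start,
                    "end": span.end,
                    "is_pos": p,
                    "g4_planted": planted,
                    "g4_offset": offset,
                    "g4_strand": strand,
                }
            )
        sequences[chrom] = seq

    genome = GenomeModel({f"chr{i + 1}": chrom_len for i in range(n_chrom)}, gaps)
    truth = TruthTable(seed=seed, params=params, origins=pd.DataFrame(truth_rows))
    seq_strings = {c: s.tobytes().decode() for c, s in sequences.items()}
    return SimulatedGenome(seq_strings, genome, origins, truth)


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    r = 1.0 / alpha
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_origin_experiment(
    origins: list[OriginRecord],
    class_mix: dict[str, float] | None = None,
    base_mean: float = 200.0,
    dispersion: float = 0.05,
    planted_lfc: float = 2.0,
    n_ctrl: int = 3,
    n_trt: int = 2,
    background_mean: float = 1.0,
    size_factor_sd: float = 0.1,
    peak_jitter: int = 20,
    seed: int = 0,
) -> SimulatedExperiment:
    """Two-condition replicate counts and peaks with planted classes.

    Origins are assigned classes from ``class_mix`` (default:
    ``DEFAULT_CLASS_MIX``).  Condition means per class: insensitive (m, m), new
    (background, m), reinforced (m, m * 2^lfc), reduced (m, m * 2^-lfc),
    suppressed (m, background); counts per sample are NB(mean * size
    factor, dispersion) with per-sample lognormal size factors.  Peaks are
    emitted per replicate only where the class is active in that
    condition (new: treated only; suppressed: control only), with summit
    at the IS and boundary jitter.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if set(mix) != set(CLASS_LABELS):
        raise ValidationError(f"class mix must cover exactly {CLASS_LABELS}")
    probs = np.array([mix[c] for c in CLASS_LABELS])
    if not np.isclose(probs.sum(), 1.0):
        raise ValidationError(f"class fractions sum to {probs.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    params = dict(
        class_mix=mix, base_mean=base_mean, dispersion=dispersion,
        planted_lfc=planted_lfc, n_ctrl=n_ctrl, n_trt=n_trt,
        background_mean=background_mean, size_factor_sd=size_factor_sd,
        peak_jitter=peak_jitter,
    )
    samples = [f"ctrl_{i + 1}" for i in range(n_ctrl)] + [
        f"trt_{i + 1}" for i in range(n_trt)
    ]
    conditions = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}
    size_factors = np.exp(rng.normal(0.0, size_factor_sd, size=len(samples)))

    labels = rng.choice(len(CLASS_LABELS), size=len(origins), p=probs)
    mean_map = {
        "insensitive": (base_mean, base_mean),
        "new": (background_mean, base_mean),
        "reinforced": (base_mean, base_mean * 2**planted_lfc),
        "reduced": (base_mean, base_mean * 2**-planted_lfc),
        "suppressed": (base_mean, background_mean),
    }
    counts = np.zeros((len(origins), len(samples)), dtype=np.int64)
    peaks: dict[str, list[NarrowPeak]] = {s: [] for s in samples}
    truth_rows = []
    presence_rows = []
    for i, o in enumerate(origins):
        label = CLASS_LABELS[labels[i]]
        mc, mt = mean_map[label]
        for j, s in enumerate(samples):
            mu = (mc if conditions[s] == "control" else mt) * size_factors[j]
            counts[i, j] = _nb_draw(rng, mu, dispersion)
        pres_c = label != "new"
        pres_t = label != "suppressed"
        for j, s in enumerate(samples):
            active = pres_c if conditions[s] == "control" else pres_t
            if not active:
                continue
            iv = o.interval
            js, je = rng.integers(-peak_jitter, peak_jitter + 1, size=2)
            start = max(0, iv.start + int(js))
            end = max(start + 1, iv.end + int(je))
            if o.is_pos is not None and not (start <= o.is_pos < end):
                start, end = iv.start, iv.end
            peaks[s].append(
                NarrowPeak(
                    interval=GenomicInterval(iv.chrom, start, end),
                    name=o.origin_id,
                    score=float(counts[i, j]),
                    summit_offset=(o.is_pos - start) if o.is_pos is not None else -1,
                )
            )
        truth_rows.append(
            {
                "origin_id": o.origin_id,
                "true_class": label,
                "ctrl_mean": mc,
                "trt_mean": mt,
                "true_lfc": float(np.log2((mt + 0.5) / (mc + 0.5))),
            }
        )
        presence_rows.append(
            {"origin_id": o.origin_id, "present_ctrl": pres_c, "present_trt": pres_t}
        )
    counts_df = pd.DataFrame(
        counts, index=[o.origin_id for o in origins], columns=samples
    )
    truth = TruthTable(seed=seed, params=params, origins=pd.DataFrame(truth_rows))
    presence = pd.DataFrame(presence_rows).set_index("origin_id")
    return SimulatedExperiment(counts_df, conditions, peaks, presence, truth)


def genes_for_origins(
    origins: list[OriginRecord],
    tss_offset: int = 500,
    gene_length: int = 5000,
) -> pd.DataFrame:
    """One plus-strand gene per origin with the IS in its promoter.

    The TSS sits ``tss_offset`` bp downstream of the IS, so the IS falls
    in the 2 kb promoter window upstream of the TSS.  Returns a frame
    compatible with :func:`g4ori.context.genes_from_frame`.
    """
    rows = []
    for o in origins:
        if o.is_pos is None:
            raise ValidationError(f"origin {o.origin_id} has no IS")
        tss = o.is_pos + tss_offset
        rows.append(
            {
                "gene_id": f"gene_{o.origin_id}",
                "chrom": o.interval.chrom,
                "start": tss,
                "end": tss + gene_length,
                "strand": "+",
            }
        )
    return pd.DataFrame(rows)


def simulate_expression_table(
    gene_ids: list[str],
    target_genes: set[str],
    effect: float = -2.0,
    effect_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """DE table with a planted expression shift for one gene set.

    Unaffected genes get log2FC ~ Normal(0, 1) and padj ~ Uniform(0, 1);
    target genes get log2FC ~ Normal(effect, effect_sd) and strongly
    deflated padj (U(0,1)^5).  Returns the table (columns gene_id,
    log2FC, padj) plus the truth.
    """
    missing = target_genes - set(gene_ids)
    if missing:
        raise ValidationError(f"target genes not in universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in gene_ids:
        if g in target_genes:
            lfc = rng.normal(effect, effect_sd)
            padj = float(rng.random() ** 5)
        else:
            lfc = rng.normal(0.0, 1.0)
            padj = float(rng.random())
        rows.append({"gene_id": g, "log2FC": float(lfc), "padj": padj})
    table = pd.DataFrame(rows)
    truth = TruthTable(
        seed=seed,
        params=dict(effect=effect, effect_sd=effect_sd, n_target=len(target_genes)),
        genes=pd.DataFrame(
            {"gene_id": gene_ids, "is_target": [g in target_genes for g in gene_ids]}
        ),
    )
    return table, truth
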