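# g4ori

Analysis toolkit for studying the role of G-quadruplexes (G4) in
metazoan DNA replication initiation. It is written for groups working
with SNS-seq (short nascent strand sequencing) data who want to ask: do
replication origins carry G4-forming elements, where do those elements
sit relative to the initiation site (IS), and how does the origin
repertoire respond when G4 structures are stabilized by a ligand such as
PhenDC3?

The package implements the full downstream pipeline as a library, plus a
thin `g4ori` command line and a synthetic-data generator with complete
ground truth, so every stage is testable without any genome download.

## What it computes

**G4 prediction.** Two sequence predictors:

* *run-capped window scorer* — each base in a G-run of length *n* scores
  `+min(n, 4)`, in a C-run `-min(n, 4)`, else 0; sliding windows of
  *w* = 25 nt are averaged, and regions where `|mean| >= 2` are called,
  with the sign giving the G-rich strand. A window mean of 2 is a
  practically false-positive-free predictor of quadruplex formation.
* *pattern scanner* — four G-tracts of length >= 3 separated by loops of
  1–7 nt (`G{3,}([ACGT]{1,7}G{3,}){3}` and its C-tract mirror), matched
  leftmost, greedy, non-overlapping per strand.

**Origin calling.** Narrow peaks overlapping broad enriched regions are
kept; peaks are clustered across replicates by single-linkage overlap and
clusters supported by >= 2 replicates become consensus origins. The IS is
the position of maximal nascent-strand coverage (or the reported summit).

**Differential classes.** Per-origin counts from 3 control and 2 treated
replicates are normalized by median-of-ratios size factors and tested
with a negative-binomial Wald test (counts `~ NB(mu, alpha)`, variance
`mu + alpha mu^2`, common method-of-moments dispersion). Benjamini–
Hochberg FDR plus per-condition peak reproducibility assign each origin
to one of five classes — *insensitive, new, reinforced, reduced,
suppressed* — at FDR <= 0.01 and `|log2FC| >= 1`.

**G4–origin association.** An origin is G4-positive if a region with
score >= 2 lies within ±500 bp of its IS. Per-bp positional profiles
report the fraction of origins covered by G4 at each offset in ±1 kb
around the IS (minus-strand G4 coverage mirror-mapped onto the plus
strand), with Wilson 95% intervals and an empirical null band from 1000
shuffles of the IS coordinates that keep the chromosomal distribution
and avoid assembly gaps.

**Context and expression.** Origins are annotated promoter (2 kb
upstream of the TSS, strand-aware) / transcribed / intergenic; origin
classes are linked to expression via a permutation GSEA: genes ranked
from up- to downregulated by adjusted *p* and fold-change sign, classic
unweighted running-sum enrichment score, p-value from 10,000 random
same-size gene sets.

## Worked example

```bash
python examples/03_positional_profile.py
```

```
window-scorer G4 calls genome-wide: 246
G4-positive origins (+/-500 bp of IS): 81.7%
profile peak offset: -261 bp (negative = upstream of the IS)
peak fraction 0.280 vs null mean 0.0048
```

The simulated genome plants G4 motifs at ~250 bp upstream of each
origin's IS: ~82% of origins are called G4-positive, the oriented
profile peaks 261 bp upstream, and the observed peak fraction (0.28)
towers over the shuffled-IS null (0.005) — the association is positional,
not a genome-wide G4-density artifact. The other examples cover G4
prediction on known sequences (`01`), five-class origin classification
with planted-label recovery (`02`), and the class–expression GSEA
(`04`).

The same stages are available from the shell:

```bash
g4ori simulate experiment --seed 4 --origins 200 --outdir sim/
g4ori g4 scan --fasta sim/genome.fa --method both --out g4.bed
g4ori origins call --narrow sim/ctrl_1.narrowPeak --narrow sim/ctrl_2.narrowPeak \
    --narrow sim/ctrl_3.narrowPeak --narrow sim/trt_1.narrowPeak \
    --narrow sim/trt_2.narrowPeak --out origins.bed
g4ori origins classify --counts sim/counts.tsv --design sim/design.tsv --out classes.tsv
```

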