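# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention. BED, narrowPeak and tab-delimited count matrices are consumed
natively; GTF (1-based closed) is shifted on read; FASTA goes through
pyfaidx. Nothing downstream of the `io` module ever sees a second
convention — this is the single cheapest way to avoid off-by-one drift in
a pipeline that mixes peak files, gene models and per-bp profiles.

## G4 prediction

The **window scorer** assigns each base in a G-run of length *n* the
score `+min(n, 4)` and each base in a C-run `-min(n, 4)`; other bases and
N score 0, and N breaks runs. Windows of 25 nt (step 1) are averaged;
regions are the per-sign unions of overlapping windows with `|mean| >=
2`, scored by the maximal absolute window mean, stranded by the sign.
Defaults (threshold 2, window 25) are the published operating point of
this score: no sequence reaching 2 has been found unable to fold in
physiological salt. Two deliberate conventions:

* regions are raw window unions with no post-hoc trimming or refinement.
  This is the simplest reproducible convention; genome-wide *counts* are
  therefore convention-dependent and may differ from tools that trim
  regions back to the scoring subsequence. Compare counts only after
  fixing the merging convention on both sides.
* windows containing N are still scored (the N contributes 0), so
  assembly gaps depress rather than erase signal.

The **pattern scanner** matches four tracts of >= 3 G separated by loops
of 1–7 nt, with G permitted in loops, plus the C-tract mirror for the
minus strand. Matching is leftmost-greedy non-overlapping per strand,
implemented as an explicit backtracking scan whose semantics mirror a
greedy regular expression (the test suite holds it equal to an
independent `re`-based oracle). Overlap resolution is the main source of
count differences between pattern scanners; leftmost-greedy matches the
common default.

## Origin consensus and initiation sites

Narrow peaks are retained only when they overlap (>= 1 bp) a broad
enriched region — the two-caller intersection that defines credible
initiation regions. Retained peaks are clustered across replicates by
single-linkage >= 1 bp overlap (our choice, matching the default
merge semantics of standard interval tooling); a cluster supported by
>= 2 distinct replicates becomes a consensus origin spanning the cluster
union. Per-condition presence — used later for the *new*/*suppressed*
classes — requires >= 2 replicates of that condition, which for a
2-replicate treated arm means both. The IS is the leftmost position of
maximal per-bp coverage over the span; a narrowPeak summit substitutes
when coverage is absent, and the span midpoint (with a warning) when
both are.

## Differential test and the five classes

Counts are modelled as NB with variance `mu + alpha mu^2`. Size factors
are median-of-ratios against the geometric-mean pseudo-reference over
all-positive origins (cross-checked in the tests against an independent
DESeq2 reimplementation); with no all-positive origin the code falls
back to total-count scaling with a warning.

With 3 + 2 replicates a per-origin dispersion is statistically
unidentifiable — a per-origin method-of-moments plug-in inflates the
Wald test's type-I error to ~0.14 at nominal 0.05 in our null
simulations. The default estimator therefore pools the method-of-moments
equations over *all* origins and both conditions into one common
dispersion (`sum df (s^2 - mu) = alpha sum df mu^2`, floored at 1e-8),
which calibrates the test (measured type-I ~0.05; the suite enforces
[0.035, 0.065]). `dispersion="per-origin"` exposes the unpooled
estimator. This NB Wald test (no shrinkage, no outlier filtering) is a
documented reimplementation, not a numerical clone of any published
tool; its validity rests on the simulation results (calibration, >90%
power for 4-fold changes at mean 100, >=90% planted-label recovery).

log2FC is the log2 ratio of normalized condition means with pseudo-count
0.5, so origins absent from one condition get large finite fold changes.
Significance = FDR <= 0.01 and `|log2FC| >= 1` (a two-fold change); both
thresholds are configurable, with 1% FDR the conventional stringency for
differential origin calling. Classes:

| class | rule |
|---|---|
| new | significant up, absent in control |
| suppressed | significant down, absent in treated |
| reinforced | significant up, present in both |
| reduced | significant down, present in both |
| insensitive | everything else |

Origins whose presence flags contradict the fold-change direction are
assigned insensitive and logged. `class_summary` reports each class's
percentage of all origins and of the affected (non-insensitive) set;
with the observed mix (77.9 / 15.7 / 0.6 / 0.7 / 5.1%), new origins are
71.0% of the affected set.

## Positional profiles and nulls

The ±500 bp G4-positivity window is anchored on the IS summit (the
"center" of an origin; the interval midpoint is available as an option)
and is inclusive at both bounds. Profiles count per-bp G4 coverage at
offsets ±1 kb from the IS as a fraction of origins; coverage rather than
G4 midpoints is the default (a midpoint mode is exposed) because it is
the convention that makes the coverage-conservation invariant exact.
Origins stay unoriented; minus-strand G4 coverage is mirror-mapped
(offset → −offset), so a G-rich element upstream on either strand
accumulates at negative offsets, and reverse-complementing the genome
leaves the oriented profile invariant (tested). Observed uncertainty is
the Wilson 95% interval per offset; the null band is the empirical
2.5–97.5 percentile range over shuffles that redraw IS coordinates
uniformly per chromosome outside assembly gaps (preserving the
per-chromosome count), by rejection sampling with a hard error after
1000 attempts — silent fallbacks would bias the null toward gap-free
chromosomes. Neither interval choice is prescribed anywhere; Wilson and
empirical percentiles are the standard options.

The read heatmap bins read midpoints into 100 bp bins over ±7 kb of each
IS (140 columns), rows sorted by log2FC.

## Context annotation and GSEA

Promoter = 2 kb strand-aware upstream of the TSS, precedence promoter >
transcribed > intergenic, decided by the IS position. Gene sets per
class: promoter mode = any class IS within TSS ± 2 kb; body mode = IS
within the first 10 kb of the gene body downstream of the TSS (our
reading of "TSS + 10 kb"). Genes are ranked by signed significance
(`sign(log2FC) · −log10 padj`), ties broken by `|log2FC|` then gene id
(adjusted p-values alone leave ties; these tie-breaks make the ranking
deterministic). The enrichment score is the classic unweighted running
sum (hit `+1/|S|`, miss `−1/(N−|S|)`, ES = maximal deviation); we prefer
the unweighted form over the weighted variant because it is the one with
an exact top-*k* calibration (ES = 1).
The permutation null draws random same-size gene sets (set-size-
preserving label permutation); `p = (1 + #{|ES_perm| >= |ES_obs|}) /
(1 + n_perm)`, 10,000 permutations by default.

Chromatin-mark association is Pearson correlation of binary occupancy
vectors over a 1 kb genome tiling; constant vectors return r = 0 with a
logged flag.

## Synthetic data: what it emulates, and what it does not

`simulate_genome_with_g4` draws i.i.d. bases at 42% GC (mouse-like),
plants the 19-mer `GGGGTGGGGTGGGGTGGGG` motif (window score 2.56,
pattern-scanner match) with its midpoint at Normal(−250, 50²) bp from
the IS on a Bernoulli(0.5) strand (minus-strand motifs placed mirrored
so oriented profiles peak at the offset mean), and scrubs accidental G4
signal from all origin flanks so recovery tests see only planted signal.
`simulate_origin_experiment` reproduces the 3-control / 2-treated
design, the outcome class mix (77.9 / 15.7 / 0.6 / 0.7 / 5.1%), NB
counts at base mean 200 and dispersion 0.05 with |log2FC| 2 for planted
changes, lognormal per-sample size factors (sd 0.1), and per-replicate
peak files whose presence follows the class. `simulate_expression_table`
plants a log2FC shift and deflated adjusted p on one class's genes.

Passing recovery tests on these data shows the pipeline's logic is
correct under its own model assumptions. Real SNS-seq data additionally
contain autocorrelated background, replication-timing structure, mapping
artifacts, GC-dependent coverage bias, broad/overlapping origins, and
G4s in repetitive sequence — none of which the generator emulates, so
quantitative results on real data (e.g. exact class percentages) should
not be expected to match the synthetic recovery rates.

## Problem sizes

The test suite runs the statistical checks at the sizes that make them
meaningful yet quick: 5,000 null origins for calibration, 2,000 origins
for label- and offset-recovery, 1,000 random 200-mers per predictor
oracle, 10,000 random vectors for the BH oracle, 500 GSEA repeats at 200
permutations, 1,000 IS shuffles for the null band. The acceptance script
uses a 4 × 1.6 Mb genome with 1,000 origins, 500 shuffles and 10,000
GSEA permutations. Genome-wide application (e.g. mm10) is a matter of
pointing `g4ori g4 scan` at the genome FASTA and the origin pipeline at
the MACS2/SICER outputs; with the conventions above, predictor totals
are reproducible up to the documented merging choices.

## Known limitations

* The NB test shares one dispersion across origins; strongly
  origin-dependent overdispersion would mis-calibrate tails.
* Read counting uses read midpoints, so reads straddling an origin
  boundary contribute to exactly one origin; tools that count any
  overlap will report slightly higher totals.
* `consensus_reproducible` is single-linkage: dense origin clusters can
  chain into one consensus span.
* GSEA permutes gene sets, not phenotypes; correlated gene statistics
  within a set are not modelled.
* The pattern scanner reports non-overlapping matches only; overlapping
  quadruplex arrangements are undercounted by construction.
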