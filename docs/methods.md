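# Methods

## Problem and scope

`scstability` quantifies how cold ischemic storage time (tissue kept at 4 °C
between collection and dissociation) degrades droplet scRNA-seq data from
solid tissues such as lung, esophagus mucosa and spleen. The pipeline covers
the droplet level (ambient RNA and debris), the cell level (read categories,
mitochondrial load, QC filters), the cell-type level (fold changes,
composition, variance partitioning) and the sample level (bulk vs
pseudo-bulk expression). It does not align reads, call cells from raw
droplets, detect doublets, or cluster/annotate cell types de novo — cell
labels are an input, produced upstream or by the synthetic generator.

## Droplet statistic and classification

For one sequencing run with per-barcode UMI totals $u_b$, the
depth-normalized UMI is

$$\tilde u_b = u_b \cdot 10^6 \big/ \textstyle\sum_{b'} u_{b'},$$

so the values of a run always sum to $10^6$ and are invariant to uniform
depth scaling. Droplets are binned into **ambient RNA** $(0, 0.25]$,
**debris** $(0.25, 5]$ and **cellular material** $(5, \infty)$; upper bounds
are inclusive, and zero-UMI barcodes are reported `unclassified` because the
first interval is open at 0. The run total includes all barcodes, called
cells or not. Per-class means are unweighted over droplets; classes with no
droplets are missing, not zero. Time contrasts on per-donor class means use
two-sided Student t tests — paired for the T0 vs 72 h contrast (donors
matched across time points), unpaired for T0 vs 24 h; the paired variant
refuses zero-variance differences rather than reporting 0/0. The ambient
expression profile of a run is the per-gene UMI sum over ambient droplets
divided by the total ambient UMIs.

## Cell-level QC

Per-barcode confidently mapped reads are consumed as a pre-extracted
exonic/intronic/intergenic table (an upstream extractor working from
alignment records should select the unique confident-mapping tag value 255;
fractions here are category over the three-category total, with zero-total
barcodes flagged and excluded). Quartile-extreme summaries rank cells by a
fraction, take the highest/lowest $\lceil n/4 \rceil$ cells with ties broken
by barcode order, and report the per-sample means of each extreme.

The cell filter keeps a cell iff detected genes $\in [300, 5000]$ (8000 in
esophagus), UMI count $\le 20{,}000$ and mitochondrial percentage
$\le 10\%$. Bounds are kept, strictly-greater/lesser values removed; the
removal log records the first rule fired per cell in the fixed order
min\_genes, max\_genes, max\_umi, max\_mt, so kept + logged = input exactly.
Genes detected in fewer than 3 cells of a tissue are dropped (idempotent).
mt\_pct is $100\times$ (UMIs on the MT gene set)/(total UMIs); the MT set
defaults to gene names prefixed `MT-`. The fraction of cells above 10% MT is
computed *before* the MT filter. Sample-level metrics (cell count, median
genes/cell, total confident reads, mean exonic fraction) are compared T0 vs
each later time point with unpaired t tests, BH-corrected within a metric;
the sample design does not guarantee matched donors across time points.

## High-MT cell reassignment

Cells failing the 10% MT rule are excluded from clustering but must still
contribute to degradation statistics. They are projected onto per-type
centroids built from the low-MT reference cells: counts are normalized to
10,000 per cell and log1p-transformed; features are the 500 genes with the
largest positive residuals of dropout rate regressed on log mean expression
(top-variance fallback when the fit is infeasible); the centroid is the
per-gene median. Query cells take the label of their most cosine-similar
centroid when similarity $\ge 0.7$, otherwise `unassigned`; ties go to the
lexicographically first label and are flagged. A single similarity measure
and a 0.7 threshold are design choices — the projection tool this step
emulates ensembles three measures, but its parameters are not pinned down
anywhere authoritative — and raising the threshold can only abstain more,
never relabel. Assignment is invariant to per-cell depth scaling.

## Degradation statistics

**Mitochondrial fold change.** On the combined table (reference plus
reassigned high-MT cells), FC(tissue, cell type, t) = mean mt\_pct at $t$ /
mean mt\_pct at T0. Significance is a two-sided Mann-Whitney rank test of
the per-cell mt\_pct values against the same stratum's T0 cells — chosen
for robustness to the right-skewed MT distributions — BH-corrected across
all non-baseline strata within a tissue. Strata with fewer than 5 cells on
either side are masked `too_few_cells` with no FC or p; a (tissue, time)
with no sample at all is `missing_sample`; T0 rows are fixed at FC = 1,
p = 1. Adjusted p-values are additionally binned for display
(\* $<10^{-2}$, \*\* $<10^{-5}$, \*\*\* $<10^{-8}$).

**Composition.** Per-sample cell-type proportions (absent types count 0)
are tested per (tissue, cell type) with unpaired two-sided t tests: all
pairwise time contrasts plus the combined early-time-points vs 72 h
contrast; BH spans cell types × contrasts within a tissue. Donor
variability uses one-way ANOVA of proportion on donor (the F test is the
standard reading of a "one-sided" ANOVA), BH within tissue, with an
explicit degenerate flag when within-group variance vanishes.

**Variance partitioning.** For each gene, the marginal $R^2$ of each factor
fitted alone: group means for categorical factors (donor, tissue, cell
type), a univariate linear fit for continuous ones (depth, time);
$R^2 = 1 - \mathrm{RSS}/\mathrm{TSS}$, NaN for zero-variance genes. For
per-cell-type time analyses, donor and depth can be residualized out first;
the global partition uses raw normalized expression per factor alone. A
factor that is a bijection of another yields identical $R^2$.

**Cross-organ dendrogram.** Up to 10 cells per (cell type, tissue, time,
donor) stratum, drawn deterministically from the seed; the 1000 most
variable genes by mean-binned normalized dispersion; average-linkage
clustering on correlation distance, exportable as Newick.

## Expression comparisons

Pseudo-bulk sums raw counts per sample (sum, not mean — the standard
construction). Both sides of any comparison are normalized to counts per
million per sample (the normalization is a package choice, recorded in
output metadata); fold changes are the median over samples of
$\log_2((a+1)/(b+1))$ on the CPM scale. The paired test is the Wilcoxon
signed-rank across matched samples with zero differences dropped (all-zero
differences report p = 1; a single usable pair is untested), exact for
small tie-free sample counts; the unpaired variant is a Mann-Whitney
rank-sum. BH spans tested genes. Note a design-implied floor: with $n$
donor pairs the smallest two-sided exact signed-rank p is $2/2^n$, which
for $n \le 5$ exceeds 0.05 — at this study size, bulk time-point DE
*cannot* produce BH-significant genes, so a negative result there is the
expected outcome under the null and a guaranteed one at $n \le 5$.

Per-cell-type storage signatures are rank-sum tests of log-normalized
expression T0 vs late (cell types with under 20 cells on a side skipped),
kept at BH p < 0.01 and ranked by absolute effect; signature similarity
across cell types is Jaccard. Overrepresentation of a signature among the
dissociation-related reference genes (FOS, FOSB, JUN, JUNB ships as the
default list) uses a one-sided (enrichment) Fisher exact test; the odds
ratio applies a Haldane 0.5 correction when a margin cell is zero.

## Synthetic experiment generator

The generator emulates the study design — donors × tissues × time points
(default 5 donors, 3 tissues, 0/12/24/72 h), one sequencing run per sample
— with known truth for every downstream statistic.

*Count model.* Per-droplet UMI totals are log-normal around the class mean
(cells σ = 0.5, debris σ = 0.35, ambient σ = 0.45; means default to
20,000 / 30 / 2 with ~1000 cells, 1500 debris and 4000 ambient droplets per
run) and each total is split over genes by a multinomial on the droplet's
profile. Cell profiles are marker-block mixtures; debris droplets reuse
cell profiles at reduced depth; ambient droplets draw from the UMI-weighted
mixture of all type profiles (optionally up-weighting a plasma-like
high-secretion gene set). The default class means sit roughly a decade
apart in depth and keep the expected run total near 20M UMIs so the three
classes land in their normalized-UMI intervals — `SimConfig.default`
rescales per-cell depth with the cell count to preserve this. The debris
band (0.25, 5] is targeted directly, as its depth distribution has no
independent ground truth. These are desk-scale runs; real runs have
hundreds of thousands of droplets, which is why the synthetic per-cell
depth exceeds real 10x depth whenever the droplet count is scaled down.

*Degradation knobs* (all null by default, all required to be null at T0):
mitochondrial inflation reallocates profile mass so the MT share equals
baseline × fold change, preserving depth so MT% and depth stay orthogonal;
the intron shift translates the per-barcode Beta-distributed exonic
fraction down by the stated amount (a pure translation, so quartile-extreme
means move by exactly the shift), the intronic fraction gaining it while
the intergenic share stays a small constant; the ambient target sets the
expected share of run UMIs in ambient droplets by rescaling their depth;
storage-signature genes are multiplied by a per-time factor. Read-category
totals are Poisson around 4 reads per UMI and are generated per barcode
independently of the gene counts, mirroring how the two measurements arise
from different records.

*Determinism.* One global seed; per-sample substreams derive from
(seed, donor index, tissue index, time index), so identical configs are
bit-identical and adding a sample leaves the others unchanged. Bulk
libraries draw from the donor's true mixture (no dissociation bias) with an
optional planted log2 offset on stated genes, giving bulk-vs-pseudo-bulk DE
known positives.

*What the generator does not emulate:* doublets, batch/chemistry effects,
gene-length or GC bias, per-gene donor effects, and raw reads. Passing
tests therefore demonstrate correctness and calibration of the statistics
under a faithful but idealized count model, not robustness to every
artifact of real data.

## Pipeline

Stages run in dependency order (droplets → cells → assign → stats; de when
bulk counts are provided) from a single config; the cell stage treats
droplets classified `cellular` as the cell set, since cell calling proper
is upstream. All intermediate tables are serialized as TSV; the manifest
records a canonical config hash and per-table checksums (identical config +
inputs ⇒ byte-identical outputs); every filter, mask and skip decision is
logged. MTX I/O converts between the 1-based on-disk convention and the
0-based internal one at the boundary. Filter thresholds are config: the
paper-scale defaults assume genome-wide panels, so synthetic runs with
small gene panels relax the gene/UMI bounds while keeping the 10% MT rule.

## Numerical and testing choices

BH correction is a single shared utility (step-up, NaN-passthrough),
verified against a brute-force implementation on all permutations of ≤ 6
p-values. Exact signed-rank p-values are verified against enumeration of
all $2^n$ sign patterns (n ≤ 10, tie-free; with ties the implementation
switches to the normal approximation), and Fisher p-values against direct
hypergeometric tail summation for universes ≤ 50. Calibration checks use
200 null-mode studies (4 donors × 1 tissue × 4 time points, 200 cells and
40 genes per sample) and require empirical size ≤ nominal + 2 binomial SE;
recovery checks use injected effects (MT fold 2 at ~500 cells/stratum,
ambient share 0.02, intron shift 0.15) at the problem sizes stated in the
test suite. Tie-breaks are deterministic throughout (barcode order for
quartiles, lexicographic labels for similarity ties, stable sorts for
rankings).
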