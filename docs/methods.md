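# Methods

`chromhier` analyses the three-layer hierarchy of chromatin architecture —
A/B compartments, topologically associating domains (TADs), and focal
chromatin loops — from binned Hi-C contact counts, and integrates the calls
with gene expression and histone-mark peaks. Because real snake venom-gland
Hi-C libraries are large and external, every stage is validated against a
synthetic generator that plants all three layers with known truth. This note
records the models, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## The synthetic contact model

The generator emulates a snake-like karyotype: a few macro-chromosomes
(MACs, > 50 Mb) and a tail of micro-chromosomes (MICs, < 50 Mb); lengths
exactly at the 50 Mb threshold are disallowed so the classification is
total. Planted structure consists of alternating A/B compartment blocks
(default 1 Mb, a multiple of the 100 kb compartment bin), per-chromosome TAD
boundary positions (kept ≥ 2 insulation windows from chromosome ends,
≥ 300 kb apart, snapped to the 10 kb TAD grid), and loop anchor pairs with
spans in [100 kb, 1 Mb], both anchors falling in A blocks with probability
`p_a = 0.7` (euchromatic-loop predominance). A second-condition compartment
labelling flips a `switch_frac = 0.2` fraction of blocks; these are the
planted compartment switches that the switch classifier and the
switch-expression test recover.

Contacts are Poisson draws from a multiplicative expected-intensity model.
For an intra-chromosomal bin pair at bin distance `d`:

    E[i,j] ∝ (1 + d)^(−α) · c^{same compartment} · t^{same domain} · l^{loop vicinity}

with decay exponent `α = 1.0`, compartment factor `c = 2.5`, domain factor
`t = 2.0`, and loop factor `l = 8` applied in the ±1-bin neighborhood of a
planted anchor pair. Inter-chromosomal pairs get a flat
`trans_level = 0.01` fraction of the mean intra intensity, doubled for
MIC–MIC pairs (micro-chromosomes cluster spatially; the magnitude of that
clustering is a free parameter, set to 2, not an estimate). The genome-wide
expected total — off-diagonal pixels counted twice, diagonal once — is
calibrated to the requested depth; with the distance unit taken in bins,
all downstream consumers (which work in bin space) see consistent decay at
any simulated resolution. Fixing the seed reproduces byte-identical output;
one global seed fans out to stage seeds via `numpy.random.SeedSequence`
spawning in a fixed documented order.

Expression is negative binomial (dispersion 0.1) around a log-normal
baseline; genes are placed Poisson with compartment-dependent density
(defaults 8/Mb in A, 3/Mb in B — A is gene-dense). Genes in switching bins
receive a ±1.5 log2 mean shift (B→A up, A→B down). FPKM is
`count / (gene_kb · library_size/1e6)` with `library_size = 5e6` mapped
fragments: the simulated genes are treated as a subset of a full
transcriptome-scale library. Normalizing by the within-simulation total
instead would inflate FPKM ~1000× at desk scale and make the conventional
FPKM > 20 "high expression" cut vacuous, which is why the library size is a
parameter rather than an observed total.

Histone peaks: H3ac falls in A blocks and H3K27me3 in B blocks with
probability `a_bias = 0.9`; lengths are exponential (mean 1.5 kb) and
overlapping peaks within a mark are merged. For mark–expression coupling a
separate generator plants one peak per gene whose length is an affine
function of a latent variable whose *sample* correlation with
log2(FPKM + 1) equals the target (noise is orthogonalized against the
expression vector), with a fixed-point pass that shrinks each gene's peak
by the coverage neighboring genes' peaks leak into its measurement window —
without it, occasional window contamination attenuates the realized R by
~0.1. Targets default to +0.56 (H3ac) and −0.45 (H3K27me3).

What the generator does *not* emulate: restriction-fragment structure,
mappability and GC biases, centromeres/telomeres (so the known failure mode
where the first principal component tracks chromosome arms cannot arise),
replicate-level variation, and inter-chromosomal loops. Passing recovery
tests therefore demonstrates correctness of the callers under the stated
generative assumptions, not robustness to every artifact of real libraries.

## Contact normalization

Library-size normalization scales the map so the genome-wide total
(off-diagonal twice, diagonal once) equals 1e9 input read pairs — the
convention for comparing tissues. ICE balancing runs per chromosome:
zero-coverage bins and bins below the 2% coverage quantile are masked
(the quantile uses the "lower" method so the minimum bin of a small dense
matrix is never spuriously masked), then iterative proportional fitting
equalizes unmasked row sums to a common target until the maximum relative
deviation drops below 1e-5 (cap 200 iterations). The target row sum is the
mean unmasked raw coverage, which keeps the balanced matrix on the raw
count scale — deliberate, so that the Poisson loop test downstream operates
on count-like values. The bias vector satisfies
`balanced = raw / outer(bias, bias)` exactly.

Observed/expected divides each pixel by the mean balanced value at its bin
distance (unmasked pairs only); distance classes with zero expectation give
zero. The interaction summary assigns every chromosome pair to one of five
classes (intra-MAC, intra-MIC, inter MAC–MAC, MIC–MIC, MAC–MIC), with
frequency = total count / bin-pair count so that chromosome length does not
confound the MAC/MIC comparison, and Welch t-tests between classes (classes
with < 2 members report not-applicable rather than raising).

## Compartments

Per chromosome, the Pearson correlation matrix of O/E rows is computed over
unmasked bins with the diagonal (distance-0) entries excluded exactly: the
pairwise-deletion sums are evaluated in closed form so the exclusion is
vectorized rather than approximated. The eigenvector of the
largest-magnitude eigenvalue is taken (correlation, not covariance — the
correlation form emphasizes the interaction pattern rather than coverage),
zero-filled at masked bins and unit-normed. Its global sign is arbitrary,
so it is oriented by correlation with per-bin gene density (TSS counts at
100 kb): negative correlation flips the sign, making positive = A =
gene-dense. Zero-variance gene density leaves the orientation "unresolved"
(flagged, labels still emitted). Orientation is involution-safe.

Switches are per-bin cross-classifications over bins unmasked in both
profiles; fractions are reported over unmasked bins per chromosome and
genome-wide — per-bin fractions are the only denominators that are
reproducible without knowing a callers' merging conventions. The
switch-expression test assigns each gene the category of its TSS bin and
compares each switching category to the pooled stable (A→A ∪ B→B) group
with the Wilcoxon rank-sum test (`scipy.stats.ranksums`, normal
approximation without tie correction — chosen so the all-ties null yields
p = 1 exactly); categories with < 2 genes report not-applicable.

## TAD boundaries and domains

Insulation at 10 kb: for each bin `i`, the mean balanced contact in the
square `[i−w, i) × [i, i+w)` with `w` = 100 kb / 10 kb bins — the contacts
crossing the bin at range ≤ 100 kb — log2-normalized by the chromosome mean
of these windowed means. Bins whose window exits the chromosome, or whose
window is > 50% masked pixels, are masked. A windowed mean of exactly zero
(perfect insulation) is floored at half the smallest positive mean rather
than masked: it is a real, very deep minimum, not missing data.

Boundaries sit at negative-to-positive zero crossings of the delta vector
(mean insulation over `(i, i+dw]` minus `[i−dw, i)`, `dw` = 100 kb); the
boundary bin is the insulation minimum around the crossing (leftmost of
ties) and is kept when its depth — the lesser of the insulation rises
within `dw` bins to the left and right — reaches `min_strength = 0.1`.
Each boundary bin is then padded 40 kb per side: 10 kb + 80 kb = 90 kb
final boundaries, absorbing between-replicate wobble. Padded intervals that
would exit the chromosome are clipped and flagged, never silently
shortened. This insulation segmentation deliberately replaces corner-score
TAD calling, so absolute TAD counts are not comparable with corner-score
tools; with compartments planted, A/B block edges are
genuine insulation minima as well, which is why boundary-recovery scoring
isolates the domain layer.

Two boundary sets are compared by ≥ 1 bp interval intersection (the weakest
criterion consistent with padding-for-variation) in both directions, plus
the Jaccard of the merged interval sets. TADs are the intervals between
consecutive boundary midpoints plus chromosome-end domains; domains under
3 bins merge into the smaller neighbor; chromosomes with < 2 boundaries
yield one whole-chromosome domain. Feature counting is by TSS containment
with boundary precedence, reported as raw counts and per-Mb densities
(boundary and TAD total lengths differ grossly, so densities are the
comparable quantity).

## Loops

Loop calling follows the donut-filter idea: for each pixel in the band
`1 bin < j − i ≤ 1 Mb / res`, four local backgrounds — donut annulus
(Chebyshev radius (1, 5] excluding the center cross), lower-left quadrant,
horizontal and vertical stripes — each rescale the distance-decay
expectation by their local observed/expected ratio. Neighborhood sums are
FFT convolutions over the masked matrix; a pixel whose neighborhoods are
> 50% masked is dropped. A pixel is significant when its observed count
exceeds 1.5× every local expectation and its Poisson upper-tail p-value
against the largest expectation survives Benjamini–Hochberg at FDR 0.1 per
chromosome and resolution (lambda-chunked FDR is deliberately simplified to
BH; this affects calibration of the threshold, not the mechanics).
Candidates within Chebyshev radius 2 merge by single linkage into loop
peaks (representative = most significant pixel); 10 kb peaks take
precedence over 25 kb peaks whose anchors both overlap them. 5 kb calling
is supported as a configuration value but is not a default. Loop peaks vs
distinct peak loci: the latter counts unique anchor intervals across both
sides. Anchor-midpoint compartment labels give A/B/mixed loop classes;
loop–gene coupling flags genes with TSS inside any anchor and compares the
FPKM > 20 fraction between coupled and uncoupled genes with a
two-proportion z-test.

## Integration

Peak-vs-feature enrichment reports (i) the odds ratio of the base-pair 2×2
table (peak bp in/out of features × genome bp), (ii) a Fisher-style
p-value — the doubled one-sided hypergeometric tail on that table, since a
full two-sided enumeration is infeasible at ~1e8 bp margins — and (iii) a
permutation z-score: each peak repositioned uniformly within its chromosome
(length preserved), 1000 shuffles by default, z = (observed − null mean)/
null sd on the count of peak midpoints inside features. Midpoint
containment is used for counts, bp overlap for the odds ratio. Promoters
are strand-aware, upstream-only, half-open 1 kb windows (`[TSS−1 kb, TSS)`
on +, mirrored on −); the TSS base itself is not upstream. The TSS
meta-profile averages strand-oriented peak coverage in ±3 kb, 100 bp bins.
Mark–expression correlation uses total peak bp in the window from 1 kb
upstream of the TSS through the far gene end against log2(FPKM + 1).

The differential-expression test is a light stand-in, not a shrinkage-based
negative-binomial model: median-of-ratios size factors, log2 fold change of
group means with a 0.5 pseudo-count, and a moderated t on log2 normalized
counts — each gene's pooled variance shrunk toward the across-gene median
with 20 prior degrees of freedom. The moderation matters: at 2–3 replicates
a plain per-gene t-test has a p-value floor (~1e-3 at df ≈ 4) that can
never clear Padj < 0.01 after BH across hundreds of genes, so sharing
variance information across genes — the small-n strategy of the standard DE
tools — is required for the conventional (|lfc| > 1, Padj < 0.01) calls to
be reachable at all. DEG counts from this test are not claimed to reproduce
any published DESeq2 counts.

## Pipeline, configuration, determinism

All numeric conventions live in a strict YAML config (unknown keys
rejected; bp quantities must be positive 1 kb multiples): 100 kb
compartment / 10 kb TAD / {10, 25} kb loop resolutions, 50 Mb MAC
threshold, 40 kb pad, 1 Mb loop cap, FPKM > 20, |lfc| > 1 & Padj < 0.01,
loop FDR 0.1, 1e9 library target. `run_all` executes simulate → normalize →
compartments → switches → TADs → loops → integrate and writes a manifest
with a SHA-256 per output; identical config + seed reproduces identical
hashes. Coordinates are 0-based half-open throughout; bin `k` at resolution
`res` is `[k·res, (k+1)·res)`.

## Problem sizes

The package's own test and example datasets use genomes of two to three
8–20 Mb micro-chromosomes at depth 1e7 (occasionally six to seven
chromosomes including 55–70 Mb MACs at coarser bins for the MAC/MIC
summaries). These sizes were chosen because every recovery statement the
package makes — ≥ 95% compartment-label accuracy at compartment factor 2.5,
≥ 80% boundary recall and precision at domain factor 2, ≥ 80% loop recall
at loop factor 8, switch-fraction recovery within 3 points, Wilcoxon power
≥ 95% with ~200 switching genes — is already achievable and stable at them;
larger genomes change runtimes, not conclusions, because all statistics are
per-bin or per-feature.

## Known limitations

* PC1 is always taken as the compartment axis; on real genomes with
  centromeres or arm-scale features PC1 can track arms instead (out of
  scope for the generator, documented here).
* The switch-fraction denominators are per-bin over unmasked bins; they are
  not comparable to published percentages with unstated denominators.
* Insulation segmentation is not corner-score TAD calling; TAD counts are
  method-dependent.
* BH replaces lambda-chunked FDR in loop calling; the effective FDR at a
  given threshold differs from the original tool's.
* The bp-scale Fisher p-value is a doubled one-sided tail and is reported
  alongside, never instead of, the permutation z.
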