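# Methods

This note documents the statistical procedures implemented in `cdscore`,
the generating processes behind its synthetic cohorts, and the numerical
choices made where the design was genuinely open. Problem sizes quoted
below are the package defaults used by the test suite and
`scripts/acceptance.py`.

## Differential chromatin analysis

**Normalization.** Sequencing depth is absorbed by total-count size
factors, `s_j = total_j / geometric mean of totals`, so the factors
multiply to one; normalized counts are `x/s_j`, optionally
`log2(x/s_j + 1)`. A consequence worth knowing: the size factor is blind
to composition, so a contrast in which only one group carries large planted
effects transfers part of the effect into the size factor and shrinks the
estimated fold change. Real cluster contrasts are roughly balanced
(both sides carry thousands of up-regions), and the calibration
simulations plant balanced designs for the same reason.

**Clustering.** Sample distance is `1 − Spearman ρ` (average ranks on
ties), with average-linkage hierarchical clustering; the linkage choice is
ours (standard for correlation distances). Cluster separation is tested by
PERMANOVA: with `SS_T = Σ_{i<j} d²_ij / N` and `SS_W` the analogous
within-group sum, `F = ((SS_T − SS_W)/(a−1)) / (SS_W/(N−a))`, and
`p = (1 + #{F_π ≥ F}) / (n_perm + 1)` over seeded free label permutations
(999 by default; an exhaustive mode enumerates all permutations for small
N). F is invariant under common positive scaling of the distances. Note
the attainable p floor: permutations that happen to recreate the group
partition (or its complement, for two equal groups) tie the observed F, so
with N = 10 balanced samples the smallest expected p is ≈ 2/C(10,5), not
1/(n_perm+1).

**Differential test.** Counts are modelled as negative binomial with
variance `μ + φμ²`. Per feature, φ is estimated by method of moments on
normalized counts, pooled across the two groups (weighted by degrees of
freedom) and floored at 1e-8 — no shrinkage; the test is validated by
type-I-error and power simulation rather than by equivalence to any
package. The effect is `log2FC = log2((m_A + 0.5)/(m_B + 0.5))` (the 0.5
pseudocount bounds the statistic for zero means), the standard error comes
from the delta method on the NB variance of each group mean, the p-value is
two-sided normal on the Wald ratio, and BH adjustment runs over all tested
features with no independent filtering. All-zero features report
(log2FC 0, p 1). Differential features satisfy `padj ≤ 0.05` (inclusive)
and `|log2FC| > 0.5` (strict). Under the null (200 simulated matrices,
2000 features, 6 + 6 samples, φ = 0.05) the fraction of features at
`padj ≤ 0.05` is ≈ 0.003; a planted log2FC of 6 in a balanced design is
recovered within ±0.5 for ≈ 97–99 % of features.

## CDS signature derivation

Peaks are linked to genes by the single nearest TSS within 400 kb of the
peak midpoint (inclusive at 400,000 bp; equidistant ties break
lexicographically by gene id; unlinked peaks drop out). Signature
candidates for a subtype must (i) exceed the subtype's expression
threshold — `log2FC > 5` for LLI and BL, `> 2` for MP, whose
transcriptional differences are subtler — with the subtype's sign (a
signature contains only genes *up* in its subtype), (ii) pass adjusted
P < 0.05 (strict), and (iii) have at least one linked subtype-specific
differential peak. Candidates are ranked by fold change and the top 15 per
subtype form the signature; a shortfall is returned in full and flagged
rather than silently truncated. Genes claimed by two subtypes go to the
larger |log2FC|, recorded on the losing signature. LLI and BL are derived
from the LLI-vs-BL contrast; MP is contrasted against the pooled URO
samples (the alternative — pairwise against each URO state — is defensible
but was not chosen; pooling matches how MP-specific regions are defined
against everything urothelial).

The size scan truncates every subtype's ranked candidate list to each size
in 5–25, scores all samples, classifies by argmax and computes accuracy
against the chromatin cluster labels, choosing the accuracy-maximizing
size with ties broken toward the smallest. Because the per-sample
enrichment score does not depend on the other samples, leave-one-out and
resubstitution accuracy coincide here; the implementation computes plain
accuracy. Equal signature sizes per subtype are enforced structurally.

## Scoring and classification

**Rank-walk enrichment score.** Genes are ordered by decreasing expression
within each sample (ties by gene id). Walking the list, a member at
descending position j contributes `+(N−j)^α / W_ideal` with α = 0.25 and
`W_ideal = Σ_{j<k}(N−j)^α` the weight mass of the ideal placement (the set
occupying the top k ranks); non-members contribute `−1/(N−k)`. The score
is the mean of the running sum over all N positions. Normalizing by the
*ideal* mass rather than by the realized member mass is deliberate: with
realized-mass normalization, moving a member to a better rank enlarges the
normalizer and lowers the walk over the prefix, so the score is not
monotone in member rank — counterexamples arise readily at N ≈ 20. With
the fixed normalizer the score is strictly monotone under rank improvement,
is maximal exactly at the top-k placement, and reaches its analytic
maximum when the set is the whole gene list. Classification uses score
differences at equal set sizes, which this scale change does not affect.

**Module score.** Genes are cut into 25 equal-frequency bins of average
expression; each signature gene draws 100 seeded controls (with
replacement) from the non-signature genes of its bin, falling back to the
nearest non-empty bin; the score is mean signature expression minus mean
control expression per cell. Constant matrices score exactly zero.

**Decision rules.** Bulk quartile: samples ranked by
`Δ = score_LLI − score_BL`; the top ⌈N/4⌉ are LLI-like, the bottom ⌈N/4⌉
BL, the rest intermediate; rank ties break by unit id. Bulk sign: Δ > 0
LLI-like, Δ < 0 BL-like; Δ = 0 is left intermediate since both published
inequalities are strict. Single-cell rule: each class's threshold is the
q-quantile (default 0.75, linear interpolation) of that class's scores
across cells; a cell is labelled with the one class whose threshold it
meets exclusively, otherwise unidentified. The quantile level itself is
not pinned down by the source description; 0.75 mirrors the bulk quartile
usage. CAF typing takes the argmax of mean z-scored marker expression
(FN1 → myCAF, C3 → iCAF, CD74 → apCAF, SLC14A1 → IFN-CAF, PSCA → PSCA+
CAF); ties and all-zero cells are unassigned. M1/M2 polarization uses
module scores of the canonical marker sets; the per-sample ratio is
`#(M2 > M1) / #(M1 > M2)`, flagged when the denominator is zero.

## scATAC copy-number inference

The genome is tiled into 1 Mb half-open bins (terminal partial bins keep
their true length); per-bin GC comes from a FASTA, a table, or a callable.
Fragments whose midpoint falls inside an accessibility peak are discarded;
the rest land in the bin containing their midpoint (boundary midpoints go
to the right-hand bin). Density is fragments per effective kilobase,
where the effective window is bin length minus peak overlap; bins with
under 10 % effective window, or without GC, are masked. Each bin's
background is the mean density of the k = 100 unmasked bins closest in GC
(ties by genomic order), excluding the bin itself to avoid self-matching
bias. The fold change is `log2((c+ε)/(B+ε))` with ε = one fragment per
effective Mb, keeping sparse per-cell values finite. Coverage is
normalized by effective length before averaging into the background.
A flag excludes designated (e.g. sex) chromosomes.

Because the background is a *mean* over GC-matched bins, planted
copy-number segments contaminate it in proportion to the fraction of the
genome they occupy relative to the matched set. The synthetic genome is
therefore three 200 Mb chromosomes (600 bins): the k = 100 matched set is
~17 % of the genome, as it would be for a real genome binned at 1 Mb, and
the planted 30-bin gain (ratio 2) plus 30-bin loss (ratio 0.5) bias the
background by only ~0.04 in log2. On the defaults (1 M fragments,
pseudobulk) the planted segments are recovered as median log2 fold changes
within ±0.1 of ±1, and a genome with GC bias but no CNV stays within
|median| < 0.01 of flat.

## IHC image analysis

Images are converted to inverted grayscale (`255 − mean(R,G,B)`) so the
dark stain is high-valued, then thresholded by the moment-preserving
(Tsai) criterion on a 256-bin histogram: the first three gray-level
moments fix the two representative levels of an ideal bilevel image and
the fraction p₀ of low-level pixels; the threshold sits just above the
gray level whose cumulative fraction is closest to p₀ (ties toward the
lower level), and pixels at or above it are foreground. Hematoxylin
nuclei survive this threshold but are removed by the strict `B > R`
filter (DAB brown has R > B; ties keep the pixel). Distances from every
marker-positive pixel to the nearest vessel pixel are exact Euclidean,
center-to-center, via a distance transform verified against brute-force
scans; no sub-pixel contouring. Vessel outlines are an input mask —
no segmentation is attempted. Marker distance distributions are compared
per image with a two-sided Wilcoxon rank-sum test (exact enumeration when
both n ≤ 8 without cross-ties, tie-corrected normal approximation
otherwise); a per-tumor aggregation is the caller's choice. The H-score
is `3·%strong + 2·%moderate + %weak` ∈ [0, 300].

## Spatial co-occurrence

For annulus (r_i, r_{i+1}] the statistic is the frequency of the target
category among non-anchor points lying within that annulus of at least one
anchor, divided by the target's global frequency among non-anchor points.
Points count once per annulus (presence semantics — the conditional
probability reading); a pair-counting mode is available by flag. Default
radii are 10 log-spaced bins up to the 90th percentile of anchor-point
nearest distances. Empty annuli are flagged, never interpolated. Distance
units follow the coordinates and are caller-defined.

## Survival and association

Kaplan–Meier: `S(t) = Π_{t_i ≤ t}(1 − d_i/n_i)` over distinct event times,
right-continuous, with events processed before censorings at tied times.
Log-rank: observed minus expected events per group accumulated over event
times with the hypergeometric covariance; the statistic is the quadratic
form over k−1 groups against chi-square with k−1 df. Chi-square
association is Pearson's X² without continuity correction (Fisher's exact
available for 2×2); zero expected cells raise rather than silently
degrade. Cox regression is out of scope.

## Synthetic data: what it does and does not emulate

All generators draw from named child streams of a single seed and are
byte-reproducible. Key defaults (the study conditions for all tests):
6 samples per subtype; 2000 peaks and 1500 genes; 15 planted differential
peaks per subtype, each placed within ~1 kb of the TSS of its own planted
signature gene carrying the same planted log2FC of 6; NB dispersion
φ = 0.05; library-size factors uniform in [0.7, 1.3]; baseline means
log-normal around 50 counts.

Single-cell mixtures contain the three tumor states, five CAF subtypes,
M1/M2 macrophages and an unmarked population (200 cells each); marked
genes are elevated 2⁶-fold. Dropout is expression-dependent
(`rate · exp(−μ/median baseline)`, rate 0.3): highly induced markers are
rarely lost, which is both the empirical behavior of droplet data and a
necessary condition for single-gene marker typing to be informative.

Fragment sets place off-target fragments proportional to
copy ratio × GC bias × effective window (per-bin GC fixed from
Beta(20, 20); default bias 0.5 + GC), with 30 % of fragments on-target
inside peaks and barcodes spread over 200 cells. IHC images put one
marker's DAB blobs within 40 px of a vessel stripe and the other's beyond
120 px, over hematoxylin nuclei and Gaussian noise (σ = 8) on colors
chosen so the blue-red filter is exercised non-trivially. Spatial fields
put anchor (MP) cells in three Gaussian nests (σ = 30) — uniform anchors
at these densities would leave almost no point farther than the
attraction radius from some anchor, making planted attraction
undetectable — with the target placed within 50 units of random anchors
and other categories uniform. Survival times are exponential with an
LLI:BL hazard ratio of 3 on a baseline of 0.03/month, censored uniformly
over 72 months.

None of these distributional choices estimate the real cohorts: the
generators exist to give every estimator a known truth. Passing tests
demonstrate correctness of the computations and calibration under the
stated models — NB counts, exponential hazards, circular stain blobs,
isotropic spatial noise — not performance on FFPE chromatin data, real
droplet sparsity patterns, or scanner-calibrated stain color. Raw reads,
FASTQ, motif content and realistic fragment-length distributions are
deliberately not simulated.

## Known limitations

* The NB test uses unshrunken method-of-moments dispersions; at 2–3
  samples per group it loses power relative to shrinkage estimators,
  though its type-I error remains controlled in simulation.
* The CNV caller reports per-bin fold changes only — no segmentation or
  HMM smoothing — and the mean-based background inherits a small bias
  whenever altered bins are a non-negligible fraction of the GC-matched
  set.
* The single-cell quantile rule's threshold level and the kernel of the
  originally used gene-set-variation scoring are not pinned down by the
  source description; the rank-walk score reproduces the decision rules'
  behavior on score orderings, not any package's numeric values.
* PERMANOVA permutes labels freely; designs needing strata are not
  supported.
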