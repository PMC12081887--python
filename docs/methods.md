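# Methods

`hicstack` re-implements, as one tested pipeline, the analysis stack used
to characterize 3D chromatin organization in binned Hi-C data together
with its companion assays: matrix normalization, insulation/TAD calling,
A/B compartment analysis, two interaction-significance models, ROSE-style
super-enhancer identification, SSIM-based map comparison, GWAS-SNP-to-gene
linkage, and fuzzy clustering of developmental expression trajectories.
Every stage is exercised end-to-end on synthetic contact maps whose
structure is planted and recorded, so recovery and calibration are
measurable.

## The synthetic data model

One chromosome is simulated at a working resolution (10/25/40/100 kb).
Counts are Poisson draws around the composed intensity

    lambda_ij = L * f(|i-j|) * (1 + a*c_i*c_j) * T_ij * P_ij * b_i * b_j

with `f(d) ~ d^-alpha` (default alpha = 1, the typical cis-decay scaling),
`c_i` the +/-1 compartment sign, `a` the plaid amplitude (default 0.4),
`T_ij = tau` (default 2.5) when i and j share a TAD, `P_ij = phi` (default
5) at planted loop pixels with a one-bin shoulder ring at `phi/2`, and
`b_i` hidden multiplicative biases, log-uniform in [0.5, 2]. The intensity
is rescaled so its upper triangle sums to the library size (default 5e6
counts for a 20-Mb chromosome — the depth a several-hundred-million-pair
genome-wide library delivers to 20 Mb of cis contacts).

Structural choices that make the planted truth self-consistent:

- TAD segments (uniform 400 kb–1.2 Mb) tile the chromosome; compartment
  blocks are unions of consecutive TADs, so compartment transitions fall
  on domain boundaries, as they do in real chromatin. Without this
  alignment, plaid edges plant insulation valleys that no boundary label
  explains.
- Regulatory loops (SNP-anchor→promoter at fold 6, SE→promoter at fold 5)
  are intra-TAD, like the plain loops; distal regulatory contacts in real
  data are predominantly domain-internal.
- Planted loops keep a Chebyshev separation of more than 8 bins so that
  no two loops share a caller neighborhood and recovery scoring is
  unambiguous.
- H3K27ac: each super-enhancer locus carries 3–6 strong peaks within
  stitching range; typical-enhancer loci carry 1–4 weak peaks so that
  stitched typical enhancers populate the flat part of the ROSE ranking
  curve. Gene TSSs are kept out of SE cluster footprints (the promoter
  exclusion would otherwise dismember a planted cluster). CTCF peaks sit
  at domain boundaries over a uniform background.
- Expression: log2-FPKM = baseline + beta_comp·1[A] + beta_se·1[SE-linked]
  + beta_loop·(per-stage loop multiplier) + one of two stage-trend shapes
  + Gaussian noise (sd 0.5). The compartment profile switches halfway
  through the stages, with at least one block switching in each direction.
- GWAS SNPs: 60% of index SNPs sit in distal loop anchors of recorded
  target genes; decoys above the association threshold, duplicate
  positions, and LD proxies at r² in [0.5, 1] exercise filtering, dedupe,
  and expansion.

What the generator does **not** emulate: read-level artifacts, mappability
structure (masked bins arise only from sampling noise), sub-compartments,
nested/hierarchical TADs, trans contacts beyond a uniform background, and
correlated biological replicates. Passing recovery tests therefore show
the algorithms are correct and calibrated under the stated generative
model, not that they are robust to every pathology of real libraries.

## Normalization

Low-coverage filtering masks bins with zero marginals or marginals below
a quantile (default 0.02) of the nonzero marginals. ICE then equalizes
marginals by iterative correction (tolerance: coefficient of variation
< 1e-5, max 200 iterations), with multiplicative weights normalized to
mean 1 over unmasked bins; `balanced = raw * w_i * w_j`. Expected-by-
distance is the mean over unmasked pixels at each offset, counting stored
zeros; O/E divides by it, and the compartment correlation matrix is the
Pearson correlation between O/E rows over unmasked columns (non-finite
O/E pixels neutralized to 1).

## Insulation and TADs

The insulation score of bin b is the interquartile-trimmed mean of the
480 kb × 480 kb square linking the w bins left of b to the w bins right
of it (the bin's own row/column is excluded, so even a masked bin can be
scored). By default the square is first divided by the distance
expectation: on raw decaying values the IQR trim selects pixels by
distance rather than by outlier status, which both blunts valleys and
displaces their minima by 2–3 bins (verified on noise-free intensity
surfaces); the plain-signal variant remains available. Scores are
normalized per chromosome as log2(IS / mean IS). Boundaries are strict
local minima (leftmost bin of a tie plateau) whose prominence against the
nearest flanking maxima — with scored-segment endpoints admitted as
flanks — reaches delta (default 0.1, calibrated on synthetic maps; the
upstream tool's 0.01 applies to a different statistic). Unscored gaps of
up to two bins are bridged by interpolation first. TADs are the regions
between consecutive boundaries, closed by the scored span, with domains
under 400 kb dropped. The single-scale valley caller stands in for the
multi-scale q-value machinery of the reference tool; boundaries between
two sub-window (< 480 kb) domains are at the method's resolution limit
and account for most residual recovery misses.

## Compartments

Principal components of the mean-centered O/E correlation matrix are
computed by SVD (top 3). The component maximizing |Pearson r| against the
gene-density track is selected (ties to the lower index; below 0.1 the
profile is flagged unresolved) and oriented so that A = positive =
gene-dense. Per-bin dynamics across stages use one-way ANOVA on
replicate PC values with genome-wide Benjamini–Hochberg adjustment
(dynamic ⇔ q < 0.05). Compartment strength ranks bins into 5 quantiles by
the oriented PC and reports (AA + BB) / (2·AB) over the outer-quantile
corners of the saddle. The B→A expression test is a one-sided Wilcoxon
rank-sum of per-gene log2-FPKM changes in switched bins against all genes.

## Interaction calling

**NB loop candidates.** Distances are pooled into bands of ≥ 200 pixels.
The naive recipe — one NB per distance fitted to balanced values, every
pixel tested against it — fails on structured maps in both directions:
domain-elevated pixels look focal, genuine peaks drown in the mixture's
fitted dispersion, and ICE weight products turn single-digit counts into
extreme "balanced" values. The implemented test therefore (i) forms a
per-pixel expectation as the most elevated of the four local quadrant-
block means on the O/E surface (floored at the genome-wide O/E of 1, and
rescaled by the distance expectation) — quadrants, rather than a ring,
so a domain corner cannot average its own background down; (ii) converts
both observation and expectation to the raw count scale with the pixel's
balancing weights, keeping the discreteness of the data in the tail
probability; and (iii) uses the band's residual overdispersion as the NB
size (Poisson in the limit). Candidates (p < alpha, default 0.05) pass a
neighborhood comparison: per (2w+1)² window only the highest-observed
candidate survives, and it must exceed twice its neighborhood's trimmed
mean with its 3×3 shoulder itself 1.2-fold elevated — a real contact peak
spreads into adjacent pixels; a lone extreme count does not. A parameter
sweep (default alpha {1e-4, 1e-4, 1e-5} × windows {5, 2, 2}) is merged by
collapsing calls within 1 bin to the smallest p. The stricter sweep
thresholds carry the precision that the reference tool obtains from
neighborhood significance tests not reproduced here.

**Weibull significant interactions.** Per distance band, zero contacts
are removed and values above the 95th percentile are trimmed so focal
signal does not inflate the background; the trimmed count enters the
likelihood as right-censored mass (fitting the trimmed sample as if
complete compresses the fitted tail about four-fold). Shape and scale
are obtained by profile-likelihood root-finding to near machine
precision. A pixel is significant when its upper-tail probability falls
below 1e-4 (no multiplicity gate; BH q-values reported alongside). An
anchor argument restricts the test to one bin's row — virtual 4C.

Known limitation, measured rather than hidden: on Poisson decay-only
nulls the Weibull caller's significant fraction is ≈ 2×10⁻³, about 20×
the nominal 10⁻⁴. Zero-truncated low-count strata are heavier-tailed
than any Weibull fitted to their bulk, while high-count strata fit shapes
k ≫ 3.6 whose compressed right tails sit below the Poisson quantiles —
the model family is not tail-calibrated on count data at this depth. The
corresponding calibration test is left failing with the measured value.
Downstream consumers therefore demand minimal contact support: a
SNP→gene or SE→gene link requires the supporting interaction to rest on
≥ 5 raw contacts with ≥ 2-fold O/E enrichment, which removes the residual
false calls (all single-digit-count pixels on high-weight bins).

## Super-enhancers

Peaks fully inside TSS ± 2.5 kb are excluded (the source text prints
"+/−2500 kb", inconsistent with the promoter exclusion of the cited
method; 2.5 kb is used and the flank is configurable), the rest are
stitched at ≤ 12.5 kb gaps, and regions need > 2 constituents. Regions
are ranked by total signal; both axes are rescaled to the unit square and
the cutoff is the point minimizing the number of points below the
slope-1 line through it (the hockey-stick tangent); SEs are regions
above the cutoff. Specificity uses reciprocal overlap < 0.3 against every
other group. SE–gene pairs require a significant interaction between a
region bin and a promoter bin (self-bin pairs excluded; multi-gene
promoter bins flagged ambiguous). Cis SE–SE enrichment compares per-pair
O/E within 2.5 Mb (beyond a few Mb single-pixel O/E is shot noise at this
depth) to distance-matched TE pairs; trans enrichment is the SE-bin
contact rate over the uniform expectation on an inter-chromosomal
background, with a one-sided Wilcoxon for cis > trans.

## Map comparison (SSIM)

Two O/E windows are compared as S = l·c·s with the standard luminance /
contrast / structure terms. Stabilizing constants are C1 = C2 =
(0.01·D)² with D the windows' dynamic range, C3 = C2/2, exponents 1 —
the source gives none. |S| ≤ 1 holds analytically and the implementation
clips last-ulp float excursions; identical windows score exactly 1.
Unequal windows are bilinearly rescaled to a common size. The genome scan
tiles 2-Mb windows at 500-kb steps (25-kb bins), z-scores each window
against all windows of the comparison, and reports a left-tail empirical
rank probability (suppressed under 10 windows) — an empirical
significance, not the cited tool's null. Windows with > 30% undefined
pixels are skipped; lesser gaps are imputed at the O/E-neutral value 1.
Dissimilar regions are merged windows with z ≤ −2.

## SNP linkage

Index SNPs pass p ≤ 1e-6; LD proxies at r² ≥ 0.8 come from a supplied
table (the original study queried a web service; no external lookups);
duplicates collapse by position keeping the smallest p, with index
records outranking proxies. A SNP links to a gene when its 10-kb bin has
a significant, support-filtered interaction with the gene's promoter bin
in a sample; same-bin pairs are never linked (the diagonal is not
interaction evidence). Nearest-TSS annotation is provided separately for
comparison. Per-trait gene sets union over regions; pairwise and k-way
intersections and exclusive counts are reported.

## Expression dynamics

Genes below 0.5 FPKM in every stage are dropped. Stage-mean profiles are
log2-transformed and z-scored per gene, then clustered with fuzzy
c-means (fuzzifier m = 2, convergence at centroid shift < 1e-6, seeded
initialization); memberships are row-stochastic by construction. Genes
with maximum membership strictly above 0.5 are the confident members. The
cluster count can be chosen by a minimum-centroid-separation screen over
c ∈ 2..12 (> 0.5 z-units).

## Problem sizes and verification

Recovery and calibration run on 20-Mb synthetic chromosomes (500 bins at
40 kb, 2 000 at 10 kb, 200 at 100 kb), pooling three generator seeds for
stochastic proportions; calibration nulls pool five seeds. Measured under
those conditions: ICE marginal CV < 1e-5 with log-weight/−log-bias
Pearson ≈ 0.99; boundary recovery ≈ 0.93 recall / 0.96 precision within
±1 bin; compartment label agreement ≥ 0.98 with strength increasing in
the plaid amplitude; loop recovery ≈ 0.93 recall / 0.96 precision after
the sweep merge; SNP-link recovery ≈ 1.0 recall / 0.96 precision with a
permuted-interaction negative control at zero; trajectory clustering
adjusted Rand ≈ 0.99 under the trajectory-dominant configuration. The NB
caller is conservative on Poisson nulls (candidate fraction 0.020 at
alpha 0.05); the Weibull caller's null miscalibration is quantified
above.
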