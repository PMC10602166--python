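# Methods notes

This note records the models behind each pipeline stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED). Overlap means ≥1 shared base;
intervals that merely touch do not overlap, do not merge, and a variant at a
peak's end coordinate is outside the peak. Variant positions in input tables
are 1-based and converted internally to 1-bp half-open intervals
[pos−1, pos). The overlap counter works per chromosome with two sorted
binary searches per query (fragments entirely left of and entirely right of
the query are disjoint sets, so the overlap count is the complement); it is
checked exhaustively against an O(n·m) pairwise oracle in the tests.

## Barcode QC

ATAC barcodes pass with HQAA ≥ 5,000, TSS enrichment in [3, 20] (both ends
inclusive) and ≤15% of reads on any single autosome. RNA barcodes need
≥1,000 UMIs and %-mito strictly below a per-library threshold. That
threshold is the knee of the ascending %-mito rank curve: both axes are
rescaled to [0, 1] and the knee is the rank of maximum perpendicular
distance to the chord between the endpoints. This extremum-distance
estimator is unit-invariant (invariant to affine rescaling of either axis);
it is one member of the knee-detection family and is documented here as an
approximation — other members can pick a neighboring rank on noisy curves.
A curve that coincides with its chord has no interior knee; the top endpoint
value is returned. Constant input returns the constant with a warning.

## Reproducible peaks

Summits are extended ±150 bp (length 301, clipped at chromosome starts). A
primary extended summit is kept iff it overlaps extended summits from
≥`min_libraries` (default 2) *distinct* libraries — multiple summits in one
library count once, duplicates collapse — and overlaps no blacklist
interval. "Broad peaks" for the locus filter are the merged union of a cell
type's reproducible extended summits; the broad-peak dialect is not further
specified upstream of this package, so the merged-union operationalization
is a documented choice. Output is monotone in `min_libraries` by
construction.

## Effect-size DARs

Rationale: pseudo-bulk fold-change estimates blow up at low coverage, and
p-value-based calling is unstable with few libraries per condition.
Features are therefore compared only within bins of matched mean
accessibility. Defaults: mean-reads floor 3; |log2FC| > 10 removed (read as
absolute — artifactual fold-changes occur in both directions at low
coverage); 50 equal-width bins over the post-filter mean range, left-closed
right-open with a closed last bin, boundary values going right; percentile
thresholds are linear-interpolation quantiles of each bin's |log2FC| with
inclusive (≥) flagging, so ties flag together and flag sets nest (99 ⊆ 95 ⊆
… ⊆ 80). Bins with <2 features get no flags. A shrunken estimator
log2((m_A+0.5)/(m_B+0.5)) on library-size-normalized means is provided for
users without an upstream model fit; any externally estimated log2FC table
is accepted.

## PPA-weighted locus scores

Depth normalization is reads-per-million of the cell type's pass-QC
fragments — RPM is the natural choice where only "normalized by sequencing
depth" is specified, and it makes raw scores invariant to uniform
subsampling. Weighting by PPA and normalizing by depth commute, so the
order is fixed only for clarity. Merged regions carry the *maximum* member
PPA (not the sum), exactly as specified upstream; when a merged region
spans several variants this deliberately counts the region's signal once at
the top PPA. Z-scores use the sample SD (n−1); degenerate rows (all cell
types equal, SD 0) are emitted as zeros and flagged rather than dropped, so
the locus × cell-type matrix stays rectangular. Attribution sorts cell
types by Z and labels the top "specific" at a ≥1.0 Z-unit lead by default —
one sample SD across cell types, a deliberately conservative margin.

## Enrichment model and fine-mapping

The model is the standard hierarchical one-causal-per-window form: window
*w* harbors an association with probability π, and conditional on
association, variant *i* is causal with prior softmax_w(γ·x_i); marginal
window likelihood (1−π) + π·Σ_i softmax_w(γ·x_i)·ABF_i. Evidence is the
Wakefield ABF with prior effect variance W = 0.04 (prior SD 0.2 on the
log-odds scale, a conventional default for binary-trait GWAS). π and γ are
estimated jointly by L-BFGS-B on (logit π, γ) with bounds (±10, ±20), from
5 deterministic starts (one at zero, four standard-normal); all window sums
are computed in log space (segmented log-sum-exp) so very large |z| cannot
overflow. No cross-validated penalty is applied at this scale. Windows of
≤5,000 variants are built per chromosome (hard boundaries): each lead
variant gets ⌊w/2⌋ variants on each side, truncated at chromosome ends;
overlapping lead windows are truncated at the midpoint between their leads;
remaining stretches are chunked consecutively, shortening chunks that
straddle lead windows, so windows always partition the variants.
Reweighted PPAs are softmax_w(γ·x_i)·ABF_i renormalized per window
(conditional on association), invariant to adding a constant to γ·x. The
99% credible set is the smallest PPA-descending prefix reaching 0.99, ties
broken by genomic position.

## Allelic imbalance

p₀ (residual reference bias after remapping-based correction) is the pooled
ref fraction over all heterozygous sites, per cell type when labels are
provided. Each site with ≥10 reads (a coverage floor; "enough coverage" is
not quantified upstream) gets an exact binomial test of the ref count
against p₀, two-sided by the minimum-likelihood rule — sum of probabilities
of all outcomes no more likely than the observed one, with a 1+1e−7
relative tie tolerance matching the common convention — with
tail-doubling available by flag. Eligibility for the concordance comparison
uses BH FDR < 0.05 across tested sites (the upstream multiple-testing rule
is unstated; raw-p mode is available). A site agrees when
sign(alt fraction − (1−p₀)) matches the sign of the predicted alt-minus-ref
effect; the agreement fraction is tested against 0.5 with an exact binomial
test.

## Bound motifs and f-VICE

Per motif, negative binomials are fit by maximum likelihood (mean profiled
out as the sample mean, dispersion by bounded 1-D optimization from a
method-of-moments start; Poisson fallback when variance ≤ mean) to the
per-instance ATAC fragment count and to the count of same-motif instances
within 100 bp edge-to-edge (inclusive). Upper-tail p-values P(X ≥ x) are
combined by Fisher's method (χ², 4 df) and instances with BH-adjusted
combined p < 0.05 are called bound. Because the NBs describe the unbound
background but must initially be fit to all instances, one refinement round
refits them on the instances not called bound and re-scores (a one-step
contamination trim; `refine=0` disables it). Requires ≥100 instances per
motif.

Bound sites are deduplicated greedily in descending ATAC-count order
(ties by position), keeping centers >500 bp apart. The V-plot accumulates
fragment midpoints (⌊(s+e)/2⌋) at offsets within ±100 bp of site centers,
sign-flipped at minus-strand motifs. f-VICE is operationalized as
log₂((O+1)/(E+1)) where O is the midpoint count at TF-adjacent ([−25, 25])
plus TF-proximal ([−70, −50] ∪ [50, 70]) offsets — 93 of the 201 offsets,
both window ends inclusive — and E the mean of that count over 100 uniform
multinomial redistributions of the same total. This log-observed-over-
shuffled-expected functional is an approximation to the original chromatin-
information score, which is defined in its own publication; the shuffle
null, window definitions and log₂ form follow the published description.
Raw f-VICE is residualized by OLS on log₁₀(total fragments + 1) and
log₁₀(total co-occurring motifs + 1). Cross-condition comparison
Z-transforms the residuals within each donor × condition, takes per-motif
medians across donors, and (for display) Z-scales each motif row across
conditions, with constant rows set to 0.

## Synthetic data

One RNG stream per output role, derived from the master seed by CRC-32
hashing of the role name, so outputs are individually stable when new
outputs are added; identical seed and configuration give byte-identical
files. Defaults describe a deliberately small but realistic regime: one
10-Mb chromosome; 5 cell types × 3 libraries; 100,000 fragments per cell
type (exactly — depth is conserved); 301-bp peaks; 60% of fragments in
peaks (typical of a good ATAC library), the rest uniform background;
fragment lengths a 60/40 mixture of sub-nucleosomal (N(80, 15²)) and
mono-nucleosomal (N(200, 30²)) clipped to [30, 500], chosen to make V-plots
realistic; per-library summits jittered ±20 bp with 10% dropout.

Credible-set loci place their top-PPA variant (PPA 0.6, or 1.0 for
single-variant loci) at the center of a peak private to the causal cell
type, with up to 19 satellite variants sharing the remaining mass
(per-locus ΣPPA ≤ 1); shared background peaks appear in every cell type so
they cannot bias attribution. GWAS windows use π = 0.3, γ = 1.5 on one
Bernoulli(0.2) annotation, true effects N(0, 0.04) — matching the ABF prior
W, so the evidence model is well specified — and standard errors
U(0.025, 0.035), giving causal |z| frequently above 6 (high power).
Allelic sites use p₀ = 0.53, Poisson(50) coverage, a 2.0 log-odds ALT-side
shift at effect sites and predictions sign-matched to truth 90% of the
time. Footprint simulation draws per-site counts NB(r = 5; mean 30 bound /
3 unbound) and bound-site midpoints from a 0.95/0.05 mixture of a
structured component wholly inside the A∪P windows (60% tight N(0, 10²)
clipped to ±25, 40% phased at ±60 ± 4 clipped to the proximal bands) and a
uniform floor; 0.95 was set analytically so a fully bound motif's expected
f-VICE is log₂((0.95 + 0.05·93/201)/(93/201)) ≈ 1.07, i.e. a clearly phased
pattern, while unbound motifs score ≈ 0.

Not emulated: raw reads, barcode-level sparsity, doublets, ambient
contamination, LD between variants (one causal, independent errors),
mappability structure, or sequence content (the predicted allelic-effect
score is drawn, not computed from sequence). Passing tests therefore show
correctness of the statistical machinery under the stated generative
assumptions, not robustness to those real-data complications.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: 20 loci × 5 cell types ×
3 seeds for attribution recovery; 500 windows × 50 variants × 3 seeds for
enrichment recovery; 10⁵ simulated sites for exact-test calibration;
5 × 10⁴ features for DAR calibration; 2,000 instances × 5 seeds for
bound-motif recovery; 10 motifs × 150 sites for f-VICE discrimination.
Exact identities (overlap counts, binomial p-values, OLS identities, Z-row
identities) are asserted to 1e−9–1e−12; stochastic recoveries at the
binomial/simulation tolerances stated in each test. Degenerate inputs are
handled explicitly throughout: empty interval sets, constant Z rows,
single-bin DAR input, zero-coverage sites, empty V-plots, and
under-dispersed counts each have a defined behavior (empty output, zeros
with a flag, warning, error) rather than an implicit one.
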