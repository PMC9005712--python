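# Methods

This note documents the models, estimators and numerical choices behind
`rablhic`, and what the synthetic benchmark does and does not establish.

## Contact-map model and balancing

A genome is held as one dense symmetric matrix over fixed-width bins
(0-based half-open coordinates; bin index = ⌊pos / bin_size⌋). Matrices are
balanced by iterative correction: per-bin multipliers `w` are iterated until
all good-bin row sums of `w_i w_j C_ij` agree to a relative tolerance
(default 1e-8). This shares its fixed point — equal row sums — with KR
balancing up to a global scale; we use the iterative form for robustness.
Bad bins are zero-coverage bins plus the lowest 2% of the nonzero-coverage
distribution by default (`bad_bin_cov_frac`, configurable). On synthetic
Poisson maps there are no dead bins and the coverage filter would
preferentially mask TAD-boundary bins (the genuinely lowest-coverage bins),
so the benchmark analyses balance with `bad_bin_cov_frac = 0`.

The expected model is the mean balanced count per bin separation, computed
per chromosome and pooled genome-wide weighted by pair counts; the trans
expectation is the mean over good trans pixels. O/E divides each pixel by
its expectation.

## Compartments: cePC1 and baselines

Pipeline: O/E → neighborhood smoothing (default 1 bin at 25 kb) → Pearson
correlation of rows → block normalization → leading eigenvector, with the
sign fixed per chromosome against an orientation track (gene density by
default; A is the gene-dense, expressed compartment, `cePC1 > 0`).

Block normalization is the step that makes the method work on
Rabl-configured chromosomes: the correlation matrix is re-scaled within
~1 Mb windows, flattening the slow positional structure contributed by
centromere/telomere clusters and inter-arm wings while preserving the local
checkerboard contrast. Two variants are provided:

- `contrast_enhance`: tiled min–max stretch of each `block_bins × block_bins`
  block to [−1, 1] (constant blocks map to 0; result re-symmetrized). This is
  the literal image-contrast operation and is what the name refers to.
- `contrast_enhance_sliding` (pipeline default, window 40 bins = 1 Mb):
  per-entry z-score against its local window. Tile boundaries that straddle
  the edge of a cluster block leave step artifacts in the tiled variant that
  misclassify centromere/telomere-proximal bins; the sliding form removes
  them and is strictly a smoother version of the same normalization.

Baselines: `default` (eigenvector of the O/E correlation matrix), `cropped`
(drop annotated regions before PCA), `framed` (independent PC1 per 10 Mb
frame). Label accuracy against truth treats the eigenvector sign per the
orientation track; bins with missing eigenvector entries are uncalled.

## Insulation and TADs

Diamond insulation: per bin, the log2 mean balanced contact in the `w × w`
square spanning the bin (default windows 50/100/150 kb at 5 kb bins,
averaged — averaging over windows stabilizes boundary localization when TAD
sizes range from a few to dozens of bins), relative to the chromosome-mean
diamond. Normalization subtracts the mean raw score within a ±1 Mb frame
around each bin, removing megabase-scale trends; the subtraction is exact
(residual 0 at every full-frame bin). Note the frame means of the
*normalized* track are small but not zero — no single-pass subtraction can
zero them — which is why the contract is stated on the subtraction residual.

Boundaries are local minima of the normalized track whose delta — the mean
of the two flanking local maxima minus the minimum — reaches 0.05
(hicExplorer-like contract; bit-exact reproduction of hicExplorer is a
non-goal). Minima closer than the separation floor keep the deeper one.
TADs are the half-open intervals between consecutive boundaries; intervals
under 15 kb are discarded. Boundary recovery is scored within ±1 bin and,
on synthetic maps, restricted to boundaries inside the insulation track's
support (a caller cannot recover a boundary inside the window-edge zone).

## Contact scaling P(s)

P(s) is the mean balanced count per logarithmic distance bin (10 per
decade), pooled over chromosomes weighted by pair counts and normalized to
sum 1; separations under 2 bins are excluded. Each bin's abscissa is the
realized pair-weighted mean log distance, not the geometric edge midpoint —
this removes the discreteness bias at short range and the truncation bias
near the chromosome length. The slope is a centered finite difference of
log10 P against log10 s, optionally smoothed by a running mean.

Phase detection: the phase-I feature is the slope minimum below a search
bound (default 1 Mb — the phase boundary is genome-scale dependent); the
phase-II feature is the subsequent local slope maximum; the drop is the
first distance beyond it with slope < −1. On maps without TAD enrichment
the phase-I dip vanishes, which is the diagnostic that the slope minimum
measures the characteristic TAD length.

Balancing note: iterative correction up-weights chromosome ends (fewer
near-diagonal neighbors), which flattens the P(s) tail at separations within
a factor of ~2 of the chromosome length. Generator-recovery analyses
therefore run on unit-weight maps; on real data this edge effect is shared
with any balanced-map P(s).

## Synteny, breakpoints and lineage classification

Alignment blocks (reference A vs species B) merge under four rules: both
blocks same A orientation; same B orientation; both gaps < 150 kb; gap
difference < 100 kb. Merging runs to a fixed point; blocks shorter than
15 kb are then dropped. Because dropping a short block can expose a newly
mergeable adjacency, merge and filter alternate until jointly stable, making
the whole operation idempotent.

An EBR is a reference adjacency whose B-side neighbors are not contiguous in
compatible order/orientation (`b_gap_max` tolerance, default 0 for exact
simulated homology); its interval is the inter-block gap and its position
the gap midpoint. EBRs from all reference-vs-X comparisons are clustered
within 25 kb (one compartment bin) and each cluster is assigned by parsimony:
a single event on branch `b` is visible in comparison (ref, X) exactly when
one of {ref, X} descends from `b`, so the observed presence pattern selects
the branch. Terminal branches are labeled by species abbreviation + `*`,
internal branches by ingroup clade size + `A*`. The two branches flanking
the root imply identical patterns (they are one edge of the unrooted tree);
the tie-break names the smaller clade. Patterns explained only by the union
of two non-nested branches are `reused^`; anything else is `unassigned`.

Ancestral states at a junction are read in the closest species retaining the
ancestral segment order: the reference itself when the causative branch lies
outside its lineage, otherwise the phylogenetically nearest leaf outside the
event clade. Loci 1 and 4 are the newly joined ends, 2 and 3 their ancestral
neighbors; all four are read from that species' cePC1 track. The switch test
compares the observed fraction of junctions joining unlike compartments
(locus 1 vs 4) with a null of randomly re-paired ends (seeded permutations;
two-sided p centered on the null mean).

Matched randomization draws control bins whose feature-value histogram
matches the target regions' histogram over 10 equal-count bins of the target
distribution (tied values collapse bins, with quotas proportional to target
mass); quotas are exact up to rounding, so the control matches the target
distribution by construction and any residual difference is within-bin.

## Loops and Rabl quantification

Anchor scoring is percentile-based within log-distance classes (0.25
decades): an anchor rectangle's mean O/E is ranked against all same-size
windows at comparable separation (all trans windows for trans pairs).
Automated calling additionally requires a minimum O/E fold (default 2;
a percentile cut alone always selects a fixed top fraction) and a
Bonferroni-corrected Poisson test of the raw count against its distance
expectation scaled by the local (11×11) O/E background — the local scaling
absorbs compartment-plaid overdispersion, and the significance gate is what
keeps loop-free maps at zero calls where single-read noise dominates
long-range pixels. Called pixels within 2 bins merge into anchors;
connected anchors form networks.

Rabl estimators: the equidistant inter-arm enrichment is the mean inter-arm
contact among pairs with |d1 − d2| ≤ 25 kb (d = distance to centromere)
over a control matched on the d1 marginal and restricted to
|d1 − d2| ≥ 750 kb so the wing's shoulder stays out of the baseline;
bins within 1 Mb of a centromere or telomere are excluded so cluster blocks
do not leak in. Centromere/telomere clustering is the mean trans contact of
cen–cen / tel–tel / cen–tel blocks over the mean of trans pixels outside all
annotated blocks. Both estimators run on raw counts: balancing partially
absorbs cluster enrichment into the weights and would bias them low.
Because cen–cen pairs are equidistant by construction, the wing and cluster
multipliers overlap on the same pixels; estimator validation therefore runs
each on maps where only its own term is active.

## The synthetic generator

The generator is statistical, not polymer-physical: each pixel's expectation
is an explicit product — two-phase power-law decay (exponent −0.8 steepening
to −1.5 beyond 3 Mb, continuous at the break) × compartment plaid
(alternating ~0.5 Mb segments, like-label affinity 1.5, attenuated with
distance on a 6 Mb scale) × TAD blocks (~150 kb, enrichment 3) × Rabl terms
(inter-arm wing `1 + (r−1)·exp(−|d1−d2|/250 kb)` with r = 2;
centromere/telomere cluster blocks of 1 Mb at 3×) × injected loops — and
counts are independent Poisson draws around it (mean 300 at one-bin
separation for 25 kb maps, a deep-library regime consistent with data that
supports 5 kb TAD calling). Chromosomes are metacentric so the Rabl terms
act in cis (inter-arm) as well as in trans. The trans baseline is set from
the realized mean cis expectation so the pooled cis/trans ratio equals its
parameter (5) when the Rabl multipliers are off; with them on, the realized
ratio is slightly lower.

The plaid attenuation and megabase-scale cluster blocks are what make the
benchmark faithful to the Rabl regime: with a constant-affinity plaid the
default eigenvector trivially succeeds and the phenomenon cePC1 addresses
cannot be studied. Tracks (gene density, expression, GC) are Gamma-distributed
per bin with A/B mean ratios 2 / 3 / 1.05 and CV 0.35.

Rearrangement histories evolve a segmented genome (3 chromosomes × 40
segments, ~0.5 Mb exponential lengths) along a five-taxon ultrametric tree,
with per-branch inversion/transposition/translocation events
(inversion-dominated by default; inversions keep one segment on each side so
both junctions are internal). Genomes at every internal node are recorded,
so replaying any leaf's history reproduces it exactly and every breakpoint
is attributable to its branch.

What the generator does **not** emulate: polymer physics (no loop extrusion,
no distance-dependent correlations between pixels — counts are independent),
mappability/repeat structure (no systematic coverage bias, hence the
zero-filter balancing choice above), trans compartmentalization, sequence
evolution within segments, and overlapping/nested rearrangement breakpoints
sharing a junction by descent rather than by chance. Passing the benchmark
therefore shows estimator correctness under the declared statistical
structure, not robustness to artifacts absent from it.

## Problem sizes and determinism

Benchmarks use 50 Mb genomes at 25 kb bins (2000 bins) for compartment,
loop and Rabl analyses; 5 Mb at 5 kb bins for insulation; 25 Mb at 25 kb
for scaling; 20-seed replicate sets where a distributional claim is made.
Every stochastic routine takes an explicit seed; identical configuration and
seed reproduce outputs byte-for-byte (the pipeline manifest records sha256
checksums).
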