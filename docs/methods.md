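# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-study generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## The analysis chain

The package links four data streams collected at the territory scale:
nestling diet from COI metabarcoding of fecal samples; arthropod
availability from repeated, stratified field sampling of habitat elements;
vegetation percent cover per territory; and one season of nesting outcomes.
The chain runs diet profiling → length–biomass conversion → habitat-element
marginal means → cover-weighted territory upscaling → composition
statistics → performance links, and each stage is usable on its own.

## Taxonomy assignment

An OTU's candidate matches each carry a four-rank path (order, family,
genus, species) and a percent similarity. The best similarity caps the
deepest assignable rank at the published operating points 99.3 / 94.9 / 91 /
85.9 percent for species / genus / family / order. Comparisons are
**inclusive** (s ≥ cutoff): the cutoffs are operating points, and a match
sitting exactly on one is taken to satisfy it. When several candidates tie
at the best similarity (within 1e-9) with conflicting taxonomy, the OTU is
resolved to the deepest rank on which all tied candidates agree (lowest
common ancestor), further capped by the threshold rank; a tie conflicting
even at order level is excluded. Candidates with incomplete paths cap
resolution at their deepest known rank. Override rules encode regional
knowledge (a family with a single locally occurring species is promoted to
that species) and run last. OTUs unresolved at order level are excluded
from all diet metrics with their count logged.

Two properties are enforced by tests: raising the similarity of the
best-tied candidates never lowers the resolved rank, and the resolved path
is an ancestor of every tied candidate.

## Diet metrics and prey designation

Frequency of occurrence uses as denominator the samples with detectable
arthropod DNA, not all collected samples — FO answers "given a readable
diet sample, how often is this order present". Relative read abundance is
the mean over positive samples of the order's share of retained reads;
per-sample RRA vectors sum to one over detected orders. "More than one
sample" is read strictly: an order must appear in ≥ 2 positive samples to
be a prey taxon; single-occurrence orders are listed with the reason for
exclusion. FO and prey designation are invariant to rescaling read counts
within samples; RRA is invariant to total-read rescaling per sample. FO
ties in report ordering break alphabetically.

## Length–biomass conversion

Mass follows mass_mg = a·L^b per order (suborder for Hemiptera:
Heteroptera, Auchenorrhyncha, Sternorrhyncha). The packaged registry holds
editable literature-style defaults so the pipeline runs out of the box;
they are deliberately not presented as authoritative, and the test suite
uses synthetic coefficients only. Five rare taxa (Raphidoptera,
Archaeognatha, Pseudoscorpionida, Ephemeroptera, Siphonaptera) have no
registry entries by design and return a no-estimate sentinel rather than a
guessed mass. Hymenoptera records without a species flag are attributed to
the invasive Argentine ant at the observed 0.95 fraction.

Aggregation order is fixed: sum record masses within
(territory × block × time × element × stratum × taxon) cells, zero-fill
taxa absent from otherwise-sampled units, average over spatial blocks, then
total over time blocks. An element missing from a block is missing — it is
excluded from the block mean, never imputed as zero. The default time
reduction sums all five time blocks (both field seasons); a per-year or
mean reduction is exposed because the original design is ambiguous on this
point. Aggregation is additive, order-invariant, and invariant to splitting
a count-k record into k singletons.

## Marginal means

The estimator contract is the balanced-design equivalence: under the full
habitat-element × territory interaction structure, model-adjusted means
equal arithmetic cell means of the (log1p-transformed) response across
block × time replicates, and that cell-mean estimator is what
`marginal_means` computes (with SEs from the replicate spread). An optional
mixed-model refit (`mixed_model_means`) adds a random time-block intercept
and drops it when its estimated variance is ~0, matching the common
field-analysis workflow; on balanced data it reproduces the cell means, and
only that case is asserted. The log1p scale is used for hypothesis-test
refits; territory upscaling consumes raw-scale block means, and both scales
are exposed.

## Composition statistics

Bray–Curtis, PERMANOVA and PCA are implemented directly from their
definitions (they are the analytical core of the availability comparison);
scipy and scikit-bio serve as independent cross-checks in the test suite.
PERMANOVA uses Anderson's partition of squared inter-point distances with
unrestricted row permutations, 999 permutations by default, upper-tail
p = (#{F* ≥ F} + 1)/(n+1) from a seeded generator. The PCA is
column-centered but unscaled — relative biomasses share a scale — and axis
signs are fixed so each axis's largest-magnitude loading is positive, which
makes loadings interpretable across reruns.

## Territory upscaling

availability = Σ_elements (cover%/100) × element mean biomass × 31,416 m²,
the area of the 100 m nest-centered buffer. Bare ground is a focal element
with its own sampled biomass; non-focal cover (other vegetation,
artificial surfaces) contributes zero and its percentage is reported rather
than imputed. Covers are consumed as proportions of total mapped area with
no renormalization to focal-only cover. The conversion assumes equal
sampling effort per unit covered area across elements, which is crude for
structurally dissimilar elements and is flagged as such. Hymenoptera is an
independent predictor axis and never enters the prey total, even when the
diet occasionally detects it.

## Performance links

Summaries report mean ± SE (sample SD, n−1, over √n) across territories.
Clutch size is the mean of per-territory eggs/attempts ratios — this
reading reproduces the season's printed 3.3 — with the pooled ratio
(total eggs / total attempts, here 3.40) also reported. For links, first
egg date (gaussian) uses the Pearson test plus a simple linear fit; the
fledgling count uses a Poisson log-link GLM with a Wald test, resolving the
ambiguity of applying a normality-motivated transform to counts by exposing
both families. Heavy-tailed invasive-arthropod totals may be
log-transformed on the predictor side. p-values are two-sided and
uncorrected across the handful of territory-level tests, which the result
object carries as an explicit caveat: with n = 8 territories these are
hypothesis-generating analyses. Rank discordance uses Spearman's rho with
midranks, and is therefore invariant to monotone transforms of either
input.

## The synthetic-study generator

Defaults mirror the study design: 3 sites holding 8 territories (3+2+3),
2 spatial blocks per territory, 9 habitat elements (8 dominant plants plus
bare ground), canopy and ground strata, and 5 time blocks. Counts are
negative-binomial (size 0.6 — field arthropod counts are strongly
overdispersed; Poisson is the `dispersion=None` special case) around an
intensity matrix shaped to the system's qualitative pattern: invasive ants
numerically dominant in both strata, Hemiptera abundant in canopies,
caterpillars concentrated on *Eriogonum* and *Sambucus*, isopods and
beetles on the ground beneath shrubs, orthopterans in grasses. Body
lengths are lognormal with order-typical medians (ants ~2.8 mm to
orthopterans ~12 mm, log-SD 0.45). Cover is Dirichlet over the nine
elements plus an "other" category with concentration 60 and means matching
the observed cover pattern (non-native grass most common; ~9% non-focal).
Diet samples amplify with probability 0.45 (the observed fraction of
readable samples); within an amplified sample each order is detected
independently with probabilities set to the observed FO spectrum (Diptera
0.89 down to Hymenoptera 0.036), detected orders carry 1 + Poisson(0.8)
OTUs, and reads split multinomially with every detected OTU keeping at
least one read — so profile FO converges to the detection probabilities by
construction. Unidentifiable sequences enter as sub-threshold OTUs of a
non-focal lineage, exercising the exclusion path without biasing FO.

First egg date = 100 − effect·z(latent Lepidoptera relative availability) +
N(0, 12²) days, with the nominal effect 20 days/SD chosen so the availability
signal explains most but not all of the among-territory date variance (the
observed dates span Julian 52–130). The latent is deterministic given each
territory's realized cover (expected counts weighted by cover fractions),
so the truth record is exact. Fledglings are Poisson with
log λ = 1.0 − 0.015·(date − 100), i.e. ~2.7 fledglings at the mean date and
fewer for late breeders; attempts, eggs and successful clutches are drawn
with the recorded invariants enforced. One `default_rng(seed)` stream
drives everything in a fixed order, so equal seeds give byte-identical
bundles.

The generator does **not** emulate spatial autocorrelation, phenology
beyond discrete time blocks, sequence-level error, within-order taxonomic
structure of the arthropod community, or territory-specific diet sampling
intensity (samples attach to territories uniformly). Passing tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to the full messiness of field
data.

## Numerical conventions and problem sizes

Similarity ties use a 1e-9 tolerance; cover-row sums are validated to ±1
percentage point (field rounding); the standard area is reported as the
nearest integer m². Calibration checks use 1,000 PERMANOVA null datasets
(two groups of six, four taxa, 199 permutations each), a 32-sample
complete-separation fixture at 999 permutations, 100 recovery replicates
of 40-territory studies with the date effect at twice the noise SD (single
block and time block — the latent link does not depend on replication
depth), and 1,000 null-effect replicates of the 8-territory design; these
sizes give binomial standard errors well inside the asserted ±2-point
bands. Degenerate inputs fail loudly: both-zero distance vectors,
zero-variance PCA matrices, constant predictors, single-group PERMANOVA,
nonpositive lengths or radii all raise typed errors rather than returning
NaN.

## Known limitations

Marginal means beyond the balanced case rely on the optional mixed-model
path, which is not asserted against an external reference on unbalanced
designs. The allometric defaults are placeholders pending study-specific
coefficients. The upscaling inherits the equal-effort-per-area assumption.
Eight territories give the real-data links very low power; the package
reports raw p-values with a caveat rather than attempting correction.
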