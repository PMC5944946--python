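# Methods

## The paired-library model

A paired 18S survey sequences, for each sampling date, one amplicon
library from genomic rDNA and one from reverse-transcribed rRNA. Read
counts are compositional: only relative abundances within a library are
meaningful, and each OTU's relative rDNA abundance is taken as a proxy
for its share of cells while its relative rRNA abundance is taken as a
proxy for its share of ribosomes. The ratio of the two is therefore a
*relative activity* index, confounded by ribosomal gene copy number
(dinoflagellates carry orders of magnitude more rDNA operons than small
flagellates) and by life-history effects — which is why the package
reports relative patterns (prevalence slopes, quadrant phases, leads)
rather than absolute activity.

## Preprocessing

Filters run per molecule dataset, in a fixed, logged order: dataset-wide
singletons (OTU total count exactly 1 across all samples — the most
likely sequencing artefacts) are dropped; metazoan OTUs are dropped
(pre-filtration removes most metazoa at sampling, and leftovers swamp
protist signal); libraries are rarefied; relative abundances follow.

Rarefaction is subsampling without replacement (one multivariate
hypergeometric draw per library) to the minimum retained depth by
default, with the seed recorded; this keeps richness indices comparable
across libraries of unequal depth. Scaling-based normalizations were
deliberately not used because Chao-1 and the singleton/doubleton counts
it depends on are only meaningful on integer subsamples.

## Diversity indices

Chao-1 is the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, defined
even when no doubletons occur; the classic `F1²/(2F2)` form is available
via a flag. Simpson is reported as dominance `Σ p_i²` (0 → perfectly
even, 1 → single-taxon dominance); equitability is `H'/ln S_obs` with
natural-log Shannon and is flagged undefined (NaN) below two observed
OTUs. Two samples are compared by pooling their reads and re-splitting
the pool at the original depths without replacement; the two-sided
p-value uses add-one smoothing, `p = (1 + #{|Δ*| ≥ |Δ|})/(B + 1)`. The
re-split null conditions on the pooled composition and exactly preserves
both depths, which keeps the test calibrated for depth-sensitive indices
(verified on same-multinomial replicates in the test suite).

## Environmental seasons

Sub-surface light is the depth-averaged Beer-Lambert profile
`I = I0(1−e^{−kd·z})/(kd·z)`, computed with `expm1` so the transparent
and shallow limits are numerically exact. Each environmental variable is
BoxCox-transformed (maximum-likelihood λ; variables with non-positive
values get a recorded additive shift; constant variables pass through
with a warning), then standardized, so the PCA is a correlation-matrix
PCA — the variables carry incommensurable units, and covariance PCA
would let the largest-variance unit dominate. Contribution of variable
*i* to axis *j* is `100·v_ij²` (unit eigenvector squared), summing to
100 per axis; variables above 10 % are flagged as strong contributors.
Dates are grouped by Ward clustering of the first-plane scores, k = 3 by
default (spring bloom / summer / winter is the natural temperate-coastal
partition).

## Community structure

Sample dissimilarity is Bray-Curtis; linkage is group-average (UPGMA),
the convention of the PRIMER lineage of tools, and merge heights are
dissimilarities so a "cut at S % similarity" is a cut at height
`1 − S/100`. SIMPROF permutes each OTU's values independently across
samples, which destroys any sample-level structure while keeping each
OTU's marginal distribution. The statistic π is the mean absolute
deviation of the observed ordered dissimilarity profile from the mean
ordered profile of 1000 permutations; the p-value compares π against 999
further permutations measured against the same reference profile, with
add-one smoothing, and π = 0 (all profiles identical) short-circuits to
p = 1. Applied top-down from the dendrogram root, recursion stops at the
first non-significant node, whose subtree forms one homogeneous group.
Type-I calibration under an exchangeable multinomial null is close to
nominal (the fixed row totals leave the null p-distribution uniform in
practice; checked empirically at α = 0.05 in the acceptance suite).

"Side by side" placement of a date's rDNA/rRNA pair is operationalized
as a *cherry*: the two leaves merge with each other before either joins
anything else. Co-membership is evaluated at the 40 % similarity cut,
and cluster-vs-season agreement assigns each cluster its majority season
and scores the fraction of samples whose own season matches. Venn
membership of an OTU in a cluster requires at least one read in at least
one sample of that cluster; region percentages are nearest-integer
shares of the union.

## Activity framework

The signed ratio maps the raw quotient `r = rrna_rel/rdna_rel` to `+r`
when `r ≥ 1` and `−1/r` otherwise, so magnitudes are fold differences
and the sign names the prevalent molecule; exact equality returns +1,
and an OTU absent from either library at a date is excluded rather than
given an infinite ratio. The raw ratio is exactly recoverable, and
swapping the molecules negates the value.

Group-level prevalence uses reduced-major-axis regression (errors in
both axes): `slope = sign(r)·sd(y)/sd(x)`, the geometric mean of the
y-on-x and inverse x-on-y least-squares slopes, with case-resampling
bootstrap standard errors (1000 replicates). A group is RNA-prevalent
when `slope − z·SE > 1` and DNA-prevalent when `slope + z·SE < 1`, with
`z = 2` by default: a ±1 SE band is a ~68 % interval and would misclass
a genuinely neutral (slope = 1) group about a third of the time, so the
~95 % band is the deliberate default (z is configurable, and a fixed
slope cut such as 1.25 can be used instead). Fits pool all (OTU, date)
points of a higher taxonomic group among the most abundant OTUs;
per-OTU fits are available but noisier.

Quadrant phases classify each (rDNA, rRNA) relative-abundance point
against a rare threshold (0.01 % of reads) and an abundant threshold
(0.1 %): rare-low, rare-active, abundant-active, abundant-low, with any
point whose coordinate falls in the band between thresholds labelled
*transition*. The band is real — an order of magnitude wide — and
treating it as its own state avoids manufacturing sharp phase flips from
small fluctuations. A *bloom interval* is a maximal run of
abundant-active dates. An *early warning* is any earlier date, since the
previous bloom, where the rRNA signal is already above the abundant
threshold while the rDNA signal is not; its lead is reported in sampling
intervals and days. A bloom immediately followed by an abundant-low date
is flagged as entering senescence. These definitions are deliberately
threshold-based and contain no tuning beyond the two thresholds.

## Synthetic communities

The generator draws, per OTU, a latent log-biomass = baseline + seasonal
Gaussian bump (periodic over the year) + AR(1) log-noise (marginal SD
0.5, lag-1 correlation 0.5 by default). rDNA read weights multiply the
biomass by a per-group copy-number factor (1–50× across presets,
dinoflagellate-like groups highest); rRNA weights multiply it by an
activity factor. For bloom taxa the activity envelope is anticipatory:
the rRNA log-weight follows `max(bump(t), bump(t+L))`, so the rRNA
signal crosses any abundance threshold exactly L days before the rDNA
signal and then rides the bloom down with it. (A pure time-shift of the
whole profile would instead leave almost no date with both molecules
above the abundant threshold once L approaches the bloom width — no
detectable bloom at all — so the envelope is the model that actually
realizes "activity leads abundance".) The AR(1) noise is shared between
the two molecules of a date, as it models biomass rather than library
construction; only multinomial read sampling separates them otherwise.
Libraries are multinomial draws at fixed depths, 20 000 rDNA / 10 000
rRNA reads by default, matching realistic post-filtering depths; 30
paired dates is the default series length.

Presets: `three_guild_truth` plants spring/summer/winter specialist
guilds (season centers at days 105/215/355; per-OTU peaks jittered
±10 days; width 40 days; in-season rise e⁶ ≈ 400×) — chosen so that the
planted partition is strong: guild hand-over covers the whole year while
cross-season samples share little read mass, which is what "three
seasonal clusters separable at 25 % similarity" requires.
`bloom_truth` plants one bloom OTU (baseline 0.002 %, peak ~3 % of
reads, width 10 days) over a flat 60-OTU background with reduced noise
(SD 0.3), weekly sampling. `simulate_null` draws every sample i.i.d.
from one lognormal-shaped shared multinomial — the exchangeable null for
SIMPROF and diversity-test calibration. `rma_points` draws bivariate
normal log-abundance clouds whose population RMA slope is planted
exactly, with correlation 0.9 as in dense well-sampled groups.

What the generator does **not** emulate: PCR and chimera artefacts,
taxon-specific amplification bias, zero-inflation beyond multinomial
sampling, inter-taxon interactions, and multi-year trend. Passing tests
therefore demonstrate that the estimators recover planted structure
under sampling noise at realistic depths — not that any specific field
result would be reproduced from raw reads.

## Problem sizes and numerical choices

The statistical acceptance checks use: 200 null datasets of 30 samples ×
200 OTUs at depth 2000 for SIMPROF calibration; 20 seeds × 300 points ×
1000 bootstrap replicates per planted RMA slope; 20 seeds of the weekly
bloom design for each lead setting; and one fixed-seed three-guild run
(150 OTUs, 30 paired dates) for cluster recovery — sizes at which each
check completes in seconds to a couple of minutes while leaving the
binomial/bootstrap bounds meaningful. Ties in top-OTU selection break by
OTU id; p-values from permutation tests always use add-one smoothing and
never report 0; rarefaction at exactly the row total returns the row
unchanged; Bray-Curtis on two all-zero vectors, empty samples, and
constant BoxCox vectors raise or warn explicitly rather than returning
NaN silently.

## Known limitations

Copy-number variation is simulated but never *corrected*; prevalence
classes conflate genome architecture with activity exactly as the
underlying data do. The early-warning rule is a threshold crossing, not
a forecast — with sparse sampling relative to the activity lead it will
simply fire late or not at all. SIMPROF's permutation null treats OTUs
as independent; strong inter-OTU correlation (colinear blooms) makes the
test anti-conservative for detecting "any structure", which is the
intended reading. Season naming (spring/summer/winter) is a labelling
convenience over Ward groups; nothing in the clustering knows calendar
semantics.
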