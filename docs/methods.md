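# Methods

This note documents the models and numerical conventions behind
`zebratrack`: what each endpoint computes, what the synthetic generators do
and do not emulate, and the design choices made where the assay
descriptions left the details open.

## Trajectories, arenas, zones

A trajectory is a strictly frame-ordered sequence of positions in cm at a
fixed frame rate (25 fps throughout, matching standard zebrafish video
setups). Coordinates use a bottom-left origin with x rightward and y upward
in the camera plane; side-view tanks are analyzed in that plane and depth
is ignored. The trapezoid novel tank is modeled as its 30 × 15 cm
camera-facing rectangle with a 10 cm water column. Pixel trajectories are
calibrated by a scalar px/cm factor; points beyond the arena plus a 0.5 cm
tolerance are reported, not clipped.

Zones are half-open axis-aligned distance bands from a reference wall:
a zone includes its lower distance bound and excludes its upper, so every
boundary point belongs to exactly one zone. Presets: novel tank
bottom = [0, 5) cm and top = [5, ∞) from the floor; mirror contact
[0, 1.5) and approach [1.5, 5) cm from the mirror wall (farther is
"outside"); conspecific/empty halves split the 16 cm middle chamber at
8 cm. Tracking dropouts up to 5 frames (configurable) are linearly
interpolated; longer gaps split the trajectory for metric purposes, since
interpolating across long occlusions would manufacture motion.

## Ethogram

Instantaneous speed is the Euclidean displacement over a 1-frame window
divided by elapsed time (window configurable). Movement classes: small
[0, 1) cm/s, moderate [1, 15] cm/s, large (15, ∞) cm/s. The printed class
intervals overlap at 1 cm/s; both 1 and 15 cm/s resolve to "moderate" so
that "large" is strictly above 15. Freezing is operationalized as speed
below 0.5 cm/s sustained for at least 1.0 s (both configurable): trackers
report "no movement" differently, and a speed-plus-duration criterion is
the reproducible surrogate. Freezing overrides "small" in the per-frame
ethogram. Class time ratios partition session time and are renormalized to
sum to exactly 1. Average velocity divides total distance by total elapsed
time, not moving time. Sessions are additionally pooled into 1-minute
bins, each inter-frame interval assigned to the bin containing its start.

Morning/night comparisons require equal-duration sessions of the same fish
(0.5 s tolerance) and flag "night-dominant" when night total distance
exceeds the morning value — the inverted diurnal pattern of interest.

## Zone endpoints

An entry is an outside→inside transition; a fish already inside at the
first frame counts one initial entry. Time in zone is frames inside / fps;
latency is the time of the first in-zone frame (∞ if never). Distance is
attributed per inter-frame segment to the zone of the earlier endpoint —
simpler than proportional splitting and biased by at most one segment
length. Entries have no minimum dwell by default (a debounce in frames is
available). For the mirror test, biting frequency is the number of entries
into the contact strip and biting duration the time there; an *approach*
entry is counted per sortie into the whole within-5-cm region, so
continuing from the approach band into contact and back is one approach,
not two.

The social preference value is the signed normalized time difference
(t_CS − t_ES)/(t_CS + t_ES); the published assay description does not fix
the formula, and this choice is antisymmetric under CS/ES swap and
consistent with the unambiguous companion endpoints (time and distance
ratios), which remain the primary readouts.

## Shoal geometry

Per frame: mean pairwise ("interfish") distance, mean nearest-neighbor
distance, farthest pairwise distance, and the shoal polygon area taken as
the convex hull of the fish centroids — the unique ordering-independent
interpretation of "connecting the center points". A shoal exists when some
subset of ≥ 3 fish has all pairwise distances strictly below the 12 cm
threshold (a diameter criterion, equivalent to testing all triples); an
excursion is any fish strictly farther than the threshold from its nearest
neighbor. Polarization is the circular mean resultant length of unit
heading vectors — the standard polar order parameter — with headings taken
from 1-frame displacements and masked below 0.1 cm to avoid
noise-dominated directions. Note the chance level for n fish is
E[φ] ≈ √π/(2√n) ≈ 0.40 at n = 5, so "disordered" five-fish groups sit
near 0.4, not 0.

Session summaries mirror the two acquisition pipelines of the assay:
distance endpoints and polarization average over all frames (continuous
tracking), while hull area, shoal frequency and excursion frequency are
evaluated on 20 shots sampled once per minute; shorter sessions shrink the
shot spacing with a warning.

## Synthetic trajectory generators

The single-fish generator is a state-switching correlated random walk at
dt = 1/25 s over the four ethogram classes. A per-step Markov matrix (built
from mean dwell times of 2 / 1 / 4 / 0.8 s for freeze/small/moderate/large
and a target occupancy of roughly 10/15/65/10%) selects the state; speed is
drawn uniformly within the state's class range (chosen strictly inside the
class boundaries so recovered labels are unambiguous); heading accumulates
wrapped-Gaussian noise with a per-state scale; an optional constant
downward drift (cm/s) produces bottom dwelling. Walls reflect. The group
generator steers each fish by the normalized weighted sum of its heading
(persistence), the unit vector to the group centroid (cohesion), and the
mean heading of the others (alignment), plus angular noise, at a constant
cruise speed of 5 cm/s.

What these emulate: class-structured locomotion, bottom-bias anxiety
profiles, day–night activity scaling, cohesion/alignment-controlled group
structure — each with exact per-frame ground truth. What they do not:
body posture, burst-glide kinematics, wall-following (thigmotaxis),
inter-fish collision avoidance — the steering model has **no repulsion
term**, so strongly cohesive groups compress below realistic
nearest-neighbor spacing. Passing recovery tests therefore validates the
*measurement* code, not the biological realism of the generator. The
scripted-trajectory builder produces exact piecewise-linear paths (hold and
constant-speed move segments) for planted-boundary tests; all endpoint
recoveries are expected within one frame (0.04 s) per planted boundary.

## Circadian gene sets

The RNA-seq design is genotype × time-of-day with four groups (WT_M, WT_N,
MUT_M, MUT_N), four replicates each. FPKM = count · 10⁹ / (length ·
library size), with library sizes defaulting to per-sample count sums. A
gene is expressed iff FPKM > 0.1 (strict) in every sample of at least one
group. DEGs require linear fold-change ≥ 1.5 (or ≤ 1/1.5) and BH-adjusted
p ≤ 0.05. Externally computed per-gene statistics (e.g., from a
negative-binomial GLM) can be thresholded directly; for self-contained
synthetic runs the package supplies a stand-in two-sample test on
log2(FPKM + 1): a pooled-variance t with empirical-Bayes shrinkage of
per-gene variances toward their median (prior df 10; plain Welch/Student
variants available). This is a declared stand-in, not a reimplementation
of a count-model DE method.

Contrast sets follow the U/D nomenclature: U1/D1 mutant-vs-WT in the
morning, U2/D2 at night, U3/D3 WT night-vs-morning (the circadian genes),
U4/D4 mutant night-vs-morning. Night-preferring mutation-affected genes
GS1 = U3 ∩ D2 (elevated at night in WT, blunted in the mutant);
morning-preferring affected genes GS2 = D3 ∩ U2 (downregulated at night in
WT, attenuated in the mutant). The set expressions are configurable and
recorded in output metadata. Enrichment uses the G-test
G = 2ΣO·ln(O/E) on the expressed-gene 2 × 2 table (circadian ×
affected), df = 1, with an optional Williams correction
(G / [1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N)]), off by default.
G agrees with Pearson's X² near independence but diverges for strong
association; both are correct likelihood- vs. moment-based statistics.

The count generator draws negative-binomial counts (variance
μ + αμ², α = 0.1 by default; α = 0 gives Poisson) around baseline means
log-uniform in [1, 10⁴], with 130 of 2,000 genes planted as
morning-preferring (night mean ÷ 3 in both genotypes) and 30 of those as
mutation-affected (mutant-night mean × 2) — proportions scaled from a
typical brain dataset where ~6.5% of expressed genes are circadian and
under 1% are genotype-affected. **Detection-limit caveat:** at these
defaults the affected genes' between-genotype effect is 2-fold against a
per-sample log2 s.d. of ≈ 0.46, a known-variance z of only ≈ 3.1 at
n = 4 — below what BH correction across 2,000 genes can recover with high
sensitivity. GS2 recovery at these settings therefore has near-zero recall
(and vacuously high precision) for any honest two-sample test; the
recovery test documents this operating point rather than masking it. With
larger planted effects (≥ 4-fold interaction) or more replicates the
pipeline recovers planted sets essentially completely, as the unit tests
on stronger effects show.

## Group statistics

Endpoints are reported as mean ± standard error (sd/√n). Two groups use an
independent-samples t test (Student by default; Welch optional since the
equal-variance assumption is rarely checked in practice); three or more
use one-way ANOVA followed by Tukey HSD. The two-group ANOVA F equals t²
exactly, which the tests verify.

## Problem sizes and determinism

The shipped study runs at desk scale: 10 fish or groups per condition,
2–5 minute sessions, 2,000-gene count matrices, 5–20 seeds per Monte-Carlo
estimate — sizes at which every oracle comparison and planted-truth
recovery is exact or tightly bounded while the full suite runs in well
under a minute. All generators take explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
trajectories (positions written at 1e-6 cm) and count matrices.
`scripts/acceptance.py` derives all of its sub-seeds from a single `--seed`
via `SeedSequence`.
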