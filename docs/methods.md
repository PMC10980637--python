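# Methods

## Model and conditioning

The core model is a Cormack–Jolly–Seber (CJS) likelihood conditioned on
first release. An individual enters at its first winter sighting (initial
state probability 1); every subsequent occasion is a breeding season at the
colony. A single occasion axis of calendar years carries both: the winter
spanning years *y*/*y*+1 occupies slot *y* and the breeding season of year
*j* occupies slot *j*, so the entry-to-first-breeding interval is half a
year and all later intervals are annual. No recruitment, state uncertainty
or multi-site structure is modelled; only survival and detection.

The per-individual likelihood contribution multiplies survival terms (Φ¹
for the entry interval, Φ²⁺ afterwards) and detection / non-detection terms
up to the last detection, then the tail probability χ of never being seen
again, computed by backward recursion
χ_j = (1 − Φ_{j+1}) + Φ_{j+1}(1 − p_{j+1})χ_{j+1}. Identical histories are
collapsed with multiplicity weights; this is exact. An equivalent
multinomial likelihood over the new/old-stratified m-array is implemented
for time-structured models and serves as an independent cross-check in the
tests (agreement to 1e-8), never as the primary route.

## Age and interval conventions

Calendar-year (cy) age at breeding occasion *j* is *j* − birth year + 1
(hatch year = 1 cy); birds are adult from their fourth breeding season
(4 cy). Survival intervals take the age class at the interval's start; for
the entry interval this is the half-age at the entry winter (0.5 … 4.5,
adult iff ≥ 4). Resighting age classes are cy capped at 4 (2 / 3 / 4+).
The unequal first interval is handled by a distinct parameter class (Φ¹),
not by exponent scaling — the half-year survival is of direct scientific
interest.

## Design matrices

Each parameter class (Φ¹, Φ²⁺, p) carries an additive factor formula with
treatment (reference-level) coding over the factor combinations observed in
the data; the only interaction is distance × flyway, which spans exactly
the five wintering-region cells. When distance and flyway appear additively
in one formula, the resident flyway level is dropped: residents form a
single cell and their flyway indicator is structurally aliased with the
resident distance level (this reproduces the conventional parameter counts,
e.g. 13 free parameters for Φ¹ ~ age + distance + flyway alongside
Φ²⁺ ~ age and p ~ effort + age + distance). Any remaining rank deficiency
raises an error naming the aliased columns via pivoted QR. Resighting
probabilities in 2008–2013 are hard structural zeros: no columns, excluded
from K.

## Estimation

All free parameters live on the logit scale, clipped at 1e−12 from the
probability boundaries. The objective (−2 log conditional likelihood,
without the multinomial constant — ranking uses differences, which are
invariant to it) is minimised by L-BFGS-B with an analytic gradient
(adjoint of the χ recursion), from the origin plus seeded uniform(−2, 2)
multi-starts (default 5). A BFGS polish drives the gradient norm down when
L-BFGS-B terminates on function decrease. Convergence is declared when the
maximum absolute gradient falls below max(1e−8, 1e−7·(1 + deviance)) — the
scale-aware term reflects what float64 arithmetic can achieve on deviances
in the thousands — or when the optimum sits at a probability boundary
(|logit| > 15), where the link-scale gradient legitimately plateaus.
Non-convergence is flagged, and candidate models that fail to fit are
excluded from selection sweeps with a warning rather than aborting.

Profile-likelihood intervals for a real-scale class profile its linear
predictor: the parameter vector is reparameterised through the null space
of the class's design row, the constrained deviance is re-minimised
(warm-started) on a grid stepped outwards until it exceeds the minimum by
ĉ · χ²₁(0.95) = ĉ · 3.841, and each bound is then located by Brent root
finding. Boundary estimates yield one-sided intervals with a flag; level 0
degenerates to the MLE. At large n the intervals agree with Wald intervals
to within 1% relative width (checked in the tests). Wald curvature, where
needed, uses statsmodels' numerical Hessian.

## Goodness of fit and overdispersion

The four classical contingency components are computed from the
new/old-stratified m-array: TEST3.SR (ever reencountered, newly vs
previously marked), TEST3.SM (timing of first reencounter among the
reencountered), TEST2.CT (immediate vs later reencounter by detection
status at the occasion) and TEST2.CL (its timing complement). All are
Pearson chi-squares summed over groups and occasions. Occasions with
structurally zero detection produce zero-margin tables and drop out on
their own. R×C tables pool adjacent columns whose expected count falls
below 2 (rightmost offender folded left). Tables whose expected counts
cannot reach the validity threshold — 3 for the 2×2 components, 2 after
pooling for R×C — are treated as degenerate and contribute nothing; under
the tests' null this keeps every component's type-I error at the nominal
5% within Monte-Carlo error (the package's calibration test), which the
zero-margin-only rule does not achieve on sparse designs. A signed
transience z statistic is available as a supplementary output but never
enters ĉ.

ĉ sums statistics over df for a chosen component set — by convention
TEST2.CT + TEST2.CL + TEST3.SM, since the Φ¹/Φ²⁺ split absorbs TEST3.SR —
and is floored at 1 for ranking.

## Model selection

QAICc = deviance/ĉ + 2K + 2K(K+1)/(n − K − 1), with the number of marked
individuals as effective sample size n (a conservative choice; the paper-
style alternative of total releases is a one-line change via the `n`
argument). Akaike weights are computed shift-stably. The parsimony rule:
among models within two QAICc points of the best, the fewest parameters
win, ties broken by lower QAICc. The stepwise procedure fixes the non-focal
block at its broadest candidate parameterisation (breadth measured in
factor levels), ranks the focal block, freezes the winner and ranks the
other block; both orders can be run and compared, with an agreement flag.

## Permanent-emigration correction

Birds never recorded again at the colony after entry, but seen March–July
away from it, are possible permanent emigrants. The reported percentage
divides cases by the region's total (the definition consistent with the
published per-region percentages); the alternative denominator (birds never
seen again) is available behind a flag. True survival ≈ Φ/(1 − fraction),
computed with the unrounded fraction and capped at 1 with a flag; rounding
happens only at report time.

## Synthetic cohort generator

The generator draws, per individual: region (fixed uneven group sizes
257/71/75/33/48, total 484), entry winter (uniform over 2008/09–2019/20),
age at entry (uniform over 0.5–4.5 cy, truncated so hatch year ≥ 2008),
an optional transient fate (death in the entry interval) or permanent
emigration (an absorbing "alive elsewhere" state: survival continues,
colony detection stops, March–July away-resightings occur with a
configurable probability — keeping apparent and true survival separable in
the truth record), then Bernoulli survival per interval and Bernoulli
detection per free occasion. Each individual consumes an RNG stream keyed
by (seed, region index, within-region index), so group-size changes never
cascade across individuals and equal seeds give bit-identical output.

Default parameter values are declared placeholders consistent with the
study's qualitative ordering (long-distance migrants lowest on Φ¹ and on
p; adults above immatures; camera-trap years more detectable): Φ¹ and p
are generated from additive logit formulas (Φ¹ immature LD/SD/RES =
0.33/0.72/0.73 with a +0.6 logit adult effect; p anchored at 0.08 with
+1.1 camera-trap, +0.9/+1.8 age and +0.7/+0.8 distance effects), so the
additive generating structure the selection tests look for is exactly
true. Φ²⁺ is 0.85/0.94 (immature/adult). A separate `null_gof_config`
removes all age and time-since-marking structure (Φ¹ = Φ²⁺ = 0.84,
p by distance and effort only) for goodness-of-fit calibration, since the
contingency tests' null is homogeneity, not the full study structure.

What the generator does **not** emulate: movement between wintering sites,
climate or density effects, individual heterogeneity beyond the modelled
classes, ring loss, and uncertainty in region assignment. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness of the field conclusions to their violation.

## Problem sizes in the test suite

The statistical acceptance tests use 50 replicates at n = 2000 for
parameter recovery and interval coverage, 400 replicates at n = 500 for
GOF type-I calibration (200 for power at 30% transients), and 50
replicates at n = 1000 for stepwise-selection consistency, chosen to keep
the full suite within a routine CI run while leaving Monte-Carlo error
well inside the asserted bands.

## Known limitations

* Absolute deviances differ from E-SURGE's by a data-dependent constant;
  only deviance differences are comparable.
* The exact degrees of freedom of the GOF components depend on the pooling
  and validity rules; they approximate, but do not exactly replicate,
  U-CARE's df on any given dataset.
* Profile intervals assume a locally well-behaved deviance; at probability
  boundaries they degrade to flagged one-sided intervals.
* The emigration correction is the deliberate simple deterministic one; it
  is not a joint likelihood over site fidelity.
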