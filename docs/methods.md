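# Methods

## The design under study

A natural cohort of pediatric wrist radiographs contains mostly
easy-to-read cases: about two thirds carry a visible fracture, and only
~6% of images are graded *difficult* by a radiologist (subtle fracture
visibility; the grade exists only for fracture-positive images). A test set
sampled at random therefore measures models mostly on easy material. The
package implements the comparison between that random design and a
*balanced* design in which difficulty, projection and fracture presence are
equalized by matching, and quantifies the performance gap with
difficulty-stratified metrics and exact paired sign tests.

## Matched construction

Stage 1 takes every difficult visible-fracture image as an anchor and
greedily assigns the nearest-age easy-fracture image with the identical
projection, without replacement, subject to a hard age caliper
(default 1.0 year). Stage 2 repeats the assignment from all selected
fracture images (anchors + matches) to fracture-free controls. Anchors are
processed in a seeded random order; age-distance ties break on
lexicographic image id, so the construction is deterministic given the
seed. An anchor with no in-caliper candidate is a hard error naming the
anchor and stage — the construction never silently drops anchors, because
the design's arithmetic (A anchors → 2A fractures → 4A images, 50%
fractures, 25% difficult) holds only under complete matching. Greedy
nearest-age was chosen over optimal (Hungarian) assignment: it is the
simplest procedure satisfying the stated criteria, is order-reproducible,
and on feasible pools the test suite verifies it against a maximum
bipartite-matching feasibility oracle. `max_anchors` caps the anchor count
so oversized pools can reproduce a target set size exactly (e.g. 1147
anchors → 4588 images).

Images tagged *diagnosis uncertain* are excluded before any sampling, for
both the balanced and the random set. The overlap subset is the exact
intersection of the two sets, in sorted-id order.

## Synthetic cohort

`generate_cohort` draws, per image, independently:

| field | distribution | default |
|---|---|---|
| age | normal truncated to [0.4, 18.7] y | mean 10.9, SD 3.58 |
| gender | Bernoulli | 42% female |
| laterality | Bernoulli | 56% left |
| projection | categorical (ap/lateral/oblique) | 48.3 / 51.1 / 0.6% |
| study type | Bernoulli | 22% initial |
| fracture | Bernoulli | 68% |
| difficulty \| fracture | Bernoulli | 273/3132 ≈ 8.7% (≈6% of all images) |
| diagnosis uncertain | Bernoulli | 3% |
| boxes per fracture | categorical | 1: 70%, 2: 25%, 3: 5% |

The truncated normal is the simplest distribution matching the published
mean/SD/min/max of the emulated cohort; covariates are drawn independently
because only marginals are known. The diagnosis-uncertain rate and the
box-count distribution are not published; 3% and {1: .7, 2: .25, 3: .05}
were fixed once as clinically plausible values. Fracture boxes are placed
uniformly with sides 5–30% of the image extent. Every generator consumes a
single explicit `numpy` Generator per call: identical config + seed is
byte-reproducible.

Independent sampling at a ~0.6% oblique rate occasionally (roughly a third
of 22k-image draws, more often for small cohorts) produces an extreme-aged
oblique fracture with *no* same-projection candidate inside the caliper, a
pool on which no matching — greedy or optimal — can succeed. The *study
pool* is therefore defined as a cohort draw on which the construction is
feasible: `build_study_pool` redraws with derived seeds until matching
completes (deterministic given the base seed). The matching rules, caliper
and generator frequencies are never altered by this; `run_experiment` also
offers a strict mode (`ensure_feasible=False`) that surfaces the matching
error instead.

## Simulated model error

Model outputs are simulated per difficulty stratum (easy-fracture,
difficult-fracture, no-fracture), which is the mechanism that makes
balanced sets genuinely harder:

- **Classifier scores**: Beta-distributed per stratum. The packaged
  8-variant ladder uses mean scores 0.80 → 0.905 (easy), 0.52 → 0.59
  (difficult) and 0.18 → 0.124 (no fracture) with fixed concentrations, a
  monotone capacity ladder with a difficulty penalty at every rung.
- **Detections**: each ground-truth box is found with per-stratum
  probability (5-variant ladder: 0.85 → 0.91 easy, 0.58 → 0.66 difficult);
  a found box is translated along one axis by the closed-form offset
  d = e(1−t)/(1+t) (e = box extent) so its IoU with the truth equals a
  target t drawn around the stratum's localization quality (0.85 ± 0.07
  easy, 0.68 ± 0.10 difficult, clipped to [0.05, 1]); confidences are Beta
  per stratum; false positives arrive per image as Poisson(fp_rate) random
  boxes.

The simulator emulates metadata and error *structure*, not images: passing
tests demonstrate the correctness of the sampling, metric and testing
machinery and the direction of composition effects under difficulty-
dependent error. They say nothing about any real model's absolute
performance, and effect sizes here are set by the ladder profiles, not
estimated from data. Real radiograph properties that are not modeled:
covariate dependence (age × fracture type), reader disagreement on the
difficulty grade, occult fractures counted positive without a visible box,
and train/test leakage from cross-validated prediction pooling.

## Metrics

- Classification counts use score ≥ threshold (default 0.5, a convention).
  Zero-denominator ratios return NaN rather than raising; support-weighted
  two-class averages skip undefined classes with a warning. The weighted
  figures are support-weighted means of the per-class values with each
  class taken as positive in turn.
- ROC AUC is the trapezoidal area, which equals the Mann–Whitney
  probability with ties counted half; the test suite verifies that
  equivalence exactly. The 95% CI uses DeLong's structural-components
  variance by default (midrank implementation), or a seeded 2000-resample
  bootstrap.
- Detection matching is greedy by descending confidence with one-to-one
  truth consumption at the IoU threshold; sorting ties break on image id
  then coordinates. AP uses 101-point interpolation of the precision
  envelope (the convention of the common detection frameworks); an exact
  all-point area oracle lives in the test suite and must agree within 0.01.
  AP50-95 is the arithmetic mean over IoU 0.50:0.05:0.95. Box coordinates
  are continuous and corner-coded with area (x_max−x_min)(y_max−y_min), no
  +1 correction, so normalized-annotation arithmetic is exact.
- Intensity preprocessing clips at the 2nd and 99.5th gray-value
  percentiles, applies CLAHE (8×8 tiles, clip limit 0.01 — configurable;
  CLAHE can be disabled, making the pipeline strictly order-preserving),
  rescales to 8-bit and replicates to 3 channels. A constant image maps to
  mid-gray 128 instead of erroring, since flat synthetic backgrounds are
  legitimate inputs.

## Sign tests

Paired across variants, ties dropped, two-sided p = min(1, 2·P(X ≥ k)) for
X ~ Binomial(m, ½) with k the larger sign count — computed exactly for all
m used here (≤ 25); for the symmetric binomial the doubled-tail and
equally-extreme-outcome definitions coincide. n = 8 all-same-sign gives
0.0078125 (prints 0.008); 7/1 gives 0.0703125 (0.070); 5/3 gives 0.7265625
(0.727); 4/4 gives 1.0. For n = 5 all-same-sign the exact two-sided value
is 0.0625; no smaller value is attainable with five pairs. P-values are
kept at full precision and rounded to three decimals only for display.

## Problem sizes

Default experiment runs use a 20,000-image cohort; the packaged examples
and the test suite use 700–6,000-image cohorts and the composition check a
22,000-image pool (the expected anchor yield there, ≈1300, leaves a
comfortable margin over the 1147 anchors the capped construction
consumes). These sizes keep a full run in seconds on one CPU while leaving
Monte-Carlo error far below the simulated effect sizes.

## Known limitations

- Greedy matching can fail on pools where an optimal assignment exists
  (the oracle test only requires failure when *no* perfect matching
  exists); with the default caliper and realistic pools this was not
  observed.
- The overlap-set size is data- and seed-dependent and is not a target
  quantity.
- DeLong CIs are asymptotic; for strata with very few images the bootstrap
  option is preferable.
- The difficulty grade is only modeled for fracture-positive images;
  difficult fracture-free images (e.g. confusing growth plates) are not
  represented.
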