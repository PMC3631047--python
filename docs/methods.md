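# Methods

## The grading model

The scale quantifies how much of the postoperative spinal canal is
occupied by epidural scar. Per axial slice, four quadrants around the
dural-sac center are graded 0–4 by affected fraction; the grade sum
S ∈ [0, 16] counts affected sixteenths of the slice and converts to a
percentage as S/16 × 100 (so a sum of 3 is exactly 18.75 %, kept at full
precision rather than the rounded 18 % sometimes quoted for that entry).
A segment imaged on n slices scores the mean of its per-slice percentages,
equivalently ΣS_i/(16 n) × 100. The model deliberately ignores *where* in
the canal the scar sits — anterior and posterior quadrants weigh equally —
because its purpose is comparing total scar burden between treatment
groups, not predicting symptoms.

### Fraction-to-grade bins

On a continuous affected fraction the printed bin labels (1–25 %, 26–50 %,
51–75 %, 76–100 %) force closed upper endpoints: 0.25, 0.50 and 0.75 map
to grades 1, 2 and 3. "No/trace" has no published quantitative bound; the
package uses a configurable `trace_threshold`, default 0.005 (0.5 % of the
quadrant) — large enough to absorb a few stray pixels in a mask, small
enough not to eat into bin 1. Values ≥ 0.25 are rejected outright since
they would make grade 1 unreachable.

## Geometric grading from masks

`efgrade.masks` derives the per-quadrant fractions from a binary canal
(evaluation-area) mask and a binary fibrosis mask, given the dural-sac
center. Choices that the verbal description leaves open:

- **Dividing-line orientation.** "Perpendicular lines through the center"
  does not fix an orientation; the package uses lines aligned with the
  image rows/columns (axial slices are conventionally displayed anterior
  up), with a `rotation_deg` parameter for non-standard displays.
- **Laterality.** Quadrant A is the patient's right anterior space, which
  is image-left in radiological display; so "right" means smaller column
  index.
- **Tie rule.** Pixels exactly on a dividing line go to the anterior /
  patient-right side (priority A > B > C > D). Any consistent rule would
  do — it affects a measure-zero set — but this one is deterministic and
  documented.
- **Posterior border.** At laminectomy levels the line through the two
  most posterior bony remnants clips the evaluation area: pixels strictly
  posterior to the infinite line are excluded, pixels on it are kept. A
  border parallel to the anterior–posterior axis has no posterior side and
  is rejected.
- **Denominators.** Fractions are fibrosis pixels over evaluation-area
  pixels *per quadrant* (the grade is "% of quadrant affected"); a
  quadrant with no evaluation-area pixels scores 0.

## Reliability statistics

All statistics are computed in closed form in the package; scipy supplies
only the t and F distributions, and pingouin appears solely as an
independent cross-check in the test suite.

- **Paired t-test** on first-minus-second reading differences per reader:
  mean, SD, SEM = SD/√N, 95 % CI = mean ± t₀.₉₇₅,N₋₁·SEM, two-sided P.
  Zero-variance differences (perfect repeatability, or a constant offset)
  are reported with a `degenerate` flag instead of raising.
- **Unpaired t-test** between readers: pooled-variance Student form by
  default, Welch via `flavor="welch"`. The era-typical pooled form is the
  default; both are exposed because the validation study's printed
  interobserver P values (0.81/0.74) are not derivable from its own score
  table under either form, so no numerical target is attached to them.
- **ICC.** All six McGraw–Wong forms from the two-way ANOVA mean squares
  (MSR subjects, MSC raters, MSE residual), e.g.
  ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k/n(MSC − MSE)), with F-based
  95 % CIs (Satterthwaite degrees of freedom for the absolute-agreement
  forms, Spearman–Brown for average measures). Negative variance-component
  estimates are not truncated; a `negative_variance` flag is set.
- **Bland–Altman.** Bias = mean difference, 95 % limits of agreement =
  bias ± 1.96 SD(diff), repeatability coefficient 1.96·√2·s_w with the
  within-subject SD s_w = SD(diff)/√2 for duplicate measurements.

### The reference interobserver analysis

The bundled validation study reports its interobserver reliability as
"ICC 0.95; 95 % CI 0.87–0.97" without naming the estimator or the reading
occasion used. Recomputing every two-way absolute-agreement variant on the
bundled scores shows that **first readings, average measures over the two
radiologists (ICC(2,k))** gives 0.9370 with 95 % CI (0.8707, 0.9693) —
matching the published interval exactly at printed precision — while no
variant reproduces 0.95 and that interval simultaneously (single measures
give 0.88–0.91; second readings give 0.954 but CI 0.91–0.98). The package
therefore defaults `interobserver_icc` to ICC(2,k) on the first occasion
and treats the published 0.95 as a likely transcription of the same
software output whose CI it reproduces; the form (`icc1`…`icc3k`) and
occasion subset (`first`, `second`, a label, or `stacked`, which stacks
patient×occasion rows) are selectable everywhere, and machine output
always records which were used. For a single-rating reliability statement
the conservative ICC(2,1) remains available and is the default of the
low-level `icc()` function.

Similarly, the published intraobserver SD of 1.47 for radiologist 1 is the
truncation of the computed 1.4797 (which rounds to 1.48); the fixture
self-test and acceptance tests therefore allow ±0.011 around the printed
SDs while matching means and SEMs at printed precision.

## Synthetic data

`simulate_reader_study` draws score(i, r, o) = round-and-clamp(μ_i + b_r +
ε_iro) with patient effects μ_i ~ N(mean_score, σ_b²) drawn once per
patient, fixed reader biases b_r, and occasion noise ε ~ N(0, σ_e²).
Rounding to integers and clamping to `score_range` emulates ordinal
grading of a latent continuous scar burden. Defaults mirror the validation
design — 32 patients, 2 readers, 2 occasions, score range (0, 80) (a
five-slice total of sixteenths), mean 9, σ_b = 5, σ_e = 1 — the moments
chosen loosely from the bundled table's spread (patient mean ≈ 9.3,
between-patient SD ≈ 5.3, paired-difference SD ≈ 1.2–1.5). These are
conventions describing a plausible study, not measured constants. The
generator does not emulate ordinal-scale floor effects beyond clamping,
reader-by-patient interactions, or drift between occasions; a green
parameter-recovery test therefore establishes estimator correctness under
the additive Gaussian model, not robustness to those violations. Under
that model the single-rating reliability is σ_b²/(σ_b² + σ_e²), which the
ICC estimators recover within ±0.05 at N = 500 (discretization costs a
little attenuation, covered by the tolerance).

`simulate_slice_masks` builds a rectangular canal phantom and fills a
seeded random subset of each quadrant's pixels so the realized fraction
matches the request to within one pixel of quadrant area; realized
fractions are returned as ground truth, so grade-recovery tests compare
against what was actually drawn rather than what was asked.

## Numerical and I/O choices

- Percentages are exact multiples of 6.25 internally; rounding happens
  only in reports (`output_precision`, default 2 decimals; machine JSON
  keeps full precision).
- Occasions order lexicographically (numeric-aware) unless an explicit
  `occasion_order` is given; it defines the sign of "first minus second".
- The condensed CSV schema (`patient_id, reader_id, occasion, score`)
  exists so per-segment total scores — the form in which the bundled
  study's data is recorded — are first-class input; the quadrant schema
  carries per-slice grades and aggregates through the model itself.
  Parsers reject out-of-scale or non-integer grades, duplicate cells and
  mixed schemas, naming the offending row.
- `n_slices_expected` (default 5, the protocol's slice count) guards
  aggregation: comparing segments with different slice counts silently
  biases the total, since mostly-clean extra slices dilute the percentage.

## Known limitations

- The model is for group comparisons, not individual diagnosis; it makes
  no claim about the correlation between scar burden and symptoms.
- Scar identification itself (which pixels are fibrotic) is out of scope:
  readers grade visually, or masks come from elsewhere.
- With many unaffected slices the segment percentage underestimates the
  burden at the operated level; protocols should fix the slice count (≤ 5)
  across arms.
- The ICC confidence intervals assume the normal-theory two-way model;
  with N = 32 ordinal scores they are approximations.
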