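# efgrade

Quantification of epidural fibrosis (EF) in the postoperative lumbar spinal
canal from quadrant-based MRI grades, with the observer-reliability analysis
that validates the scale.

Epidural fibrosis — scar tissue replacing the normal epidural fat after
lumbar surgery — is a recognized cause of failed back surgery syndrome, and
MRI is the only way to measure it in vivo when testing scar-inhibiting
agents. The classic Ross scheme grades each quadrant of a single axial
slice on an ordinal 0–4 scale; `efgrade` implements the volumetric
extension of that scheme, which turns per-quadrant grades on several
adjoining slices into a single *total fibrosis percentage* per operative
segment, comparable across patients, readers and centers without any
calibration software. The package is aimed at radiologists and trialists
running (multi-center) reader studies of EF burden.

## The model

Each axial slice is divided into four quadrants by perpendicular lines
through the center of the dural sac (A/B = right/left anterior, C/D =
right/left posterior epidural space; at laminectomy levels a posterior
border line between the most posterior bony remnants bounds the evaluation
area). Each quadrant gets a grade $g_q \in \{0,\dots,4\}$ for the affected
fraction of the quadrant: 0 = no/trace, 1 = 1–25 %, 2 = 26–50 %,
3 = 51–75 %, 4 = 76–100 %.

Because a quarter of a quadrant is one sixteenth of the slice, the slice
sum $S = \sum_q g_q \in [0, 16]$ counts affected sixteenths, so the
per-slice percentage is

$$p = \frac{S}{16} \times 100,$$

a multiple of 6.25 %. For a segment imaged on $n$ axial slices (five per
operative level in the validation protocol), the total fibrosis percentage
is the mean of the per-slice percentages:

$$P = \frac{1}{n} \sum_{i=1}^{n} p_i .$$

The reliability module provides the statistics used to validate the scale:
paired and unpaired two-sided t-tests between readings and readers,
intraclass correlation coefficients from the two-way ANOVA decomposition
(all six Shrout–Fleiss/McGraw–Wong forms, with F-based 95 % confidence
intervals), and Bland–Altman bias / limits of agreement with repeatability
plots. A bundled dataset ships the validation reading study: 32
postoperative patients scored by two radiologists on two occasions three
weeks apart.

## Worked example

Score a five-slice segment from per-quadrant grades:

```python
from efgrade import SliceAssessment, SegmentAssessment

grades_per_slice = [[2, 1, 0, 0], [1, 1, 0, 0], [0, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]]
slices = tuple(SliceAssessment.from_grades(g) for g in grades_per_slice)
seg = SegmentAssessment(slices=slices)
print([s.slice_percent for s in slices])  # [18.75, 12.5, 6.25, 0.0, 0.0]
print(seg.total_score, seg.segment_percent)  # 6 7.5
```

The first slice has grade sum 3, i.e. 3/16 = 18.75 % of that slice is
fibrotic; averaging the five slice percentages gives 7.5 % of the segment's
epidural space affected.

Run the reliability analysis on the bundled reading study from the shell:

```sh
python -c "from efgrade import reading_study, write_grade_table; write_grade_table(reading_study(), 'scores.csv')"
efgrade reliability scores.csv --out-dir report
```

which prints (and writes to `report/reliability.{json,txt}`):

```
Reader study: 32 patients, readers R1, R2, occasions 1, 2

Variability                     Mean      SD     SEM           95 % CI       P
Intraobserver (paired t, first vs second reading)
  Reader R1                     0.06    1.48    0.26     -0.47 to 0.60    0.81
  Reader R2                    -0.25    1.16    0.21     -0.67 to 0.17    0.23
Interobserver (unpaired t, reader vs reader)
  Occasion 1                   -0.03    4.87    1.22     -2.46 to 2.40    0.98
  Occasion 2                   -0.34    4.95    1.24     -2.82 to 2.13    0.78

Interobserver ICC: 0.94 (95 % CI 0.87-0.97); two-way random effects, absolute agreement, average measures (ICC(2,k)); occasions: first
```

Neither radiologist differs between their first and second reading (P =
0.81 and 0.23), the radiologists do not differ from each other, and the
interobserver ICC of 0.94 (95 % CI 0.87–0.97) indicates good reliability
of the scale. `--plots` additionally writes the repeatability and
Bland–Altman agreement scatter plots.

Other subcommands: `efgrade grade` derives the quadrant grades of one
slice geometrically from binary canal/fibrosis masks plus a JSON sidecar
with the dural-sac center; `efgrade aggregate` collapses a per-quadrant
grade table into per-segment percentages; `efgrade simulate` draws
synthetic multi-reader multi-occasion score tables for power/design work.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the scale-conversion percentages for slice sums
1, 2, 4 and 16 (by constructing the corresponding slices and applying the
conversion) and the interobserver ICC of the bundled reading study under
the package's reference analysis, and writes them as JSON.

See `docs/methods.md` for the statistical details, defaults and known
limitations.
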