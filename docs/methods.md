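# Methods

## The pipeline and its assumptions

`ecgstemi` treats STEMI recognition on paper ECGs as two separable
problems: (1) *where* on the page the ST segment is elevated, and (2) *what*
the spatial pattern of elevations implies clinically. Stage 1 is a
detection problem over the 16 lead subregions of a standard single-page
printout (12 short panels in a 3 × 4 grid, column-major lead order
I/II/III, aVR/aVL/aVF, V1–V3, V4–V6, plus a lead-II rhythm strip split into
four even subregions). Stage 2 consumes only the per-lead detection
pattern, which is what makes the system interpretable: every positive call
can be traced to specific boxes in specific leads.

The deterministic detector assumes the page is already cropped to the ECG
region, that the calibration is the universal 25 mm/s and 10 mm/mV, and
that the trace is printed darker than the grid, which is darker than the
paper. It makes no assumptions about heart rhythm beyond R peaks being the
dominant positive deflection and beats being ≥ 300 ms apart.

## ST measurement

Per subregion, digitization proceeds: two-stage Otsu thresholding removes
background and grid (a panel whose darkest pixel is within 100 grey levels
of its lightest is declared traceless); the trace row per pixel column is
the centroid of mask pixels (sub-pixel stable on thick traces); empty
columns are linearly interpolated and flagged invalid; the baseline row is
the modal trace row, which is robust while the trace is isoelectric in most
columns.

Beats are segmented by peak-picking (local maxima above baseline + 0.4 ×
signal range, ≥ 300 ms apart). QRS onset and offset are the first points,
searched within ±80 ms of the R peak, where |dv/dt| stays below 10 % of its
QRS maximum for three consecutive samples; the boundary is placed at the
*end* of that quiet run. The run requirement skips the momentary
zero-slope instant at the S trough, and taking the run's end means the
J-point sample is read where the trace has fully settled — placing it at
the run's start leaves the sample on the QRS recovery flank and biases the
measurement low by ~0.1–0.3 mm.

ST deviation = (v(J point + `j_offset_ms`) − median v over the PR window
[onset − 80 ms, onset − 20 ms]) × gain, in signed millimetres.
`j_offset_ms` defaults to 0 (measurement exactly at the J point, per the
guideline criterion) and is configurable (e.g. 80 ms) for sensitivity
studies. Beats whose PR window or ST sample fall outside the subregion are
flagged unavailable rather than guessed.

## Detection boxes and scores

A beat becomes a detection when its ST deviation exceeds `lesser_floor`
(default 0.5 mm): class `STE` above 1.0 mm, `lesser_STE` in between. The
floor keeps noise-level deflections out of the lesser class, which the
annotation definition bounds only from above. Boxes span [QRS onset −
40 ms, QRS offset + 120 ms] horizontally — covering the QRS complex and ST
segment as the annotation convention requires — and the trace's vertical
extent in that span padded by 2 mm, clipped to the subregion. Border-
clipped beats produce boxes clipped to the subregion.

The confidence score is `sigmoid((st − floor) / 0.25)` with `floor` the
class's lower boundary (1.0 mm for STE, `lesser_floor` for lesser-STE).
This is monotone in the measured evidence, lies in [0, 1], and exercises
the 0.7 score threshold meaningfully: a 2 mm elevation scores ≈ 0.98, a
marginal 1.1 mm elevation ≈ 0.60. An alternative — distance to the
*nearest* boundary — caps the lesser class at sigmoid(1) ≈ 0.73 and would
have the score threshold silently remove almost every lesser detection, so
it was rejected.

Soft-NMS is the Gaussian variant (decay `exp(-iou²/σ)`, σ = 0.5, the
method's customary default) applied within each subregion only: boxes in
different subregions describe different beats and never suppress each
other. With the 0.5 IoU and 0.7 score thresholds the output is provably
idempotent: two same-subregion boxes with IoU > 0.5 cannot both survive,
since the maximal decay factor exp(−0.5) ≈ 0.61 would require an input
score above 1.

The anchor-relative box codec (t_x = (x−x_a)/w_a, t_y = (y−y_a)/h_a,
t_w = log w/w_a, t_h = log h/h_a) is retained and tested standalone so
detections can be exchanged with learned two-stage detectors that
parameterize boxes this way; anchors and feature maps themselves are out of
scope.

## Encodings and clinical logic

The six encodings are fixed-dimension integer aggregates of the post-NMS
detections (see the module docstring of `ecgstemi.encoder` for the table).
Lead-indexed schemes have dimension 12, not 16: detections from the four
rhythm-strip subregions aggregate into lead II, since the clinical criteria
speak of leads, not page regions. Lead order is the canonical I, II, III,
aVR, aVL, aVF, V1–V6, and 24-dim schemes are lead-major with the STE slot
first; the order is recorded in `PipelineConfig` so models and encodings
stay consistent.

Territory rules fire on STE presences only (the lesser class is evidence
for the *classifier*, not for the guideline rules): anterior requires
≥ `anterior_min` of {V1–V4} (default 2 — the "more than one lead" phrasing
read literally, kept configurable because it differs from the "two or
more" phrasing of the other rows), lateral ≥ 2 of {V5, V6, I, aVL},
inferior ≥ 2 of {II, III, aVF}, suspected left-main disease on any aVR
elevation. Rule-based STEMI is definitionally "territory set non-empty";
its score is 1 when a territory fires, else a sub-threshold evidence score
(0.15 per STE lead + 0.05 per lesser lead, capped at 0.49) that keeps the
diagnosis monotone in the evidence without ever crossing the 0.5 decision
threshold on rule-negative patterns.

Territory prediction is multi-label (four independent binary heads),
because occlusions co-occur in real cohorts — the territory counts of the
motivating clinical population sum to more than its STEMI count. The
trainable STEMI classifier defaults to regularized logistic regression;
`learner="ensemble"` fits five heterogeneous base learners (logistic
regression, k-NN, random forest, extra-trees, gradient boosting) weighted
by held-out-AUROC above chance and refit on the full data — the
validation-weighted-averaging concept of AutoML ensembles without
reproducing any particular stack's membership or hyperparameters, which are
not public.

## The synthetic generator

The generator emulates what the downstream pipeline actually measures, not
cardiac electrophysiology. Each beat is a sum of five Gaussians — defaults
P(0.15 mV, 40 ms), Q(−0.1, 15), R(1.2, 20), S(−0.2, 15), T(0.3, 70),
centred at 90/225/250/275/450 ms within the RR interval — plus an ST
plateau between QRS offset and T onset with 20 ms half-cosine ramps placed
*outside* the plateau, so the full injected offset is already present at
the J point where the criterion measures. Heart rate is drawn from
60–95 bpm; R amplitude varies ±10 % per lead.

Case structure: the STEMI fraction defaults to 677/888 and territory
weights to 467/233/123/49 (anterior/lateral/inferior/left-main),
emulating the class structure of a hospital MI cohort; 20 % of STEMI cases
carry two territories. STEMI elevations are drawn uniformly from
1.5–3.0 mm and assigned by `territory_profile` to a random qualifying
subset of the territory's lead set (large enough to satisfy the rule), so
generated labels and the clinical rules close over each other by
construction — a property the acceptance suite verifies on 500 cases.
NSTEMI cases have zero elevation; 30 % carry a single lesser-STE lead at
0.6–0.9 mm, reflecting that minor abnormalities occur without STEMI.

Noise is additive sinusoidal baseline wander (default 0.03 mV at 0.4 Hz,
per-figure phase), per-column vertical jitter (SD 0.4 px), and a grid-
contrast scale. What the generator does *not* model: arrhythmias, ST
depression and T/Q-wave abnormalities, axis deviation, scanner skew or
rotation, ink dropout, and overlapping traces. Passing tests therefore
demonstrate that the pipeline's geometry, calibration, measurement and
logic are correct — not that the detector would reach the same operating
point on real scanned hospital ECGs.

## Evaluation protocol

Detection matching is greedy by score, one-to-one, at IoU ≥ 0.5 (the NMS
IoU reused for evaluation); average precision uses all-point
interpolation. Classification metrics are AUROC (tie-corrected rank
statistic), AUPRC (all-point PR integration), and the thresholded
confusion-matrix set with STEMI as the positive class. Cross-validation is
stratified 5-fold, seeded, reporting per-fold values with mean and
standard deviation. Undefined metrics (no ground truths, single-class
folds, zero denominators) are reported as NaN, never as 0.

Problem sizes in the acceptance suite — 500 cases for rule closure, ~230
beats for elevation recovery, 200 cases for the cross-validated protocol —
were chosen as the package's own desk-scale working conditions: large
enough for stable stochastic checks, small enough to run in well under a
minute each on one CPU.

## Known limitations

* The guideline detector measures a single J-point sample per beat; very
  short ST segments at high heart rates shrink the measurable window.
* Lesser-STE detections near the 0.5 mm floor score below the 0.7 NMS
  score threshold and are filtered; this is the intended behaviour of the
  operating point, but it caps lesser-class sensitivity.
* The digitizer assumes one trace per subregion; overlapping leads or
  annotations drawn over the trace would corrupt the column centroid.
* VOC serialization rounds box coordinates to integer pixels; round trips
  are lossless for integer boxes only.
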