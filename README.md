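# ecgstemi

Clinically interpretable STEMI analysis of **printed 12-lead ECG images**.

In emergency settings the ECG often exists only as a paper printout, yet the
decisive finding for ST-segment-elevation myocardial infarction (STEMI) — an
ST elevation of ≥ 1 mm above baseline at the J point — is read off exactly
that printout. `ecgstemi` implements a two-stage pipeline that mirrors how a
clinician works:

1. **Detect** ST-segment elevation per lead. Each scanned page
   (3 × 4 grid of short lead panels plus a long lead-II rhythm strip,
   16 detection subregions in total) is digitized back into calibrated
   signals (25 mm/s, 10 mm/mV), beats are segmented, and the ST deviation is
   measured at the J point against the PR-segment baseline. Each qualifying
   beat yields a scored bounding box in one of two classes — `STE`
   (> 1 mm) or `lesser_STE` ((0.5, 1] mm) — refined by Gaussian soft
   non-maximum suppression (IoU threshold 0.5, score threshold 0.7).
2. **Classify and localize.** Detections are aggregated into six encodings
   (image- or lead-wise, counts or presences, with or without the lesser
   class). A rule pathway applies the guideline lead-set criteria —
   anterior: ≥ 2 of V1–V4; lateral: ≥ 2 of V5, V6, I, aVL; inferior:
   ≥ 2 of II, III, aVF; suspected left-main disease: STE in aVR — to call
   STEMI vs NSTEMI and the infarction territories; a trainable pathway fits
   scikit-learn-style classifiers (logistic regression or a
   validation-weighted heterogeneous ensemble) on the encodings.

Hospital scans are private, so the package ships a seeded **synthetic
printout generator**: grid background, sum-of-Gaussians PQRST traces with a
controllable ST plateau, per-beat ground-truth boxes, and case labels whose
territory structure is consistent with the clinical rules by construction.
The deterministic guideline detector sits behind a single
`detect(image) -> detections` contract, so a learned object detector can be
slotted in without touching the rest of the pipeline.

## Worked example

```python
import ecgstemi as es

layout = es.build_layout()            # 1228 x 2460 page, 16 subregions
calib = es.CalibrationSpec()          # 25 mm/s, 10 mm/mV, 10 px/mm

spec = es.CaseSpec(
    label="STEMI",
    territories=frozenset({"inferior"}),
    per_lead_st_mV={es.LeadID.II: 0.2, es.LeadID.III: 0.2},  # 2 mm on paper
    seed=7,
)
image, truth = es.render_case(spec, layout, calib)
dets = es.detect(image, layout, calib)

diag, call = es.classify_rule(dets)
vec = es.encode(dets, es.EncodingScheme.LEAD_DETAILED_PRESENCE)
res = es.evaluate_detections([truth], [dets])["STE"]
```

Output:

```
ground-truth boxes: 17, detections: 17
leads with STE: ['II', 'III']
diagnosis: STEMI (score 1.00)
territories: ['inferior']
Lead-Detailed Presence: [0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
STE sensitivity 1.000, AP 1.000
```

The case injects a 2 mm elevation into leads II and III. Every rendered
beat in the qualifying subregions (II and III short panels plus the four
rhythm-strip splits) is detected as an `STE` box; the presence encoding
lights the STE slots of leads II and III (positions 2 and 4 in lead-major
order); two inferior leads satisfy the inferior criterion, so the rule
pathway calls STEMI with the inferior territory.

A command-line interface covers the same pipeline end to end:

```bash
ecgstemi synth --n 200 --seed 1 --out data/
ecgstemi detect --data data/ --out run/
ecgstemi classify --detections run/detections.csv --method rule --out run/
ecgstemi evaluate --pred run/ --data data/ --out run/
ecgstemi crossval --data data/ --scheme "Lead-Detailed Presence" --k 5 --out cv/
```

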