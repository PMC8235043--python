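# gazeaoi

Automatic visual-attention detection for (mobile) eye tracking, plus a
complete segment-based evaluation framework.

Two detection methods map gaze to areas of interest (AOIs):

* **IC** — gaze-guided image classification: the gaze signal is resampled
  (default 5 Hz), a 200×200 px patch around each sample is classified by a
  pluggable backend (top-5 labels with probabilities), similar labels are
  merged by summing probabilities, and the top-1 stream drives a working
  memory of duration/noise counters that emits *attention started /
  confirmed / ended* events. Default setting: `IC-152-300-40`
  (`Tdur = Tnoise = 300 ms`, `Tp = 40%`).
* **OD** — fixation-to-object matching: for each fixation, the frame
  closest to the fixation start is sent to an object-detection backend and
  the fixation centroid is hit-tested against instance bounding boxes
  (`OD-bbox`, default) or segmentation masks (`OD-mask`); multiple hits
  resolve to the highest-probability instance.

Around the detectors the package provides:

* keyframe-interpolated rectangle/polygon AOI tracks and ground-truth
  extraction from fixations (frame-wise hit testing; frames claimed by two
  AOIs go to the AOI with the longer candidate event),
* event/frame error scoring in the style of activity-recognition
  evaluation — insertions, deletions, fragmentations, merges, overfill and
  underfill — with conservative/progressive precision and recall, f1, rate
  decompositions, event-analysis-diagram (EAD) tables/plots, count-based
  aggregation across recordings and a failing-AOI rule (`dr ≥ 90%`),
* a synthetic generator: seeded ground-truth event streams, error-injected
  predictions with **exact** expected error ledgers, noisy gaze traces and
  scripted classifier/detector backends, so the whole pipeline runs and is
  tested fully offline,
* label→AOI mapping tables for the 11 VISUS scenarios (both methods),
  packaged as YAML.

Real CNN backends (ResNet / Mask R-CNN) are deliberately not bundled; the
backend interfaces accept any object with a `top5(request)` /
`detect(frame_index)` method, and scripted backends replay fixture files.

## CLI

```bash
# synthetic fixture set (gaze, fixations, AOI tracks, gt/pred events, ledger)
gazeaoi simulate --out-dir fixtures/ --seed 7

# ground truth from fixations + annotated tracks
gazeaoi ground-truth --fixations fixtures/fixations.csv \
    --tracks fixtures/tracks.json --out gt.jsonl

# IC detection from a scripted prediction stream
gazeaoi detect-ic --gaze fixtures/gaze.csv --video fixtures/tracks.json \
    --scenario "02-turning car" --scripted-predictions preds.csv \
    --t-dur 300 --t-noise 300 --t-prob 0.40 --out events.jsonl

# OD detection from scripted per-frame detections
gazeaoi detect-od --fixations fixtures/fixations.csv --video fixtures/tracks.json \
    --scenario "07-kite" --scripted-detections det.json \
    --object-mask bbox --out events.jsonl

# evaluation (per-AOI metrics CSV, optional EAD table/plot)
gazeaoi evaluate --gt gt.jsonl --pred events.jsonl --fps 25 \
    --out metrics.csv --ead ead.csv --plot ead.png
```

File formats are plain text: gaze/fixation CSV, events JSON Lines, AOI
tracks JSON, scenario YAML; all writers add a provenance header.

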