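# gaitrp

Classification of neurodegenerative gait from vertical ground reaction
force (vGRF) traces via recurrence-plot image encoding.

The pipeline:

1. **synthetic** — simulate labeled two-channel (left/right foot) gait
   force cohorts with class-specific stride regularity, stance fraction
   and double-peak stance pulses (HC / ALS / PD / HD profiles), so the
   whole pipeline runs with no data download.
2. **io** — read/write records as delimited text (three-column,
   two-column, or a comment-tolerant `wfdb-like` dialect); channel
   selection LF / RF / CF (compound foot = LF + RF elementwise).
3. **preprocessing** — drop the first 20 s, cut 10-s rectangular windows
   whose starts are spaced by exactly one third of the window length
   (82 windows from 280 s of signal).
4. **recurrence** — unthresholded recurrence plot
   `P(i,j) = |x_i - x_j| / max(x)` (no embedding, no epsilon), resampled
   to a 227×227 gray-level image.
5. **pca** — optional full-principal-component enhancement of flattened
   images: uncentered `C = XᵀX` diagonalized via the dual (thin-SVD)
   route, `F = XW`, reshaped back to images.
6. **features** — deep-feature extraction (`alexnet-fc7` optional
   backend; deterministic offline `tiny-cnn-test` and
   `random-projection-test` backends) + linear SVM.
7. **evaluation** — leave-one-out cross-validation (window- or
   subject-wise), confusion matrices, accuracy / sensitivity /
   specificity, balanced and rank AUC, Youden's index `J = sens + spec - 1`,
   and Youden-based best-channel selection.

## CLI

```bash
# simulate a cohort of text-file records + manifest
gaitrp simulate --out cohort/ --subjects-per-class 4 --duration 300 --fs 300 --seed 1

# run the full pipeline into a run directory (stages are cached by
# content key; re-running an identical config recomputes nothing)
gaitrp run --run-dir runs/demo --config config.json --seed 1

# stage-wise entry points resume from cached upstream artifacts
gaitrp rp --run-dir runs/demo --config config.json
gaitrp evaluate --run-dir runs/demo --config config.json

# print the metric summary and Youden-selected channels
gaitrp report --run-dir runs/demo
```

The config is a JSON object; any subset of the default keys may be
given (see `gaitrp.pipeline.DEFAULT_CONFIG`): simulation parameters (or
`ingest` for external records), an `exclude_subjects` list, windowing,
RP resolution, the PCA toggle, extractor/classifier specs, CV unit
(`window` mirrors the published setup and the report carries a leakage
warning; `subject` gives honest generalization estimates), channels and
the task grid (seven two-class tasks and the four-class task).

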