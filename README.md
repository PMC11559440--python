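# posturekit

Quality control, preprocessing, summary statistics and subtyping for
continuously recorded inpatient posture telemetry (15-second posture-code
streams from wearable monitors), plus a synthetic cohort generator with
ground truth so the whole pipeline is testable without hospital data.

The pipeline stages:

1. **Ingest** (`posturekit.io`) — read recordings/admissions CSVs, validate
   the 15-s grid, tokenize posture strings.
2. **Clean** (`posturekit.cleaning`) — two-stage exclusion with full flow
   accounting: recordings outside the admission window (inconsistency), then
   colliding recordings at the same patient/timestamp (overlap; exact
   duplicates are deduplicated, ambiguous collisions are fully excluded).
3. **Preprocess** (`posturekit.groups`) — consolidate the raw code alphabet
   into five posture groups (Lying, Reclined, Upright, Unknown,
   UserDefined) and remove isolated single-timestamp flips with a one-pass
   3-window majority vote.
4. **Summarize** (`posturekit.stats`) — per-patient total/analysis days
   (analysis day = ≥22 h = ≥5280 recordings), posture durations for whole
   day / daytime (07:00–18:59) / nighttime windows, transition frequencies
   (transitions per hour among Lying/Reclined/Upright), Rest = Lying +
   Reclined, and the analysis-days-on-total-days regression.
5. **Cluster** (`posturekit.cluster`) — z-score the summary statistics and
   run k-means over k = 2..10, selecting k by average silhouette width;
   four feature sets (WD, DT, NT, combined DT+NT).
6. **Report** (`posturekit.report`) — demographics, quartile tables,
   histogram/scatter exports, and the nurse labor-savings arithmetic.
7. **Simulate** (`posturekit.synth`) — archetype-driven cohort generation
   with injected overlap collisions, out-of-window recordings, incomplete
   days and isolated noise flips, all flagged in a ground-truth sidecar.

## CLI

```sh
# generate a synthetic cohort (YAML config; see tests/test_cli.py for the schema)
posturekit simulate --config cohort.yaml --out data/

# stage by stage
posturekit clean --in data/recordings.csv --admissions data/admissions.csv \
    --out clean.csv --report flow.json
posturekit preprocess --in clean.csv --out groups.csv
posturekit stats --in groups.csv --out summaries.csv
posturekit cluster --in summaries.csv --set wd --seed 1 \
    --out labels.csv --table clusters.csv

# or everything at once
posturekit run --config pipeline.yaml
```

`flow.json` carries the per-stage patient/recording counts and excluded
percentages; `summaries.csv` has one row per retained patient with the 20
summary statistics (columns `Lying-WD` … `FPT-NT`, plus `total_days`,
`analysis_days`, `Rest-DT`, `Rest-NT`).

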