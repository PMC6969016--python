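# scentmark

Detect canid scent-marking postures in pelvis-mounted tri-axial accelerometer
data and map the marks in space and time.

Held marking postures show up as quasi-static gravity projections in the raw
50 Hz signal (left leg raised ≈ −1 g on the sway axis, right leg ≈ +1 g,
squats ≈ −1 g on the surge axis). `scentmark` classifies each raw triaxial
sample with a native k-nearest-neighbour voter, smooths the predictions into
1 Hz modal bins, extracts discrete scent-mark events, georeferences them to a
concurrent GPS track, and derives the downstream spatial indices:

- **home range vs. territory** — percent minimum convex polygons (MCP) over
  all fixes vs. over scent-mark locations only, plus their overlap proportion;
- **overmark revisits** — marks placed within a buffer (default 10 m) of an
  earlier mark, with the revisit interval;
- **extra-territorial forays** — runs of fixes outside the territory MCP,
  timed from first exit fix to last fix before re-entry and split at a
  duration threshold (default 10 min).

A seeded synthetic-data simulator (`scentmark.synthetic`) generates labelled
accelerometer traces and territory-confined GPS tracks with the same
statistical structure, so the whole pipeline is testable without field data.

## CLI

The `scentmark` command exposes three pipeline modes plus per-stage tools:

```sh
# generate a synthetic deployment (accel.csv, labels.csv, gps.csv, truth.geojson)
scentmark simulate -o sim/ --seed 1

# validation experiment: train/test split, k tuning, metrics report
scentmark validate -c config.yaml -o run_val/

# deployment: train on the annotated window, predict, smooth, extract and
# georeference events, compute MCPs / overlap / revisits / forays
scentmark deploy -c config.yaml -o run_dep/
```

Config files are flat YAML mappings of `scentmark.pipeline.RunConfig` fields,
e.g.

```yaml
accel_csv: sim/accel.csv
labels_csv: sim/labels.csv
gps_path: sim/gps.csv
seed: 1
n_scent: 50        # training records per scent class
n_other: 500       # training records of "other" behaviour
folds: 5           # cross-validation folds for the k grid search
min_duration_s: 2  # shortest run of 1 s bins kept as an event
buffer_m: 10       # overmark revisit buffer
mcp_percent: 95
```

Every run writes a `manifest.json` with the seed, parameters, per-stage
record counts and SHA-256 digests of all outputs; identical config + seed
reproduce byte-identical output. Per-stage subcommands (`train`, `predict`,
`evaluate`, `smooth`, `events`, `territory`, `forays`, `revisits`) operate on
the same CSV/GPX/GeoJSON artefacts. Exit codes: 0 success, 1 user error,
2 internal error.

## Formats

- accelerometer CSV: `epoch_s,x_g,y_g,z_g` (units of g; m/s² accepted with a
  flag), nominally 50 Hz, gaps logged;
- annotations CSV: `start_s,end_s,class` half-open intervals; fine labels
  (walk, run, jump, stand, lie, sit, shake) collapse to `other`;
- GPS: CSV (`time,lat,lon`) or GPX 1.1 track; planar analysis happens in a
  local equirectangular frame (exactly invertible at study-site scale);
- outputs: events CSV/GeoJSON, MCP polygons GeoJSON, foray and revisit CSVs,
  metrics JSON.

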