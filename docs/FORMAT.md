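# File formats

## Model directory

```
model_dir/
  manifest.json          # plain-text model manifest (see below)
  layer_01/task_000.joblib
  layer_01/task_001.joblib
  ...
  layer_0K/task_TTT.joblib
  run_manifest.json      # written by `mtfn train`: resolved config + version
  run.log                # training log
```

`manifest.json` keys:

- `format_version` — integer, currently 1; loaders reject other versions.
- `task_order` — list of task names; fixes the column order of every score
  matrix and prediction CSV.
- `params` — forest configuration (`n_estimators`, `max_features_rule`,
  `random_state`).
- `include_own_score` — whether a task's own previous-layer score feeds its
  stacked input.
- `feature_length` — m, the fingerprint width the model expects.
- `n_layers`, `best_layer` — layers stored / layer used by `predict`.
- `per_layer_validation_auc` — per-layer lists of per-task validation AUCs
  (`null` where undefined); `mean_validation_auc` — their means.

One serialized scikit-learn classifier per (layer, task), named
`layer_{k:02d}/task_{t:03d}.joblib` with t indexing `task_order`.
`load(save(model))` reproduces `predict` outputs bit-identically.

## Task manifest CSV

Declares the learning tasks for `train` / `evaluate` / `chemspace` /
`ablate`. Columns: `task_name`, `path` (task CSV, relative paths resolved
against the manifest), `label_col`, `group` (dataset-group name used by
`chemspace` and `ablate --exclude`).

## Task / chemical CSVs

Task data: `chem_id`, `fingerprint` (hex-packed bits, most significant bit
first), `n_bits`, and a label column. Prediction inputs accept the same
layout, or any CSV with a SMILES column via `--smiles-col` (featurized to
ECFP on the fly).

## Score and call CSVs

`mtfn predict` writes `chem_id` plus one probability column per task in
`task_order`; `--calls` writes the same layout with binary calls at
threshold 0.5. `mtfn augment` writes `chem_id`, `fingerprint`, `n_bits`,
then `zf_<task>` binary columns.

## EZ weights YAML

`endpoint: {weight: <nonnegative float>, group: 24hpf|120hpf}` (or plain
`endpoint: weight`). See `examples/ez_weights_uniform.yaml` (uniform
placeholder).
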