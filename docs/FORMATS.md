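# File formats

All delimited-text artifacts begin with a schema header line

    # schema: <name> v<major>

optionally followed by further `# key: value` metadata lines. Readers
reject files whose major version is newer than the one they support.

## spike-table (TSV)

One row per spike.

| column        | type   | meaning                                  |
|---------------|--------|------------------------------------------|
| subject_id    | str    | subject identifier                       |
| trial_id      | str    | trial (wing stroke) identifier           |
| label         | int    | stimulus class, 1–6                      |
| muscle_id     | str    | one of the fixed 10-muscle roster        |
| spike_time_ms | float  | spike time within the trial, ≥ 0         |

Muscle roster (canonical order): L-DLM, L-DVM, L-3AX, L-BA, L-SA, R-DLM,
R-DVM, R-3AX, R-BA, R-SA. Out-of-roster muscles are rejected with the
offending row number. Unknown extra columns are ignored with a warning.

## muscle-roster (TSV)

Sidecar declaring missing muscles: columns `subject_id`, `muscle_id`; one
row per missing (subject, muscle). Missing muscles contribute exact zero
blocks to the assembled features.

## features (TSV)

Header metadata: `# subject: <id>`. Columns: `label`, then `f0 … f{P-1}`.
One row per trial. NaN cells cause rejection with a count of offending
cells.

## eval-report (TSV)

Long form, one row per (cell, repeat): `scenario`, `method`, `source_id`,
`target_id`, `repeat`, `accuracy`. Accuracies are written with 17
significant digits so summaries recomputed from the file are bit-identical.

## loss-trace (TSV)

Columns: `epoch`, `objective`, `wall_time_s`. For CD runs the objective is
the 1-sweep reconstruction MSE (monitoring only).

## rbm-checkpoint (JSON)

```json
{
  "schema": "rbm-checkpoint",
  "version": 1,
  "arrays": {"W": [[..]], "b": [..], "c": [..], "lam": [..]},
  "layout": {"subjects": [..], "dims": [..]},
  "config": { ... training config ... },
  "seed": 0
}
```

## Manifests

Every CLI command writes `<command>.manifest.json` beside its outputs with
the resolved configuration, seed, and package version.

## Importing external archives

The real multi-animal archive's native layout is not standardized here; an
import adapter producing the spike-table/muscle-roster schemas above is the
documented extension point.
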