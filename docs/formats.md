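# File formats

All files are plain text, SI units, comma-separated with a header row.

## Hydraulic field CSV

Columns `x, y, z, u, v, w[, tke][, alpha]` — point coordinates (m), velocity
components (m/s), turbulence kinetic energy (J/kg, default 0), water
fraction (0–1, default 1). Other dialects are ingested via a column map,
e.g. `read_field_table(path, column_map={"u": "Vx"})`. Written by
`trutta synthflow` / `write_field_table`.

## Track CSV

Columns `fish_id, t_s, x_m, y_m, z_m` — one row per record, time strictly
increasing per fish. An optional `group_size` column is carried through.
Round-trips to 1e-9 m / 1e-3 s. Written by `trutta simulate` /
`write_tracks`; read by `read_tracks`.

## Observation workbook (XLSX)

Minute-resolution observation records with columns `fish_id, minute, x_m,
y_m, z_m` (sheet and column names configurable via a column map).
`convert_xlsx_tracks` distributes multiple records within the same minute
evenly over its seconds and emits canonical tracks.

## Run configuration (YAML/JSON)

Top-level keys: `geometry` (any `FlumeGeometry` field), `field`
(`synthetic: {setup, Q, resolution, seed}` or `file` + `column_map`),
`params` (any of the 20 parameter names), `version`, `dt`, `n_fish`,
`seeds`, `out_dir`, `log_level`. Unknown keys are rejected by name.

## Pattern set (JSON)

Keys `p1, p2, p3` (triples, %), `p4, p5` (%), cohort counts `n, n_turns,
n_few_turns, n_D`. `p3` is null when the cohort has no turning fish.

## RMSE table (CSV)

Columns `setup, version, param_set_id, rmse_mean` — one seed-averaged RMSE
per parameter set; consumed by `trutta rank`.

## Provenance (JSON)

`config_sha256, seed, trutta_version, numpy_version` — written next to
simulation outputs so any result can be regenerated from its config + seed.
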