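# Station CSV schema

UTF-8 CSV with a header row. One row per net tow.

## Mandatory columns

| column | type | meaning |
|---|---|---|
| `station_id` | string | opaque station identifier |
| `latitude` | float, [-90, 90] | decimal degrees |
| `longitude` | float | decimal degrees; normalized to [-180, 180) on read |
| `particle_count` | integer ≥ 0 | plastic particles caught |
| `mesh_size_um` | float > 0 | lower mesh size of the net, micrometres |
| `source` | string | dataset label |

## Date (one of)

| columns | meaning |
|---|---|
| `date` | ISO `YYYY-MM-DD` |
| `year`, `month` (+ optional `day`) | day imputed as the 15th when absent |

Dates outside 1979-01-01..2019-12-31 are flagged in `date_out_of_window`
but retained; the trend model picks its own window.

## Tow geometry (one of)

| columns | meaning |
|---|---|
| `swept_area_km2` | precomputed swept sea-surface area, km² > 0 |
| `tow_width_m`, `tow_distance_m` | aperture width (transverse to tow direction) × distance towed, metres > 0; area = width × distance / 10⁶ |

## Optional columns

| column | meaning |
|---|---|
| `net_opening_m` | upper aperture dimension, metres (recorded, not filtered on) |
| `wind_speed_u10_ms` | 10 m wind speed at the station, m s⁻¹ (monthly mean attached upstream); missing treated as calm by the wind stage, with a count |

## Columns added by the pipeline

`swept_area_km2` (resolved), `concentration` (pieces km⁻², NaN while
censored), `censored` (bool, true iff `particle_count == 0`),
`detection_limit` (1/area, censored rows only), `wind_factor`, `basin`,
`expected_z`, `date_out_of_window`.

Malformed rows are reported with their physical line numbers (header =
line 1) and never silently dropped; a missing mandatory column aborts with
the column named.
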