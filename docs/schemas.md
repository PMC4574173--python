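# CSV schemas

All interchange tables are plain CSV with ISO-8601 timestamps
(timezone-naive, 1-s resolution). Written by `bovigas simulate` /
`bovigas all` and consumed by the stage subcommands.

## gas_log.csv
| column | type | unit | notes |
|---|---|---|---|
| timestamp | datetime | — | on the 15-s sampling grid |
| ch4_ppm | float | ppm | raw concentration at the inlet |
| co2_ppm | float | ppm | raw concentration at the inlet |

## visit_log.csv
| column | type | unit | notes |
|---|---|---|---|
| visit_id | str | — | unique, time-ordered |
| cow_id | str | — | |
| entry_time / exit_time | datetime | — | half-open [entry, exit) |
| concentrate_kg_dm | float | kg DM | dispensed this visit |
| milk_kg | float | kg | milked this visit |

## cow_table.csv
| column | type | unit | notes |
|---|---|---|---|
| cow_id | str | — | |
| bw_kg | float | kg | one record per cow-year |
| parity | str | — | primiparous / multiparous |
| days_pregnant | int | days | 0 = open |
| milk_kg_day | float | kg/day | |
| fat_pct / protein_pct | float | % | |
| concentrate_kg_dm | float | kg DM/day | daily total |

## background_windows.csv
date, start, end — the daily ~10-min instrument-disconnection windows
used for barn-background estimation.

## ground_truth_cow.csv / ground_truth_cow_day.csv
Simulation-only: `cow_id, cow_effect` (multiplicative, mean 1) and
`cow_id, date, realized_ratio`.

## ratios_{sample,visit,day,period}.csv
`cow_id, [date, visit_id, timestamp, hour_of_day,] ratio, n` — the
CH₄:CO₂ ratio at each aggregation level; `n` counts the units averaged
(samples per visit, visits per day, days per period).

## daily_phenotypes.csv
| column | unit |
|---|---|
| cow_id, date, year | — |
| ratio | — |
| n_visits | count |
| hp_watts | W |
| co2_l_day, ch4_l_day | L/day |
| edmi_kg_day, ecm_kg_day | kg/day |
| ch4_per_edmi, ch4_per_ecm | L/kg |
| ch4_std_l_day, ratio_std | L/day, — (at 30 kg/day ECM) |
| parity, bw_kg, milk_kg_day, days_pregnant | as cow table |

## variance_report.csv
`response, year, mean, cv_bc, cv_wc, r_within, r_between_years, n_cows,
n_obs, fixed_effects` — one row per response per year.

## diurnal_profile_y{1,2}.csv
`hour, adjusted_mean, se, interval, n` — adjusted hourly CH₄ (L/h).

## cv_by_level.csv
`level, cv_pct, n_units` — pooled CV at each aggregation level.

## manifest.json
Config snapshot, package version, `generated_at`, SHA-256 checksums of
the written input tables, and per-stage row counts.
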