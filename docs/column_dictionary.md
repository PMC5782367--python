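# Cohort CSV column dictionary

All tables are comma-separated UTF-8 with a header row. Keys:
`patient_id` is an opaque string; `icu_day` is days since ICU admission
(integer ≥ 1); `(patient_id, icu_day)` identifies one study occasion.

## patients.csv — one row per patient

| column | type | constraints / units |
|---|---|---|
| patient_id | str | unique |
| sex | str | category (e.g. F/M) |
| age | float | years, > 0 |
| bmi | float | kg/m², > 0 |
| admission_weight | float | kg |
| diagnosis_class | str | `medical` or `surgical` |

## occasions.csv — one row per study occasion

| column | type | constraints / units |
|---|---|---|
| patient_id | str | must exist in patients.csv |
| icu_day | int | ≥ 1; unique per patient |
| hematocrit | float | strictly inside (0, 1) |
| sofa | int | optional |
| kcal_per_kg_day | float | optional, kcal/kg/24 h |
| aa_g_per_kg_day | float | optional, g amino acid/kg/24 h |

## samples.csv — one row per (occasion, minute, site)

| column | type | constraints / units |
|---|---|---|
| patient_id, icu_day | | occasion reference |
| minute | int | one of 135, 140, 145, 150 |
| site | str | `artery` or `vein` |
| phe_ttr | float | phenylalanine tracer-to-tracee ratio, [0, 1) |
| mh3_ttr | float | 3-methylhistidine TTR, [0, 1) |
| mh3 | float | 3-methylhistidine plasma concentration, µmol/L ≥ 0 |
| ala … val | float | one column per amino acid (lowercase 3-letter code), plasma concentration µmol/L ≥ 0; `phe` is mandatory |

## biopsies.csv — at most one row per occasion

| column | type | constraints / units |
|---|---|---|
| patient_id, icu_day | | occasion reference |
| phe_ttr_muscle | float | intracellular free-phe TTR, [0, 1); occasions without a biopsy simply have no row (two-pool results are still computed) |

## plethysmography.csv — one row per occlusion reading

| column | type | constraints / units |
|---|---|---|
| patient_id, icu_day | | occasion reference |
| phase | str | `pre` or `post` (relative to the sampling period) |
| reading_index | int | 1..10 within a phase |
| slope_pct_per_min | float | limb-volume slope, % per minute, ≥ 0 and finite |

## Outputs

`kinetics.csv`: per occasion — PF, blood_flow, NB, Rd, Ra, NB3, Rd3,
Ra3, F_MA, F_VM, F_VA, F_M0, F_0M, total_aa_flux, total_arterial, and
flags (qc_flag, inverted_gradient, three_pool_flag). `aaflux.csv`: long
format, one row per occasion × amino acid plus a `total` row.
`stats_report.csv`: per outcome — β0, β1, SE, p, σ_b, σ_e, zero-crossing
day ± SE, sensitivity-refit summary. `comparison_report.csv`: per
outcome — group sizes, medians, quartiles, U, p.
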