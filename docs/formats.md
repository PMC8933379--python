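# Data formats

All files are comma-separated UTF-8 text with dot decimal separators and a
header row. Parsing is strict: locale commas, blank required fields or
unknown codes are reported with 1-based line numbers, never guessed.

## Concentration table

One row per sample.

| column | type | notes |
|---|---|---|
| subject_id | text | |
| sequence | text | `IV_then_oral` or `oral_then_IV` |
| period | int | 1 or 2 |
| treatment | text | `oral` or `iv`; must match the dose route |
| analyte | text | `parent` or `metabolite` |
| nominal_time_h | float | protocol time, h |
| actual_time_h | float | used for all computation, h |
| conc_ng_ml | float | ≥ 0; BLQ rows carry 0 |
| blq | int | 0/1; 1 forces the concentration to 0 |

Within a subject-period-analyte, actual times must be strictly increasing
after sorting; duplicates are rejected.

## Dose table

One row per subject-period.

| column | type | notes |
|---|---|---|
| subject_id | text | |
| period | int | 1 or 2 |
| treatment | text | `oral` or `iv` |
| route | text | `oral` or `iv_infusion` |
| dose_mg | float | > 0 |
| infusion_duration_h | float | required > 0 for `iv_infusion`, empty for oral |

## NCA parameter table (output)

One row per subject-period-analyte: identifiers, `dose_mg`, `cmax`, `tmax`,
`auc_last`, `auc_inf`, `auc_extrap_pct`, `t_half`, `cl_or_clf`,
`vz_or_vzf`, `vss`, `mrt`, `kel`, `lambda_z_n`, `lambda_z_r2`,
`well_characterized`, `reason`. Terminal-phase-dependent columns are empty
when the phase is not well characterized.

## Scenario file (simulator input)

Plain `key = value` lines, `#` comments. Recognised keys: the population
fields (`n_compartments`, `cl_typ`, `v_central_typ`, `v_peripheral_typ`,
`q_intercompartmental`, `ka_typ`, `f_oral_true`, `sigma_prop`, `lloq`,
`omega_cl`) and template fields (`n_subjects`, `oral_dose_mg`,
`iv_dose_mg`, `infusion_duration_h`, `washout_days`,
`period2_exposure_ratio`, `sequence_exposure_ratio`,
`sequence_allocation` as `;`-separated codes).
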