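# File formats

All tabular artifacts are CSV with one header-comment line
`# saccs-format v1 seed=<seed>`; nested state is JSON with a
`format_version` field.  Units everywhere: angles in degrees, times in
milliseconds, contrasts as linear proportions (0.66 = 66%), sensitivities
as log10 CS.

## Gaze trace CSV (one trial)

```
t_ms,x_px,y_px,valid
0.0,959.8,600.2,1
1.0,960.1,599.7,1
```

`valid = 0` marks track loss (blink).  Times are non-decreasing from trial
onset; positions are screen pixels.

## Trial / session / study log CSV

One row per trial attempt.  Columns: `trial_id, meridian_deg,
orientation_deg, is_catch, contrast, fixation_ms, saccade_correct,
keyboard_correct, beta_g_deg, exit_time_ms, false_positive, status`.
Study-level logs prepend `participant, mode, eccentricity_deg,
spatial_freq_cpd`.  `status` is `done` or `repeated` (blink); catch rows
carry an empty `contrast`.

```
trial_id,meridian_deg,orientation_deg,is_catch,contrast,fixation_ms,...
0,90,135,False,0.0123,561.2,True,True,92.4,384.0,False,done
```

## QUEST+ state JSON

`thresholds` (natural-log contrasts), `slopes`, `gamma_fixed`, `lam_fixed`,
`stimulus_domain` (linear contrasts), `posterior` (row-major
thresholds × slopes), `trial_count`, `location_label`.

## Observer config JSON

Flat fields of the generative model plus `csf_table` keyed
`"<meridian>:<eccentricity>"`, each value `{gamma_max, sf_max, beta}`.

## Fit outputs

`psychometric_fits.csv`: one row per (participant, channel,
eccentricity_deg, spatial_freq_cpd, meridian_deg) with `m, w, lam, log_cs,
boundary`.  `csf_fits.csv`: one row per (participant, channel,
eccentricity_deg, meridian_deg) with `gamma_max, sf_max, beta`.

## Report bundle

Directory with `triplets.csv` (paired log CS per cell across the three
channels), `correlations.csv` (`pair, r, n`), `bland_altman.csv`
(`pair, bias, sd_diff, loa_lower, loa_upper, n`), `location_summary.csv`
(median/mean ± SD log CS per channel × meridian × eccentricity) and
`summary.json`.
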