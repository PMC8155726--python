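# File formats

All pipeline outputs are plain CSV/JSON.

## cohort.csv
One row per accepted subject.

| column | units | meaning |
|---|---|---|
| subject_id | — | `s00000`… in acceptance order |
| class | — | `normotensive` / `hypertensive` |
| brSBP, brDBP, brPP, MAP | mmHg | brachial systolic/diastolic/pulse/mean pressure |
| aoSBP, aoDBP, aoPP | mmHg | aortic root pressures |
| SV | mL | stroke volume |
| HR | bpm | heart rate |
| Zao_true | mmHg·s/mL | analytic aortic characteristic impedance |
| CT_true | mL/mmHg | analytic total arterial compliance |
| TPR | mmHg·s/mL | mean aortic pressure / cardiac output |
| cfPWV, crPWV | m/s | tangent-method carotid-femoral / carotid-radial PWV |
| cf_path_length, cr_path_length | m | tree-path travel lengths |

## waveforms/ (optional)
`<subject>_pressure_<site>.csv` and `<subject>_flow_aortic_root.csv`,
two columns `time_s,value` (mmHg or mL/s), one cardiac period.

## features_noisy.csv
Same columns as cohort.csv with every feature column (and, by default, the
target columns) multiplied by independent U[0.85, 1.15] factors.

## model_report.csv
One row per family × target × configuration: slope, intercept, r, p, rmse,
nrmse_pct, bias, loa_low, loa_high on the held-out test set.

## hyperparameters.csv, importances.csv, learning_curve_*.csv, sensitivity.csv, cfpwv_only.csv
Chosen hyperparameters per M1 model; permutation importances
(mean ± SD RMSE increase per feature and target); train/validation RMSE per
training size; test nRMSE per training fraction; the single-input baseline
report.

## classical.csv / classical_report.csv
Per-subject classical estimates (`zao_tdp`, `zao_pf`, `ct_dtm`, `ct_ppm`
with ground truths) and their agreement statistics (per-method mean ± SD,
min/max percent error, r, RMSE, nRMSE, Bland-Altman bias and limits).

## manifest.json
Package version, the full configuration snapshot (seeds included), and per
stage the wall-clock seconds and sha256 of every output file.

## Model directory (`pwvest train --out DIR`)
`results.joblib` (fitted results object), `model.json` (family, target,
configuration, chosen hyperparameters, seeds), `report.json` (test-set
agreement), `train_ids.csv` / `val_ids.csv` / `test_ids.csv`.

## results/acceptance.json
Flat JSON: `{"<key>": {"value": <number>, "n": <sample size>}}` for the
headline quantities recomputed by `scripts/acceptance.py`.
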