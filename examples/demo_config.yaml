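# Demo pipeline configuration: run `paspectrum simulate --outdir demo --seed 1
# --n-subjects 300` first, then `paspectrum all --config examples/demo_config.yaml`.
# Repetition counts here are reduced from the full-scale defaults
# (1000 CV / 10000 permutations / 10000 bootstrap) for a quick demo run.
epochs_dir: demo/epochs
cohort_csv: demo/cohort.csv
out_dir: demo/output

filter_low_hz: 0.29
filter_high_hz: 10.0
filter_order: 4
night_start: "23:00"
night_end: "06:00"
nonwear_window_min: 60
nonwear_allowance_min: 2
cuts_mg: [40, 360, 710, 1065]

responses: [mets, z_bmi, z_sbp, z_dbp, z_hdl, z_ir]
a_max: 10
cv_reps: 200
n_perm: 500
perm_reps: 40
n_boot: 1000
holdout_fraction: 0.2
cutoff_sd: 0.5
seed: 1

# secondary x-axis: bin intensity -> metabolic equivalents
secondary_axis:
  - {intensity_mg: 40, MET: "1.5"}
  - {intensity_mg: 360, MET: "3"}
  - {intensity_mg: 710, MET: "6"}
  - {intensity_mg: 1065, MET: "9"}
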