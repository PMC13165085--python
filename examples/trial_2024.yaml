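# Demonstration trial configuration: first-campaign layout, stress onset
# on day 3, default spectral scenario.  Run:
#   vinestress report --config examples/trial_2024.yaml --out scratch/demo
design:
  preset: "2024"
  seed: 0
scenario:
  stress_onset_day: 3
preprocess:
  window: 11
  polyorder: 2
  mean_center_scope: per_plant_all_days
monitor:
  k: 3
  alpha: 0.01
refstats:
  alpha: 0.01
trim_max_wavelength: 980.0
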