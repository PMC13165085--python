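"""Simulate a seeded vineyard trial and look at what it contains.

Builds the first-campaign layout (18 vines, 8 control / 10 stress, 5
acquisition days, 10 pixels per vine and day), generates the spectrum
table, stem-potential records and onset ground truth, and prints the
dataset's shape and the irrigation arithmetic.
"""

import vinestress as vs

design = vs.design_2024(seed=0)
scenario = vs.default_scenario(stress_onset_day=3)
table, psi_records, truth = vs.generate_trial(design, scenario)

print(f"spectra: {len(table)} rows "
      f"({design.n_plants} plants x {len(design.days)} days x "
      f"{design.pixels_per_plant_day} pixels)")
print(f"bands per spectrum: {len(table.columns) - 4}")
print(f"psi records: {len(psi_records)}")
stressed = {p: d for p, d in truth.items() if d is not None}
print(f"stressed plants: {len(stressed)}, true onset day: "
      f"{sorted(set(stressed.values()))}")
dose = vs.irrigation_dose(design.irrigation_minutes_per_day, design.emitter_rate)
print(f"control irrigation dose: {dose} L/day "
      f"({design.irrigation_minutes_per_day:g} min at {design.emitter_rate} L/h)")
# 900 rows, 204 bands; every stressed vine starts changing on day 3 here.
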