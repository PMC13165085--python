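"""Per-day reference statistics on stem water potential.

Simulates Ψ trajectories (controls stationary near -0.55 MPa, stressed
vines dropping toward -0.90 MPa from day 3), then runs the reference
analysis: normality screening, log transform where needed, one-way ANOVA
at the 99% confidence level, and Duncan's multiple range test.
"""

import pandas as pd

import vinestress as vs
from vinestress.refstats import comparisons_to_frame, reference_table

design = vs.design_2024(seed=0)
records = vs.simulate_stem_potential(design, vs.default_scenario(stress_onset_day=3))
psi = pd.DataFrame(
    [(r.plant_id, r.group, r.day, r.psi) for r in records],
    columns=["plant_id", "group", "day", "psi_MPa"],
)
frame = comparisons_to_frame(reference_table(psi, alpha=0.01))
print(frame.to_string(index=False))
# Expected pattern: 'ns' on days 1-2 (groups indistinguishable), '*' from
# day 3 on, with Duncan letters separating the groups once Ψ diverges.
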