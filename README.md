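# vinestress

Early detection of water stress in individual grapevines from proximal
VIS–NIR (400–1000 nm) hyperspectral time series — for viticulture and
plant-phenotyping researchers who image potted or field vines repeatedly
and want a per-plant, label-free change statistic rather than a trained
classifier.

## The method

Each vine is its own reference. Its spectra from all acquisition days are
preprocessed (SNV → Savitzky–Golay 11/2 → per-plant mean centering,
noisy NIR tail trimmed), stacked, and projected into the vine's own PCA
space (k = 3 components by default). The first day's score cloud defines
a baseline — centroid μ̄_ref and sample covariance Σ_ref — and every
later pixel's divergence from it is the squared Mahalanobis distance

    MD² = (μ_t − μ̄_ref)ᵀ Σ_ref⁻¹ (μ_t − μ̄_ref).

For each day t > 1, a two-sided Mann–Whitney U test compares the day-t
MD² distribution with day 1's (computed leave-one-out so the comparison
is calibrated). The vine's **change day** is the earliest day with
p < 0.01, defaulting to the last trial day when none is significant.
Wavelength importance comes from |PC1 loadings|; stem-water-potential
(Ψ, MPa) reference tables are built with Lilliefors screening, a log|Ψ|
transform where needed, one-way ANOVA and Duncan's multiple range test.

No field imagery is publicly deposited for the trials this pipeline
operationalizes, so a seeded synthetic-scene generator (first-class,
tested code) emulates them: vegetation continua with pigment absorption
wells (445/550/680 nm), a logistic red edge, a 970 nm water well,
day-to-day illumination drift, heteroscedastic NIR noise, and
treatment-dependent stress ramps with a known onset day. See
`docs/methods.md` for every modeling choice.

## Worked example

```bash
python examples/02_monitor_change_days.py
```

simulates the 18-vine, 5-day campaign with stress onset on day 3 and
monitors every vine:

```
plant  group    change_day  defaulted  true_onset
P01   control      5      True      None
...
P09   stress       3      False     3
...
P18   stress       3      False     3
control: mean change day 5.0 +- 0.0 (n=8)
stress: mean change day 3.0 +- 0.0 (n=10)
```

Every stressed vine is flagged on the true onset day; controls show no
significant divergence and default to the last day — the stressed group's
mean change day is two days earlier. `examples/03_wavelength_importance.py`
perturbs only the water well and prints the top PC1 range
`923.1–979.3 nm (peak 961.6)`: the monitor attributes the change to water
content. `examples/04_stem_potential_stats.py` prints the per-day Ψ table
with the `ns, ns, *, *, *` significance pattern as the groups diverge.

Other entry points: `examples/01_simulate_trial.py` (trial generation and
irrigation arithmetic), `examples/05_cube_io_and_sampling.py` (ENVI-style
cube I/O, dark/white reflectance correction, mask-random pixel sampling),
and a thin CLI:

```bash
vinestress report --config examples/trial_2024.yaml --out scratch/demo
```

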