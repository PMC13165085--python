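# Methods

## Problem and model

`vinestress` monitors individual grapevines for the onset of water stress
from VIS–NIR (400–1000 nm) hyperspectral reflectance time series. The core
idea: each vine is its own reference. Spectra from all acquisition days of
one plant are preprocessed, stacked and projected into that plant's own PCA
score space; the first day's score cloud defines the baseline condition;
and the divergence of every later pixel from that baseline is measured by
the squared Mahalanobis distance

    MD² = (μ_t − μ̄_ref)ᵀ Σ_ref⁻¹ (μ_t − μ̄_ref),

where μ_t is a pixel's score vector on day t, μ̄_ref the day-1 score
centroid and Σ_ref the day-1 sample covariance (n−1 denominator). A
per-day two-sided Mann–Whitney U test compares the day-t MD² distribution
with the day-1 MD² distribution; the plant's *change day* is the earliest
day with p < α (default α = 0.01), defaulting to the trial's last day when
no day is significant. Group behaviour is summarized as the mean ± sd of
change days per treatment group, and wavelength importance is read off
each plant's first principal component.

Assumptions: the day-1 state is unstressed; within-day pixel-to-pixel
variation is exchangeable; illumination varies multiplicatively between
days (removed by SNV); and stress expresses as a coherent shift of spectral
shape, not merely of brightness.

## Preprocessing

The chain is SNV → Savitzky–Golay smoothing → mean centering.

- **SNV** standardizes each spectrum to mean 0 / sd 1 (sample sd, n−1 —
  the chemometrics convention), removing per-spectrum gain and offset.
- **Savitzky–Golay**: 11-point window, order 2, zeroth derivative.
  Edges use scipy's polynomial-fit scheme (`mode="interp"`: one
  least-squares polynomial over each terminal window, no mirroring), so
  polynomials of degree ≤ 2 pass through unchanged everywhere.
- **Mean centering** is computed per plant over the plant's full
  day-stacked matrix (`per_plant_all_days`). This is the only scope under
  which all days of a plant share one centered space, so that day-1 scores
  can act as a baseline for later days; a `per_plant_per_day` scope is
  implemented for comparison but destroys the between-day signal by
  construction.
- **Band trimming**: the noisy NIR tail is cut before analysis —
  default cutoff 980 nm for the 10-pixel campaign layout and 926 nm for
  the noisier 100-pixel one (both configurable). On the default 204-point
  linear grid the 926 nm cutoff retains 178 bands.

## Monitoring choices

- **k = 3 retained components** by default (a ≥95 %-variance rule,
  `k="var95"`, is available). The change-day ordering of treatment groups
  is stable across k = 2, 3, 4 on the default scenario (tested).
- **Per-day test**: Mann–Whitney U on per-pixel MD², two-sided, robust to
  the strongly skewed MD² distribution. MD² is computed per pixel and the
  distributions compared, which is what yields a defensible per-day
  significance statement at 10–100 pixels per day.
- **Day-1 comparison sample is leave-one-out.** In-sample MD² of the
  points that built the baseline is biased low (their mean is exactly
  k(n−1)/n, while a new point's expectation is (n+1)(n−1)k/(n(n−k−2)));
  testing day-t values against in-sample day-1 values would therefore
  reject far too often under no change. Each day-1 pixel is instead scored
  against the baseline refitted without it, making day-1 and day-t MD²
  exchangeable under the null and the rank test calibrated: the measured
  per-plant false-alarm rate, ≈4 % over 4 tested days at α = 0.01, matches
  the theoretical 1 − 0.99⁴ ≈ 3.9 % of the uncorrected earliest-crossing
  rule. `mahalanobis_md2` itself keeps the plain in-sample definition,
  which satisfies the exact identity Σ MD² = (n−1)k over the baseline.
- **No multiple-testing correction across days**: the earliest-crossing
  rule is the monitoring semantics; its family-wise error is quantified
  (above) rather than corrected away.
- **Numerics**: PCA via SVD with a deterministic sign convention (each
  loading's largest-magnitude element positive); MD² via Cholesky solve,
  never an explicit inverse; Σ_ref ridge-regularized on the diagonal by
  ε·trace/k (ε = 1e−6) only when its condition number exceeds 1e8;
  degenerate baselines (zero covariance) raise instead of being patched.
- **Wavelength importance**: bands with |PC1 loading| above the 80th
  percentile, merged across gaps of ≤2 bands, ranked by peak loading.

## Reference statistics (stem water potential)

Ψ (MPa, strictly negative) is compared between groups day by day:
Lilliefors-type Kolmogorov–Smirnov normality screening of the pooled
group-centered residuals (parameters estimated from the sample; p-values
by seeded Monte-Carlo with 10,000 replicates, cached per sample size, so
results are deterministic); when normality is rejected at 0.05, the
analysis switches to ln|Ψ| (Ψ is strictly negative, so magnitudes are
logged — the order reverses, which affects no F statistic or letter).
Then a classical one-way ANOVA at α = 0.01 and Duncan's multiple range
test, with critical values from the studentized-range quantile function
(protection level 1 − (1 − α)^(p−1) for a span of p ordered means,
harmonic-mean group size), so arbitrary error degrees of freedom are
supported without printed tables. Group means ± sd are always reported on
the original MPa scale.

## The synthetic-scene generator

No field imagery is deposited with the study this pipeline operationalizes,
so trials are emulated. A vegetation spectrum is a continuum (0.12) plus a
logistic red edge (inflection 715 nm, steepness 12 nm, NIR plateau +0.38)
minus Gaussian absorption wells at 445, 550, 680 and 970 nm (depths 0.060,
0.030, 0.070, 0.080) — reproducing the two well-separated VIS reflectance
valleys and the NIR water feature of real leaf spectra. Stress deepens the
wells: each has a `stress_gain` (0.020, 0.012, 0.030, 0.035) multiplied by
a severity ramp that is 0 before the plant's onset day, 0.6 on the onset
day, and rises linearly to 1.0 by the last day. Days differ by a
multiplicative illumination factor (lognormal, sd 0.05); pixels differ by
a multiplicative gain (lognormal, sd 0.03); additive band noise has sd
0.004 below 900 nm and 0.020 above it (5:1, the noisy spectral tail).
All randomness derives from one root seed through named substreams
(illumination / spectra / potentials / cube / sampling), so each module's
draws are independently reproducible.

Two design presets mirror the study's campaigns: 18 plants × 5 days ×
10 pixels (8 control / 10 stress, full deprivation → 900 spectra) and
18 × 7 × 100 (9/9, dose reduced to a third → 12,600 spectra). Irrigation
arithmetic: 28 min/day at 2.3 L/h = 1.07 L/day.

Stem potentials: controls draw from N(−0.55, 0.08) MPa on every day;
stressed plants track the control mean before onset, then step down by
0.25 MPa at onset and ramp linearly to −0.90 MPa by the last day. The
step-plus-ramp (rather than a pure linear decline from the control level)
matches the contrast magnitude a deprivation trial shows on the first day
stress is physiologically established (≈ −0.67 vs −0.42 MPa, a ≈6σ
group contrast) — a pure linear decline would make the onset-day contrast
a coin flip at α = 0.01 with 8–10 plants per group, which is not how such
trials read. Spectral severity and Ψ are parameterized independently; no
quantitative Ψ↔reflectance link is modeled.

What the generator does *not* emulate: radiative transfer (no leaf-optics
model), canopy geometry, leaf veins, weather, or any Ψ–spectrum coupling.
Passing tests therefore show that the statistical machinery recovers
changes of the assumed form at realistic sizes and noise levels — not that
real vineyard imagery has that form.

### Synthetic cubes and sampling

`generate_cube` renders a raw-count scene (elliptical leaf mask over a
bright sloped soil background, per-band dark ≈80 and white ≈2400–3100
counts) that round-trips through the ENVI-dialect I/O and the dark/white
reflectance correction R = (raw − dark)/(white − dark). Pixel sampling
draws uniformly inside the mask after excluding saturated pixels (any
band at the sensor ceiling) and pixels above the 90th brightness
percentile — an explicit, configurable surrogate for selecting shadowed
leaf area by eye; uniformity over eligible pixels is χ²-tested.

## Problem sizes used in the checks

The recovery checks run at the first campaign's own sizes (18 plants ×
5 days × 10 pixels): 500 single-plant null trials for the false-alarm
rate, 100 full trials for change-day recovery and group ordering, 100
trials (stressed plants only) for the 970 nm loadings attribution. These
complete in about two minutes on one CPU.

## Known limitations

- The Mann–Whitney day test needs ≥ ~8 pixels/day for a two-sided p below
  0.01 to be attainable at all; the 10-pixel layout is near that floor.
- With 10 baseline pixels and k = 3, leave-one-out MD² has a heavy upper
  tail (a mildly atypical baseline pixel scores large when left out),
  which is what occasionally delays detection by a day at moderate effect.
- Duncan letters use the harmonic-mean group size; for strongly unbalanced
  groups the usual caveats of range tests apply.
- `per_plant_per_day` centering and the diagonal-Σ_ref option exist for
  sensitivity analysis, not as recommended settings.
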