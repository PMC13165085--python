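"""Seeded synthetic vineyard trials with a known stress-onset ground truth.

No imagery from the original pot trials is publicly deposited, so the
pipeline is exercised on generated scenes that carry the statistical
structure the analysis assumes: per-plant vegetation reflectance built
from a continuum, Gaussian pigment absorption wells (~445, ~550, ~680 nm),
a logistic red edge (~700-740 nm) and a water well (~970 nm); day-to-day
multiplicative illumination drift; heteroscedastic noise (stronger above a
NIR cutoff); and treatment-dependent stress trajectories that deepen the
pigment/water wells from a known onset day onward.  Stem-water-potential
tables with matching treatment divergence are generated alongside.

All randomness flows from the trial seed through named substreams, so
spectra, cubes and potentials are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hsi_io import HyperCube, ReferencePair
from .tables import make_table

__all__ = [
    "TrialDesign",
    "AbsorptionFeature",
    "SpectralScenario",
    "StemPotentialRecord",
    "design_2024",
    "design_2025",
    "default_scenario",
    "water_only_scenario",
    "generate_trial",
    "generate_cube",
    "simulate_stem_potential",
    "irrigation_dose",
    "reflectance_spectrum",
]

# Named substreams off the root trial seed.
_STREAMS = {"illumination": 0, "spectra": 1, "potentials": 2, "cube": 3, "sampling": 4}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Independent generator for a named component of the trial."""
    return np.random.default_rng([int(seed), _STREAMS[name], *map(int, extra)])


@dataclass
class TrialDesign:
    """Who was imaged, when, and under which irrigation treatment.

    ``irrigation_minutes_per_day`` and ``emitter_rate`` (L/h) describe the
    drip schedule of the control dose; stressed plants receive
    ``stress_dose_fraction`` of it (0 = full deprivation).
    """

    year_label: str
    n_plants: int
    group_of_plant: dict[str, str]  # plant id -> "control" | "stress"
    days: list[int]
    pixels_per_plant_day: int
    irrigation_minutes_per_day: float = 28.0
    emitter_rate: float = 2.3
    stress_dose_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("trial must have at least one acquisition day")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly ordered and unique")
        if self.pixels_per_plant_day < 2:
            raise ValueError("need >= 2 pixels per plant/day to estimate covariance")
        if len(self.group_of_plant) != self.n_plants:
            raise ValueError(
                f"{self.n_plants} plants declared but {len(self.group_of_plant)} assigned"
            )
        bad = {g for g in self.group_of_plant.values()} - {"control", "stress"}
        if bad:
            raise ValueError(f"unknown group labels {bad}")
        if not 0.0 <= self.stress_dose_fraction <= 1.0:
            raise ValueError("stress_dose_fraction must lie in [0, 1]")

    @property
    def plants(self) -> list[str]:
        return list(self.group_of_plant)

    def plants_in(self, group: str) -> list[str]:
        return [p for p, g in self.group_of_plant.items() if g == group]


@dataclass(frozen=True)
class AbsorptionFeature:
    """Gaussian absorption well: depth subtracted from the continuum.

    ``stress_gain`` is the extra depth (reflectance units) added at full
    stress severity; pigment/water wells deepen as severity ramps up.
    """

    center: float  # nm
    width: float  # nm (Gaussian sigma)
    depth: float  # reflectance units
    stress_gain: float = 0.0


@dataclass
class SpectralScenario:
    """Generative model of per-pixel vegetation reflectance.

    Reflectance = continuum + logistic red edge - sum of Gaussian wells,
    scaled by a per-day illumination factor and a per-pixel gain, plus
    band-dependent white noise (``noise_sd_nir`` above ``nir_cutoff``).
    Stress multiplies each well's ``stress_gain`` by a severity ramp that
    is 0 before the onset day.
    """

    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(400.0, 1000.0, 204)
    )
    continuum_level: float = 0.12
    absorption_features: list[AbsorptionFeature] = field(
        default_factory=lambda: [
            AbsorptionFeature(445.0, 22.0, 0.060, stress_gain=0.020),
            AbsorptionFeature(550.0, 28.0, 0.030, stress_gain=0.012),
            AbsorptionFeature(680.0, 20.0, 0.070, stress_gain=0.030),
            AbsorptionFeature(970.0, 35.0, 0.080, stress_gain=0.035),
        ]
    )
    red_edge: tuple[float, float, float] = (715.0, 12.0, 0.38)  # inflection, steepness, plateau
    stress_onset_day: int | dict[str, int] = 3
    severity_per_day: dict[int, float] | None = None  # explicit override
    onset_severity: float = 0.6  # severity on the onset day itself
    illumination_scale_per_day: dict[int, float] | None = None
    illumination_drift_sd: float = 0.05  # lognormal sd when scales are drawn
    pixel_gain_sd: float = 0.03  # per-pixel multiplicative variability
    noise_sd_vis: float = 0.004
    noise_sd_nir: float = 0.020  # 5:1 vs VIS, mimicking the noisy spectral tail
    nir_cutoff: float = 900.0

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        wl = self.wavelength_grid
        if wl[0] > 400.0 or wl[-1] < 1000.0:
            # grid must span the camera's VIS-NIR range
            if not (wl[0] <= 400.0 + 1e-9 and wl[-1] >= 1000.0 - 1e-9):
                raise ValueError("wavelength grid must span 400-1000 nm")
        for f in self.absorption_features:
            if not 0.0 <= f.depth <= self.continuum_level + self.red_edge[2]:
                raise ValueError(f"feature depth {f.depth} outside valid range")
        if self.noise_sd_nir < self.noise_sd_vis:
            raise ValueError("NIR noise must be >= VIS noise")

    def onset_for(self, plant_id: str) -> int:
        if isinstance(self.stress_onset_day, dict):
            return self.stress_onset_day[plant_id]
        return int(self.stress_onset_day)

    def severity(self, day_position: int, onset_position: int, n_days: int) -> float:
        """Severity at a 1-based day position; 0 strictly before onset.

        Default ramp: ``onset_severity`` on the onset day, rising linearly
        to 1.0 on the last day.
        """
        if self.severity_per_day is not None:
            return 0.0 if day_position < onset_position else float(
                self.severity_per_day.get(day_position, 1.0)
            )
        if day_position < onset_position:
            return 0.0
        span = max(n_days - onset_position, 1)
        frac = (day_position - onset_position) / span
        return min(1.0, self.onset_severity + (1.0 - self.onset_severity) * frac)

    def noise_sd(self) -> np.ndarray:
        sd = np.full_like(self.wavelength_grid, self.noise_sd_vis)
        sd[self.wavelength_grid >= self.nir_cutoff] = self.noise_sd_nir
        return sd


@dataclass(frozen=True)
class StemPotentialRecord:
    """One pressure-chamber reading: xylem tension in MPa (negative)."""

    plant_id: str
    day: int
    psi: float
    group: str

    def __post_init__(self) -> None:
        if self.psi >= 0:
            raise ValueError("stem water potential must be negative (MPa)")


def design_2024(seed: int = 0, pixels_per_plant_day: int = 10) -> TrialDesign:
    """First-campaign layout: 18 vines (8 control, 10 stress), 5 days,
    10 manually picked pixels per vine and day, full water deprivation."""
    groups = {f"P{i + 1:02d}": ("control" if i < 8 else "stress") for i in range(18)}
    return TrialDesign(
        year_label="2024",
        n_plants=18,
        group_of_plant=groups,
        days=[1, 2, 3, 4, 5],
        pixels_per_plant_day=pixels_per_plant_day,
        stress_dose_fraction=0.0,
        seed=seed,
    )


def design_2025(seed: int = 0, pixels_per_plant_day: int = 100) -> TrialDesign:
    """Second-campaign layout: 18 vines (9/9), 7 days, 100 mask-random
    pixels per vine and day, stressed dose reduced to a third."""
    groups = {f"P{i + 1:02d}": ("control" if i < 9 else "stress") for i in range(18)}
    return TrialDesign(
        year_label="2025",
        n_plants=18,
        group_of_plant=groups,
        days=[1, 2, 3, 4, 5, 6, 7],
        pixels_per_plant_day=pixels_per_plant_day,
        stress_dose_fraction=1.0 / 3.0,
        seed=seed,
    )


def default_scenario(**overrides) -> SpectralScenario:
    return SpectralScenario(**overrides)


def water_only_scenario(**overrides) -> SpectralScenario:
    """Scenario in which stress perturbs only the ~970 nm water well,
    for attributing wavelength importance to a single known feature."""
    scn = SpectralScenario(**overrides)
    scn.absorption_features = [
        replace(f, stress_gain=(f.stress_gain if abs(f.center - 970.0) < 1 else 0.0))
        for f in scn.absorption_features
    ]
    return scn


def reflectance_spectrum(scenario: SpectralScenario, severity: float = 0.0) -> np.ndarray:
    """Noise-free, unit-illumination reflectance on the scenario grid."""
    wl = scenario.wavelength_grid
    infl, steep, plateau = scenario.red_edge
    r = scenario.continuum_level + plateau / (1.0 + np.exp(-(wl - infl) / steep))
    for f in scenario.absorption_features:
        depth = f.depth + severity * f.stress_gain
        r = r - depth * np.exp(-0.5 * ((wl - f.center) / f.width) ** 2)
    return np.clip(r, 1e-4, None)


def _illumination_scales(
    design: TrialDesign, scenario: SpectralScenario
) -> dict[int, float]:
    if scenario.illumination_scale_per_day is not None:
        return {d: float(scenario.illumination_scale_per_day[d]) for d in design.days}
    rng = substream(design.seed, "illumination")
    draws = np.exp(rng.normal(0.0, scenario.illumination_drift_sd, len(design.days)))
    return dict(zip(design.days, draws))


def generate_trial(
    design: TrialDesign, scenario: SpectralScenario
) -> tuple[pd.DataFrame, list[StemPotentialRecord], dict[str, int | None]]:
    """Simulate a full trial: spectrum table, Ψ records, true onset days.

    Returns one spectrum per (plant, day, pixel) — row count is exactly
    ``n_plants x |days| x pixels_per_plant_day`` — plus stem-potential
    records per plant and day, and a map plant -> onset day (None for
    controls).  Identical seeds give identical output.
    """
    n_days = len(design.days)
    illum = _illumination_scales(design, scenario)
    rng = substream(design.seed, "spectra")
    noise_sd = scenario.noise_sd()
    wl = scenario.wavelength_grid

    onset_map: dict[str, int | None] = {}
    keys_rows = []
    spectra_rows = []
    for plant in design.plants:
        group = design.group_of_plant[plant]
        onset = scenario.onset_for(plant) if group == "stress" else None
        onset_map[plant] = onset
        for pos, day in enumerate(design.days, start=1):
            sev = 0.0
            if onset is not None:
                onset_pos = design.days.index(onset) + 1
                sev = scenario.severity(pos, onset_pos, n_days)
            base = reflectance_spectrum(scenario, sev)
            gains = np.exp(
                rng.normal(0.0, scenario.pixel_gain_sd, design.pixels_per_plant_day)
            )
            noise = rng.normal(
                0.0, 1.0, (design.pixels_per_plant_day, wl.size)
            ) * noise_sd
            block = illum[day] * gains[:, None] * base[None, :] + noise
            spectra_rows.append(block)
            for px in range(design.pixels_per_plant_day):
                keys_rows.append((plant, group, day, px))

    keys = pd.DataFrame(keys_rows, columns=["plant_id", "group", "day", "pixel_id"])
    table = make_table(keys, np.vstack(spectra_rows), wl)
    records = simulate_stem_potential(design, scenario)
    return table, records, onset_map


def simulate_stem_potential(
    design: TrialDesign,
    scenario: SpectralScenario,
    control_mean: float = -0.55,
    control_sd: float = 0.08,
    onset_drop: float = 0.25,
    final_psi: float = -0.90,
    stress_sd: float = 0.08,
) -> list[StemPotentialRecord]:
    """Per-plant, per-day Ψ (MPa): controls stationary around
    ``control_mean``; stressed plants track the control mean before onset,
    then step down by ``onset_drop`` and ramp to ``final_psi`` by the last
    day — the divergence pattern a deprivation trial shows once stress has
    set in."""
    rng = substream(design.seed, "potentials")
    records = []
    last_pos = len(design.days)
    for plant in design.plants:
        group = design.group_of_plant[plant]
        onset = scenario.onset_for(plant) if group == "stress" else None
        for pos, day in enumerate(design.days, start=1):
            if onset is None or day < onset:
                mu, sd = control_mean, control_sd
            else:
                onset_pos = design.days.index(onset) + 1
                frac = (pos - onset_pos) / max(last_pos - onset_pos, 1)
                stepped = control_mean - onset_drop
                mu = stepped + frac * (final_psi - stepped)
                sd = stress_sd
            psi = min(rng.normal(mu, sd), -0.05)
            records.append(StemPotentialRecord(plant, day, float(psi), group))
    return records


def generate_cube(
    design: TrialDesign,
    scenario: SpectralScenario,
    plant_id: str,
    day: int,
    shape: tuple[int, int] = (64, 64),
) -> tuple[HyperCube, np.ndarray, ReferencePair]:
    """Render one raw-count scene for a plant/day: cube, leaf mask, refs.

    Vegetation pixels inside an elliptical leaf mask follow the scenario
    (with the plant's severity for that day); background pixels follow a
    distinct soil-like continuum.  Dark/white reference frames are
    returned so the cube round-trips through reflectance calibration.
    Same design seed gives bit-identical output.
    """
    if plant_id not in design.group_of_plant:
        raise KeyError(f"unknown plant id {plant_id!r}")
    if day not in design.days:
        raise KeyError(f"unknown acquisition day {day!r}")
    rows, cols = shape
    plant_index = design.plants.index(plant_id)
    day_index = design.days.index(day)
    rng = substream(design.seed, "cube", plant_index, day_index)

    wl = scenario.wavelength_grid
    sev = 0.0
    if design.group_of_plant[plant_id] == "stress":
        onset_pos = design.days.index(scenario.onset_for(plant_id)) + 1
        sev = scenario.severity(day_index + 1, onset_pos, len(design.days))
    leaf = reflectance_spectrum(scenario, sev)
    soil = 0.18 + 0.25 * (wl - wl[0]) / (wl[-1] - wl[0])  # bright sloped background

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    mask = (
        ((rr - rows / 2) / (0.38 * rows)) ** 2 + ((cc - cols / 2) / (0.30 * cols)) ** 2
    ) <= 1.0
    if not mask.any():
        raise ValueError("leaf mask contains no vegetation pixels")

    refl = np.where(mask[:, :, None], leaf[None, None, :], soil[None, None, :])
    gains = np.exp(rng.normal(0.0, scenario.pixel_gain_sd, (rows, cols)))
    refl = refl * gains[:, :, None]
    refl += rng.normal(0.0, 1.0, refl.shape) * scenario.noise_sd()

    dark = np.full(wl.size, 80.0)
    white = 2400.0 + 1.2 * (wl - wl[0])  # lamp curve, counts
    counts = refl * (white - dark)[None, None, :] + dark[None, None, :]
    cube = HyperCube(
        data=counts.astype(np.float32),
        wavelengths=wl.copy(),
        meta={"plant id": plant_id, "acquisition day": day,
              "integration mode": "automatic"},
    )
    return cube, mask, ReferencePair(dark=dark, white=white)


def irrigation_dose(
    minutes_per_day: float, rate_L_per_h: float, fraction: float = 1.0
) -> float:
    """Daily water supply in litres: minutes/60 x emitter rate x dose
    fraction, rounded to 2 decimals for reporting."""
    if minutes_per_day < 0 or rate_L_per_h < 0 or fraction < 0:
        raise ValueError("irrigation inputs must be nonnegative")
    if fraction > 1:
        raise ValueError("dose fraction cannot exceed 1")
    return round(minutes_per_day / 60.0 * rate_L_per_h * fraction, 2)
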