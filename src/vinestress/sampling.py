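"""Per-plant, per-day pixel selection and spectrum extraction.

Two selection modes mirror field practice: a manual coordinate list, and
uniform-random draws inside a leaf mask.  Random selection excludes
saturated pixels (any band at the sensor ceiling) and the brightest mask
pixels — a stated, configurable surrogate for picking only shadowed leaf
area.  Vein avoidance is not emulated; synthetic masks contain no veins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsi_io import HyperCube
from .tables import make_table

__all__ = ["PixelSelection", "sample_pixels", "extract_spectra"]

#: default sensor ceiling (16-bit counts)
SATURATION_LEVEL = 65535.0


@dataclass
class PixelSelection:
    plant_id: str
    day: int
    mode: str  # "manual" | "mask_random"
    coordinates: list[tuple[int, int]]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "mask_random"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ValueError("coordinates must be unique")

    def to_json_dict(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "day": self.day,
            "mode": self.mode,
            "coordinates": [list(c) for c in self.coordinates],
            "seed": self.seed,
        }


def sample_pixels(
    cube: HyperCube,
    mask: np.ndarray,
    n: int,
    seed: int,
    plant_id: str = "",
    day: int = 0,
    saturation_level: float = SATURATION_LEVEL,
    brightness_quantile: float = 0.90,
) -> PixelSelection:
    """Draw ``n`` distinct uniform-random in-mask pixels.

    Eligibility excludes (a) saturated pixels — any band at or above
    ``saturation_level`` — and (b) pixels whose band-mean brightness is
    strictly above the ``brightness_quantile`` of the remaining in-mask
    pixels (the shadowed-area proxy).  Deterministic for a given seed.
    Raises ``ValueError`` if fewer than ``n`` pixels remain eligible.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial extent")
    if not mask.any():
        raise ValueError("mask is empty")
    saturated = (cube.data >= saturation_level).any(axis=2)
    ok = mask & ~saturated
    if ok.any():
        brightness = cube.data.mean(axis=2)
        cutoff = np.quantile(brightness[ok], brightness_quantile)
        ok = ok & ~(brightness > cutoff)
    rows, cols = np.nonzero(ok)
    if rows.size < n:
        raise ValueError(f"only {rows.size} eligible pixels for n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    coords = [(int(rows[i]), int(cols[i])) for i in idx]
    return PixelSelection(plant_id=plant_id, day=day, mode="mask_random",
                          coordinates=coords, seed=seed)


def extract_spectra(
    cube: HyperCube, selection: PixelSelection, group: str = ""
) -> pd.DataFrame:
    """Copy the spectra at the selected coordinates into table rows.

    One row per coordinate, band values unmodified, keyed by
    (plant, day, pixel index in selection order).
    """
    rows, cols, _ = cube.data.shape
    for r, c in selection.coordinates:
        if not (0 <= r < rows and 0 <= c < cols):
            raise IndexError(f"coordinate ({r}, {c}) outside cube bounds")
    spectra = np.stack(
        [cube.data[r, c, :].astype(float) for r, c in selection.coordinates]
    )
    keys = pd.DataFrame(
        {
            "plant_id": selection.plant_id,
            "group": group,
            "day": selection.day,
            "pixel_id": np.arange(len(selection.coordinates)),
        }
    )
    return make_table(keys, spectra, cube.wavelengths)
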