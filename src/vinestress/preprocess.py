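"""Spectral pre-treatment chain: SNV, Savitzky-Golay smoothing, mean centering.

The chain runs in that order.  SNV standardizes each spectrum to mean 0 /
sd 1, removing multiplicative scatter and illumination effects;
Savitzky-Golay (11 points, order 2 by default) suppresses band-to-band
noise; mean centering is applied per plant over the plant's full
day-stacked matrix, so that all days of one plant live in a common
centered space — the only scope under which day-1 scores can serve as a
baseline for later days.  A per-day centering scope is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .tables import spectra_matrix, wavelength_columns

__all__ = ["PreprocessConfig", "snv", "smooth", "mean_center", "preprocess_table"]


@dataclass
class PreprocessConfig:
    snv: bool = True
    window: int = 11
    polyorder: int = 2
    mean_center_scope: str = "per_plant_all_days"  # or "per_plant_per_day"

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed polynomial order")
        if self.mean_center_scope not in ("per_plant_all_days", "per_plant_per_day"):
            raise ValueError(f"unknown centering scope {self.mean_center_scope!r}")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: (x - mean) / sd with the sample (n-1) sd.

    Invariant to per-spectrum gain and offset.  Accepts a vector or a
    (rows x bands) matrix transformed row-wise.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim == 1:
        return snv(x[None, :])[0]
    if x.shape[1] < 2:
        raise ValueError("spectrum must have >= 2 bands")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum has zero spread; SNV undefined")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def smooth(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing (zeroth derivative).

    Edges are handled by a least-squares polynomial fit over the terminal
    window (no mirroring), so polynomials of degree <= ``polyorder`` pass
    through unchanged everywhere.
    """
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    return savgol_filter(x, window, polyorder, axis=-1, mode="interp")


def mean_center(matrix: np.ndarray) -> np.ndarray:
    """Subtract column (band) means; output columns average to zero."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("mean centering needs a matrix with >= 2 rows")
    return m - m.mean(axis=0, keepdims=True)


def preprocess_table(table: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Run the full chain on a spectrum table, returning a new table.

    SNV and smoothing act per row; centering is grouped by plant (and by
    day as well under the ``per_plant_per_day`` scope).
    """
    config = config or PreprocessConfig()
    cols, _ = wavelength_columns(table)
    X, _ = spectra_matrix(table)
    if config.snv:
        X = snv(X)
    X = smooth(X, config.window, config.polyorder)

    out = table.copy()
    out[cols] = X
    group_keys = ["plant_id"]
    if config.mean_center_scope == "per_plant_per_day":
        group_keys.append("day")
    for _, idx in out.groupby(group_keys, sort=False).groups.items():
        out.loc[idx, cols] = mean_center(out.loc[idx, cols].to_numpy(dtype=float))
    return out
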