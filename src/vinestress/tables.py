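"""Long-form spectrum tables: the pipeline's working currency.

A spectrum table is a :class:`pandas.DataFrame` with the key columns
``plant_id, group, day, pixel_id`` followed by one column per wavelength
(column name = wavelength in nm, e.g. ``"702.97"``).  One row = one pixel
spectrum on one acquisition day.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

KEY_COLUMNS = ["plant_id", "group", "day", "pixel_id"]


def wavelength_columns(table: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Return (column names, wavelengths as floats) for the spectral columns."""
    cols, wls = [], []
    for c in table.columns:
        if c in KEY_COLUMNS:
            continue
        try:
            wls.append(float(c))
            cols.append(c)
        except (TypeError, ValueError):
            continue
    return cols, np.asarray(wls)


def spectra_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (rows x bands) spectral matrix and its wavelength grid."""
    cols, wls = wavelength_columns(table)
    return table[cols].to_numpy(dtype=float), wls


def make_table(
    keys: pd.DataFrame, spectra: np.ndarray, wavelengths: np.ndarray
) -> pd.DataFrame:
    """Assemble a spectrum table from key columns and a spectral matrix."""
    wl_cols = [f"{w:.2f}" for w in wavelengths]
    spec = pd.DataFrame(np.asarray(spectra, dtype=float), columns=wl_cols,
                        index=keys.index)
    return pd.concat([keys, spec], axis=1)


def save_table(table: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    """Write a table to CSV with an optional leading provenance comment."""
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
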