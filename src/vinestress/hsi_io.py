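"""ENVI-dialect hyperspectral cube I/O and reflectance calibration.

A cube is a ``rows x cols x bands`` array with a strictly increasing
wavelength grid (nm).  On disk it is the pair the camera writes: a text
header (``key = value`` lines plus a ``wavelength = { ... }`` block) and a
flat little-endian binary in BSQ or BIL interleave.  Raw sensor counts are
converted to reflectance against dark/white reference frames; values above
1 (specular highlights) are kept, not clipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HyperCube",
    "ReferencePair",
    "read_cube",
    "write_cube",
    "to_reflectance",
    "trim_bands",
]

# ENVI numeric codes for the sample formats the camera family emits.
_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


@dataclass
class HyperCube:
    """Reflectance or raw-count cube with its wavelength grid and metadata."""

    data: np.ndarray  # (rows, cols, bands)
    wavelengths: np.ndarray  # (bands,), nm, strictly increasing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """Dark (sensor noise) and white (maximal reflectance) reference frames.

    Either per-band vectors or full spatial frames; frames are averaged
    over their spatial extent before use, because the white plate is a
    scene-level reference.
    """

    dark: np.ndarray
    white: np.ndarray

    def per_band(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatially averaged (dark, white) per-band vectors."""
        dark = np.asarray(self.dark, dtype=float)
        white = np.asarray(self.white, dtype=float)
        if dark.ndim > 1:
            dark = dark.reshape(-1, dark.shape[-1]).mean(axis=0)
        if white.ndim > 1:
            white = white.reshape(-1, white.shape[-1]).mean(axis=0)
        return dark, white


def _format_header(cube: HyperCube, interleave: str, dtype: np.dtype) -> str:
    rows, cols, bands = cube.data.shape
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    for key, val in cube.meta.items():
        lines.append(f"{key} = {val}")
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    lines.append("wavelength = {" + wl + "}")
    return "\n".join(lines) + "\n"


def write_cube(
    cube: HyperCube,
    hdr_path: str | Path,
    bin_path: str | Path,
    interleave: str = "bsq",
    dtype: str | np.dtype = "float32",
) -> None:
    """Serialize a cube to an ENVI-style header + flat binary pair."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    Path(hdr_path).write_text(_format_header(cube, interleave, dtype))
    data = cube.data.astype(dtype)
    if interleave == "bsq":  # (bands, rows, cols)
        arr = np.transpose(data, (2, 0, 1))
    else:  # bil: (rows, bands, cols)
        arr = np.transpose(data, (0, 2, 1))
    arr = np.ascontiguousarray(arr, dtype=dtype.newbyteorder("<"))
    Path(bin_path).write_bytes(arr.tobytes())


def _parse_header(text: str) -> dict:
    # wavelength (and any other brace block) may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    out: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        out[key.strip().lower()] = val.strip()
    return out


def read_cube(hdr_path: str | Path, bin_path: str | Path) -> HyperCube:
    """Read an ENVI-style header/binary pair into a :class:`HyperCube`.

    Raises ``ValueError`` if the header lacks a wavelength list or the
    binary's byte count disagrees with the declared dimensions.
    """
    hdr = _parse_header(Path(hdr_path).read_text())
    try:
        cols = int(hdr["samples"])
        rows = int(hdr["lines"])
        bands = int(hdr["bands"])
        code = int(hdr["data type"])
        interleave = hdr["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"header missing required field: {exc}") from exc
    if "wavelength" not in hdr:
        raise ValueError("header missing wavelength list")
    wl_text = hdr["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if code not in _DTYPES:
        raise ValueError(f"unsupported data type code {code}")
    dtype = np.dtype(_DTYPES[code]).newbyteorder("<")
    raw = Path(bin_path).read_bytes()
    expected = rows * cols * bands * dtype.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"binary holds {len(raw)} bytes, header implies {expected}"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    meta = {
        k: v
        for k, v in hdr.items()
        if k
        not in {
            "samples", "lines", "bands", "data type", "interleave",
            "byte order", "header offset", "file type", "wavelength",
        }
    }
    return HyperCube(data=np.array(data), wavelengths=wavelengths, meta=meta)


def to_reflectance(raw: HyperCube, refs: ReferencePair) -> HyperCube:
    """Dark/white-correct raw counts: R = (raw - dark) / (white - dark).

    References are averaged to per-band scalars first.  Output may exceed
    1 for specular pixels; no clipping is applied.
    """
    dark, white = refs.per_band()
    if dark.shape != (raw.n_bands,) or white.shape != (raw.n_bands,):
        raise ValueError("reference band count does not match cube")
    denom = white - dark
    if np.any(denom <= 0):
        bad = raw.wavelengths[denom <= 0]
        raise ValueError(f"white <= dark at wavelengths {bad[:5]}...")
    data = (raw.data.astype(float) - dark) / denom
    meta = dict(raw.meta)
    meta["calibration"] = "reflectance"
    return HyperCube(data=data, wavelengths=raw.wavelengths.copy(), meta=meta)


def trim_bands(obj, max_wavelength: float):
    """Drop bands at or above ``max_wavelength`` (nm), keeping grid/data aligned.

    Works on a :class:`HyperCube` or on a long-form spectrum table
    (:class:`pandas.DataFrame` with one column per wavelength).  The noisy
    NIR tail of field spectra is removed this way before analysis.
    """
    if isinstance(obj, HyperCube):
        keep = obj.wavelengths < max_wavelength
        if not keep.any():
            raise ValueError("no bands retained below cutoff")
        return HyperCube(
            data=obj.data[:, :, keep],
            wavelengths=obj.wavelengths[keep],
            meta=dict(obj.meta),
        )
    if isinstance(obj, pd.DataFrame):
        from .tables import wavelength_columns

        cols, wls = wavelength_columns(obj)
        keep_cols = [c for c, w in zip(cols, wls) if w < max_wavelength]
        if not keep_cols:
            raise ValueError("no bands retained below cutoff")
        other = [c for c in obj.columns if c not in cols]
        return obj[other + keep_cols].copy()
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")
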