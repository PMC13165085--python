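"""From a raw-count hypercube to a spectrum table.

Renders a synthetic scene for one vine/day, writes and re-reads it in the
ENVI-style dialect, converts counts to reflectance with the dark/white
references, samples 10 in-mask pixels (excluding saturated and brightest
pixels), and extracts their spectra.
"""

import tempfile
from pathlib import Path

import vinestress as vs
from vinestress.sampling import extract_spectra, sample_pixels

design = vs.design_2024(seed=0)
cube, mask, refs = vs.generate_cube(design, vs.default_scenario(), "P01", 1)
print(f"cube: {cube.shape[0]}x{cube.shape[1]} pixels, {cube.n_bands} bands; "
      f"leaf mask covers {mask.sum()} pixels")

with tempfile.TemporaryDirectory() as tmp:
    hdr, raw = Path(tmp) / "scene.hdr", Path(tmp) / "scene.raw"
    vs.write_cube(cube, hdr, raw, interleave="bil")
    cube = vs.read_cube(hdr, raw)  # lossless round trip

refl = vs.to_reflectance(cube, refs)
print(f"reflectance range: {refl.data.min():.3f} - {refl.data.max():.3f}")

sel = sample_pixels(refl, mask, n=10, seed=0, plant_id="P01", day=1,
                    saturation_level=1.5)
table = extract_spectra(refl, sel, group="control")
print(f"extracted {len(table)} spectra at coordinates {sel.coordinates[:3]}...")
# The table rows are the same currency generate_trial produces, ready for
# preprocessing and monitoring.
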