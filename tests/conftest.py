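import numpy as np
import pytest

import vinestress as vs
from vinestress.hsi_io import trim_bands


@pytest.fixture(scope="session")
def small_design():
    """Six-plant, four-day miniature trial for fast unit tests."""
    groups = {f"P{i:02d}": ("control" if i <= 3 else "stress") for i in range(1, 7)}
    return vs.TrialDesign(
        year_label="mini",
        n_plants=6,
        group_of_plant=groups,
        days=[1, 2, 3, 4],
        pixels_per_plant_day=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_trial(small_design):
    scenario = vs.default_scenario(stress_onset_day=3)
    return vs.generate_trial(small_design, scenario)


@pytest.fixture(scope="session")
def preprocessed_2024():
    """One full first-campaign trial, trimmed and preprocessed."""
    design = vs.design_2024(seed=11)
    table, psi, truth = vs.generate_trial(design, vs.default_scenario())
    pre = vs.preprocess_table(trim_bands(table, 980.0))
    return design, pre, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
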