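import json
from pathlib import Path

import pytest
from hypothesis import settings

from gwqual import worked_cohort
from gwqual.chemistry import WaterSample

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def cohort():
    """The shipped 5-sample hand-checked fixture."""
    return worked_cohort()


@pytest.fixture(scope="session")
def expected():
    """Frozen outputs of the independent spreadsheet-style oracle."""
    return json.loads((DATA / "worked_cohort_expected.json").read_text())


@pytest.fixture
def mean_sample():
    """A sample at the survey's mean composition (mg/L)."""
    return WaterSample(
        site_id="MEAN", ph=7.64, ec=830.13, tds=562.83, turbidity=7.99,
        hardness=285.8,
        ions={"Na": 61.87, "K": 3.57, "Ca": 65.0, "Mg": 34.89, "Cl": 81.43,
              "SO4": 156.67, "HCO3": 183.33, "CO3": 0.19, "NO3": 2.61,
              "F": 0.55},
    )
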