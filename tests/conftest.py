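import numpy as np
import pandas as pd
import pytest

from apexds.simulate import bear_scenario, simulate_survey
from apexds.tables import SurveyDesign


@pytest.fixture(scope="session")
def default_survey():
    """One default aerial bear survey (~150 detections), shared read-only."""
    obs, design, truth = simulate_survey(bear_scenario(seed=42))
    return obs, design, truth


@pytest.fixture()
def toy_design():
    t = pd.DataFrame({"transect": ["t1", "t2", "t3"],
                      "length_km": [1.0, 1.0, 2.0],
                      "stratum": ["all"] * 3})
    return SurveyDesign(t, w=400.0, area_km2=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
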