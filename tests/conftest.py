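import dataclasses

import pytest

from mammosim import make_default_params
from mammosim.params import (ClinicalDetectionParams, GrowthParams,
                             SensitivityParams, SpreadFunction, StageModel,
                             SurvivalParams, make_life_table)


@pytest.fixture(scope="session")
def default_params():
    return make_default_params(seed=7)


@pytest.fixture(scope="session")
def immortal_life_table():
    """qx = 0 below 109 (forced terminal death): isolates screening logic
    from competing mortality."""
    return make_life_table(0.0, 0.0, 0.1)


def scripted_params(**overrides):
    """Fully deterministic parameter set for hand-traceable histories.

    Onset is forced just past age 45 (a huge hazard spike in that year),
    the tumor is invasive at onset with a fixed growth rate (lognormal sd
    0), never spreads, never surfaces clinically, and screens detect with
    certainty.  Individual pieces can be overridden per test.
    """
    import numpy as np

    hazard = np.zeros(110)
    hazard[45] = 1e12
    base = make_default_params(seed=3)
    params = dataclasses.replace(
        base,
        life_table=make_life_table(0.0, 0.0, 0.1),
        onset_hazard=hazard,
        growth=GrowthParams(log_mean=np.log(0.3), log_sd=0.0, d0=5.0, dmax=128.0),
        insitu_fraction=0.0,
        stage_model=StageModel(nodal=SpreadFunction.flat(0.0),
                               distant=SpreadFunction.flat(0.0)),
        sensitivity=SensitivityParams(smax=1.0, d50=-1000.0, k=0.45, insitu=1.0),
        clinical_detection=ClinicalDetectionParams(c0=0.0, dref=15.0),
        fp_recall_rate=0.0,
        survival=SurvivalParams(
            cure={"0": 1.0, "1": 0.9999, "2A": 0.9998, "2B": 0.9997,
                  "3": 0.9996, "4": 0.9995},
            rate={"0": 0.01, "1": 0.02, "2A": 0.03, "2B": 0.04,
                  "3": 0.05, "4": 0.06}),
    )
    params = dataclasses.replace(params, **overrides)
    return params.validate()


@pytest.fixture()
def traceable_params():
    return scripted_params()


def zero_screen_params(params):
    """Variant in which screening can have no effect: zero sensitivity for
    invasive and in-situ disease and zero false-positive recalls."""
    return dataclasses.replace(
        params,
        sensitivity=dataclasses.replace(params.sensitivity, smax=0.0, insitu=0.0),
        fp_recall_rate=0.0,
    )
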