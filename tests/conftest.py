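import numpy as np
import pandas as pd
import pytest

from oxprof import panel
from oxprof.synthetic import CohortConfig, GroupSpec, SubunitModel


def make_config(
    seed: int,
    *,
    groups=None,
    intercept=0.0,
    slope=1.0,
    resid_sd=0.25,
    vdac_mean=5.0,
    vdac_sd=0.5,
    deficits=None,
    label_correlation=0.0,
) -> CohortConfig:
    regression = {
        s: SubunitModel(intercept=intercept, slope=slope, resid_sd=resid_sd)
        for s in panel.SUBUNITS
    }
    return CohortConfig(
        seed=seed,
        groups=groups or [GroupSpec("control", 10, 45, 0)],
        regression=regression,
        vdac_mean=vdac_mean,
        vdac_sd=vdac_sd,
        deficits=deficits or {},
        label_correlation=label_correlation,
    )


@pytest.fixture
def control_config():
    """Control-only cohort: a=0, b=1, s=0.25, 10 cases x 45 neurons."""
    return make_config(1)


@pytest.fixture
def five_point_xy():
    """The 5-point OLS fixture with frozen normal-equation oracle values."""
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([0.1, 0.9, 2.1, 2.9, 4.0])
    oracle = {
        "slope": 0.98,
        "intercept": 0.04,
        "s_resid": 0.10954451150103342,
        "s_perp": 0.0677561791747736,
        "s_vert": 0.09486832980505154,
        "sxx": 10.0,
        "x_mean": 2.0,
    }
    return x, y, oracle


@pytest.fixture
def five_point_table(five_point_xy):
    """Neuron table whose ln-ln scatter for NDUFB8 is the 5-point fixture."""
    x, y, oracle = five_point_xy
    data = {
        "neuron_id": [f"n{i}" for i in range(len(x))],
        "case_id": "control01",
        "group": "control",
        "age": 70.0,
        panel.MASS_TARGET: np.exp(x),
    }
    for s in panel.SUBUNITS:
        data[s] = np.exp(y)
    return pd.DataFrame(data), oracle
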