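import numpy as np
import pandas as pd
import pytest

from physioclock import SimDesign, generate_control_timecourse


@pytest.fixture(scope="session")
def default_design():
    return SimDesign(seed=1)


@pytest.fixture(scope="session")
def control_data(default_design):
    """Planted-trend control time course: 2000 probes, 19 samples."""
    expr, meta, truth = generate_control_timecourse(
        default_design, drop_day3_outlier=True)
    return expr, meta, truth


@pytest.fixture(scope="session")
def null_design():
    """Global null: no probe has any age trend."""
    return SimDesign(frac_aging=0.0, n_mutant_specific=0, seed=7)


@pytest.fixture(scope="session")
def null_data(null_design):
    expr, meta, truth = generate_control_timecourse(
        null_design, drop_day3_outlier=True)
    return expr, meta, truth


@pytest.fixture()
def tiny_expr():
    return pd.DataFrame(
        np.array([[2.0, 3.0], [4.0, 5.0], [6.0, 7.0]]),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=["s1", "s2"],
    )
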