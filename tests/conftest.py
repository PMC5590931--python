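import numpy as np
import pytest

from ozotox import GrowthTrajectory, fit_lgm, gen_study


@pytest.fixture(scope="session")
def a549_tables():
    """Default A549 study bundle, fixed seed."""
    return gen_study("A549", seed=0)


@pytest.fixture(scope="session")
def hs27_tables():
    return gen_study("Hs27", seed=0)


@pytest.fixture(scope="session")
def rise_fall_control():
    """Control viability means with the study's rise-then-fall shape
    (normalised units, peak at 48 h, 50% drop by 72 h)."""
    return GrowthTrajectory([0.0, 24.0, 48.0, 72.0], [1.0, 2.2, 3.6, 1.8])


@pytest.fixture(scope="session")
def fitted_control(rise_fall_control):
    """Time-varying-scenario fit of the rise-then-fall control curve."""
    return fit_lgm(rise_fall_control, scenario="time_varying", seed=0)


@pytest.fixture
def csv_bundle(tmp_path, a549_tables):
    """The A549 bundle written out as the three CSV files."""
    paths = {}
    for name, df in a549_tables.items():
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
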