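import numpy as np
import pytest

from reachofc.finite_horizon import fit_kinematic_condition
from reachofc.plant import PlantParams, build_plant, reach_start_state


@pytest.fixture(scope="session")
def system():
    """The study plant with its default control-dependent noise."""
    return build_plant(PlantParams())


@pytest.fixture(scope="session")
def system_ce():
    """Certainty-equivalent plant (no control-dependent noise)."""
    return build_plant(PlantParams(c_scale=0.0))


@pytest.fixture(scope="session")
def x0():
    return reach_start_state(0.25)


@pytest.fixture(scope="session")
def baseline_fit(system):
    """Baseline condition fit (50 cm/s peak at 50% of the reach)."""
    return fit_kinematic_condition(system, 0.5, 50.0, seed=11)


@pytest.fixture(scope="session")
def condition_fits(system, baseline_fit):
    """Fits for the three modelled conditions, keyed by label."""
    return {
        "baseline": baseline_fit,
        "late": fit_kinematic_condition(system, 0.5, 66.0, seed=12),
        "early": fit_kinematic_condition(system, 0.5, 33.0, seed=13),
    }
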