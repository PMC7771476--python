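"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from cropforesight import StudyConfig, run_study
from cropforesight.model import (Commodity, MarketCalibration, Region,
                                 WorldModel, validate_world)
from cropforesight.synthetic import DEFAULT_FIXTURE_SEED


def make_single_market(eta=-0.5, eps_yield=0.1, eps_area=0.3,
                       p0=200.0, q0=1000.0, years=(2015, 2016),
                       income_elast=0.3) -> WorldModel:
    """A closed 1-region 1-commodity world calibrated at (p0, q0)."""
    cal = MarketCalibration(
        yield_base=np.array([[10.0]]),
        area_base=np.array([[q0 / 10.0]]),
        demand_base=np.array([[q0]]),
        price_base=np.array([p0]),
        price_margin=np.ones((1, 1)),
        yield_price_elast=np.array([[eps_yield]]),
        input_price_elast=np.zeros((1, 1)),
        area_elast=np.array([[[eps_area]]]),
        demand_elast=np.array([[[eta]]]),
        income_elast=np.array([[income_elast]]),
        population_base=np.array([100.0]),
        income_base=np.array([1.0]),
    )
    world = WorldModel(
        commodities=[Commodity("potato", is_focus=True)],
        regions=[Region("home")],
        calibration=cal,
        years=np.arange(years[0], years[1] + 1),
    )
    problems = validate_world(world)
    assert problems == [], problems
    return world


@pytest.fixture(scope="session")
def fixture_study():
    """The default seeded study: full 4-technology x 4-scenario grid."""
    return run_study(StudyConfig(seed=DEFAULT_FIXTURE_SEED))
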