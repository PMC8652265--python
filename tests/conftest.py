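import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import greencool as gc

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_blueprint():
    """A 400 m (40x40 coarse) city: fast, yet every class is present."""
    return gc.CityBlueprint(side_m=400, pop_total=2000, seed=3)


@pytest.fixture(scope="session")
def small_city(small_blueprint):
    lulc = gc.make_lulc(small_blueprint)
    tree, bld = gc.make_masks(lulc, small_blueprint)
    return lulc, tree, bld


@pytest.fixture(scope="session")
def small_refined(small_blueprint, small_city):
    lulc, tree, bld = small_city
    f = small_blueprint.factor
    covers = gc.CoverFractions(gc.cover_fractions(tree, f),
                               gc.cover_fractions(bld, f))
    return gc.refine_lulc(lulc, covers)


@pytest.fixture(scope="session")
def small_inputs(small_blueprint):
    return gc.synthesize_inputs(small_blueprint)


def make_refined(base, tree_frac, building_frac):
    """Small hand-built refined grid from explicit fraction rasters."""
    covers = gc.CoverFractions(np.asarray(tree_frac, float),
                               np.asarray(building_frac, float))
    return gc.refine_lulc(np.asarray(base, dtype=int), covers)
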