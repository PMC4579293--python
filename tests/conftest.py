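"""Shared fixtures: reduced-size study phantom and its fitted field."""

import numpy as np
import pytest

import tractdissect as td

SMALL_SHAPE = (24, 36, 24)


@pytest.fixture(scope="session")
def monkey_sch():
    return td.monkey_scheme()


@pytest.fixture(scope="session")
def small_phantom(monkey_sch):
    """Noiseless reduced-size pathway phantom: (spec, dwv, gt)."""
    spec = td.build_pathway_spec(SMALL_SHAPE, with_stria=False, bundle_radius=1.8)
    dwv, gt = td.simulate_phantom(spec, monkey_sch)
    return spec, dwv, gt


@pytest.fixture(scope="session")
def small_field(small_phantom):
    spec, dwv, gt = small_phantom
    return td.fit_volume(dwv, td.brain_mask(spec, gt), K=20, rng_seed=7)


@pytest.fixture(scope="session")
def small_gt_field(small_phantom):
    spec, _, gt = small_phantom
    return td.ground_truth_field(spec, K=8, gt=gt)


def straight_bundle_spec(shape=(16, 30, 16), radius=2.0, f=0.7):
    """A straight tube along y through the grid center."""
    extent = np.array([(s - 1) * 1.0 for s in shape])
    c = extent / 2
    line = np.array([[c[0], 3.0, c[2]], [c[0], extent[1] - 3.0, c[2]]])
    return td.PhantomSpec(
        grid_shape=shape,
        bundles={"tube": td.BundleSpec(line, radius=radius, stick_fraction=f)},
    )
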