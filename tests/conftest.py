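import numpy as np
import pytest

from genmod import build_jacobian, default_ranges, fixture
from genmod.sampling import ParameterRanges, _draw_samples


@pytest.fixture(scope="session")
def one_d_jac():
    return build_jacobian(fixture("one_d_gain_loss"), timescale_reference="X")


@pytest.fixture(scope="session")
def predator_prey_jac():
    return build_jacobian(fixture("predator_prey"), timescale_reference="X")


def draw_admissible(jac, n, seed, overrides=None):
    """Random admissible parameter sets for a Jacobian: uniform scalars from
    the default illustrative ranges, branching weights on the simplex."""
    bounds = default_ranges(tuple(s.name for s in jac.free_symbols))
    if overrides:
        bounds.update(overrides)
    rng = np.random.default_rng(seed)
    frame = _draw_samples(jac, ParameterRanges(bounds), n, rng)
    return [dict(zip(frame.columns, row)) for row in frame.to_numpy()]
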