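import numpy as np
import pytest

from plotalign.grid_model import DisplacementField, make_uniform_grid
from plotalign.scalar_field import ScalarField, build_summed_area_table
from plotalign.synthetic import validation_trial_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_field(rng):
    """A 30 x 40 field of uniform values in [-1, 1]."""
    return ScalarField(values=rng.uniform(-1, 1, size=(30, 40)))


@pytest.fixture
def random_sat(random_field):
    return build_summed_area_table(random_field)


@pytest.fixture
def small_grid():
    """3 x 3 grid of 6 x 4 px cells on a 10 px pitch, interior of a 40 x 40
    field."""
    return make_uniform_grid(3, 3, cell_w=6, cell_h=4, origin=(8, 8), pitch_u=10, pitch_v=10)


def random_instance(rng, max_pq=3, field_size=50):
    """A random small grid + field + in-bounds displacements, for oracle
    comparisons."""
    P = int(rng.integers(1, max_pq + 1))
    Q = int(rng.integers(1, max_pq + 1))
    values = rng.uniform(-1, 1, size=(field_size, field_size))
    cell_w = int(rng.integers(3, 9))
    cell_h = int(rng.integers(3, 9))
    pitch_u = cell_w + int(rng.integers(0, 4))
    pitch_v = cell_h + int(rng.integers(0, 4))
    origin = (float(rng.integers(5, 12)), float(rng.integers(5, 12)))
    grid = make_uniform_grid(P, Q, cell_w, cell_h, origin, pitch_u, pitch_v)
    bound_u, bound_v = pitch_u / 2.0, pitch_v / 2.0
    du = rng.uniform(-bound_u, bound_u, size=(P, Q))
    dv = rng.uniform(-bound_v, bound_v, size=(P, Q))
    disp = DisplacementField(du=du, dv=dv, bound_u=bound_u, bound_v=bound_v)
    return values, grid, disp


@pytest.fixture(scope="session")
def tiny_trial_spec():
    """A fast-to-render validation-style trial: 2 x 3 plots at coarse
    resolution, used wherever a full pipeline is exercised in unit tests."""
    return validation_trial_spec(P=2, Q=3, resolution_cm_per_px=3.2)
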