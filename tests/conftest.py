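import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A small LV phantom for unit tests: 48-cube, 4 frames."""
    from myotrack.phantom import PhantomSpec

    return PhantomSpec(
        grid_shape=(48, 48, 48),
        center=(24.0, 24.0, 34.0),
        outer_semiaxes=(16.0, 16.0, 18.0),
        inner_semiaxes=(9.0, 9.0, 11.0),
        n_frames=4,
        end_systolic_index=2,
        bulk_translation=(1.0, -1.0, 1.2),
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    from myotrack.phantom import make_deformation

    return make_deformation(small_spec)


@pytest.fixture(scope="session")
def small_volumes(small_spec, small_truth):
    from myotrack.phantom import render_frames

    return render_frames(small_spec, small_truth)
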