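import numpy as np
import pytest

from tensortomo import Geometry, DetectorSegments


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_geometry(rng, volume_shape=(8, 8, 8), n_projections=5,
                    projection_shape=None, offsets=False):
    """Standard-axes geometry with random goniometer angles (and optional
    random sub-pixel offsets)."""
    if projection_shape is None:
        projection_shape = volume_shape[1:]
    kwargs = dict(
        inner_angles=rng.uniform(0, 2 * np.pi, n_projections),
        outer_angles=rng.uniform(-0.8, 0.8, n_projections),
        volume_shape=volume_shape,
        projection_shape=projection_shape,
    )
    if offsets:
        kwargs["j_offsets"] = rng.uniform(-1, 1, n_projections)
        kwargs["k_offsets"] = rng.uniform(-1, 1, n_projections)
    return Geometry(**kwargs)


@pytest.fixture
def single_projection_geometry():
    """One untilted projection, beam along the x axis of an 8^3 grid."""
    return Geometry(inner_angles=np.zeros(1), outer_angles=np.zeros(1),
                    volume_shape=(8, 8, 8), projection_shape=(8, 8))


@pytest.fixture
def segments_half_8():
    return DetectorSegments.evenly_spaced(8, coverage="half")
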