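import numpy as np
import pytest
from hypothesis import settings

import hsegmod as hs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    """Standard synthetic case: seed points, truth contour, truth mask."""
    seeds, contour, mask = hs.make_fixture(rng=7)
    return seeds, contour, mask


@pytest.fixture(scope="session")
def fitted(bundle):
    """A fitted model on the standard case, shared across tests."""
    seeds, contour, mask = bundle
    model = hs.HSegMod(seeds, frame_shape=mask.shape)
    return model.fit(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def circle_sequence(m: int = 16) -> hs.VertexSequence:
    """Vertex sequence sampled from the unit circle (already normalized)."""
    from hsegmod.ccps import ClosedPolyline, NormalizationParams, to_vertex_sequence

    theta = 2 * np.pi * np.arange(m) / m
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    return to_vertex_sequence(ClosedPolyline(xy), NormalizationParams(0.0, 0.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def circle_seq():
    return circle_sequence()
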