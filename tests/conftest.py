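import numpy as np
import pytest

import mgdrqa as m


@pytest.fixture(scope="session")
def identity_bundle():
    """Default two-beam tangential bundle with no injected error."""
    return m.default_tangential_bundle()


@pytest.fixture(scope="session")
def blob_bundle():
    """Bundle with the out-of-field +20% blob aimed at lung-traversing rays."""
    return m.default_tangential_bundle(errors=m.lung_blob_errors())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def small_grid(values, spacing=(2.0, 2.0, 2.0), origin=None,
               frame_id="frame-0"):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = -(np.array(values.shape) - 1) / 2 * np.asarray(spacing)
    return m.DoseGrid(origin, spacing, values, frame_id=frame_id)
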