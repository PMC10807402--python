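import numpy as np
import pytest

from v1colmap.ganglion import DOGParams
from v1colmap.tiling import build_tiling, generate_index_matrices


@pytest.fixture(scope="session")
def dog_params():
    return DOGParams()


@pytest.fixture(scope="session")
def small_tiling():
    """5x5 field grid on a 33x33 frame (the standard small-scale geometry)."""
    return build_tiling(33, 33)


@pytest.fixture(scope="session")
def small_index(small_tiling):
    return generate_index_matrices(small_tiling)


@pytest.fixture(scope="session")
def paper_tiling():
    """The reference frame geometry: 123x183, 9x9 fields, stride 6."""
    return build_tiling(123, 183)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def isotropic_test_columns():
    """Hand-constructed columns whose shared chip set is closed under
    90-degree rotation and tie-free on axis/diagonal bars.

    Chips are the canonical bar patterns of {0, 45, 90, 135} degrees at
    perpendicular offsets {0, +3*sqrt(2), -3*sqrt(2)} (the offsets at which
    a centred bar crosses a neighbouring field's centre or corner),
    identical in every column; remaining chips are silent.
    """
    from v1colmap.cortex import probe_gc_vector, probe_tuning
    from v1colmap.som import OrientationColumnSet, SOMConfig, hex_topology

    dogp = DOGParams()
    tiling = build_tiling(33, 33)
    corner = 3.0 * np.sqrt(2.0)
    pats = []
    for th in (0.0, 45.0, 90.0, 135.0):
        for off in (0.0, corner, -corner):
            v = probe_gc_vector(th, 9, dogp, offset=off).astype(float)
            if v.any():
                pats.append(v)
    while len(pats) < 19:
        pats.append(np.zeros(81))
    W = np.repeat(np.stack(pats[:19])[None], tiling.n_fields, axis=0)
    cols = OrientationColumnSet(W, hex_topology(), SOMConfig(T=1), tiling, t=1)
    tuning = probe_tuning(cols, np.arange(0, 180, 15.0), dogp)
    return cols, tuning, dogp
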