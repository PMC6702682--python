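import numpy as np
import pytest

from sopes.grids import build_dvr
from sopes.surfaces import toy_reference, toy_reference_morse


@pytest.fixture(scope="session")
def toy3():
    """3D harmonic-member toy reference surface and its metadata."""
    return toy_reference(0, f=3)


@pytest.fixture(scope="session")
def morse3():
    """3D anharmonic (Morse-well) toy reference surface."""
    return toy_reference_morse(0, f=3)


@pytest.fixture(scope="session")
def grids12(toy3):
    """12^3 DVR grid covering the toy surface's sampling box."""
    surf, _ = toy3
    b = surf.coordinate_bounds()
    return [
        build_dvr("harmonic", 12, (b[0, 0], b[0, 1]), name="q1"),
        build_dvr("harmonic", 12, (b[1, 0], b[1, 1]), name="q2"),
        build_dvr("cosine", 12, (0.0, 2.0 * np.pi), name="phi"),
    ]


def grid_backend(surface, grids, zeta=None):
    """Index-tuple energy callable over the direct-product grid."""
    points = [g.points for g in grids]

    def backend(idx):
        return surface.energy(
            np.array([points[k][i] for k, i in enumerate(idx)]), zeta)

    return backend
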