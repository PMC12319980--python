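"""Shared fixtures: small phantoms and forward solutions reused across tests.

Everything is generated programmatically at collection time; grids are kept
small so the full suite runs quickly on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from anisofield.grids import LabeledVolume, TensorField
from anisofield.phantoms import (
    Montage,
    cylinder_montages,
    default_head_phantom,
    make_cylinder_phantom,
    make_layered_phantom,
    synth_diffusion_tensors,
)
from anisofield.tissues import default_assignment


@pytest.fixture(scope="session")
def assign():
    return default_assignment()


@pytest.fixture(scope="session")
def head32():
    """Default head-like phantom at 32^3 / 4 mm with synthetic tensors."""
    labels = default_head_phantom((32, 32, 32), spacing=4.0)
    D = synth_diffusion_tensors(labels)
    return labels, D


#: Fat-shelled 6-tissue phantom radii for very coarse grids (mm).
TINY_RADII = {
    "scalp": 56.0,
    "compact_bone": 46.0,
    "spongy_bone": 38.0,
    "csf": 30.0,
    "gm": 22.0,
    "wm": 12.0,
}


@pytest.fixture(scope="session")
def tiny_head():
    """16^3 six-tissue phantom with exaggerated shell thicknesses, for tests
    that need many forward solves (surrogate training, Monte Carlo)."""
    labels = make_layered_phantom((16, 16, 16), 8.0, TINY_RADII)
    D = synth_diffusion_tensors(labels)
    return labels, D


@pytest.fixture(scope="session")
def cylinder():
    labels, D = make_cylinder_phantom()
    return labels, D, cylinder_montages(labels)


def slab(shape=(20, 10, 10), spacing=1.0, sigma=0.3):
    """Homogeneous conducting slab with full-face plate electrodes along x."""
    labels = LabeledVolume(np.ones(shape, int), spacing, tissues={"medium": 1})
    tensors = np.broadcast_to(sigma * np.eye(3), shape + (3, 3)).copy()
    faces_a = [(0, j, k, 0, 0) for j in range(shape[1]) for k in range(shape[2])]
    faces_b = [(shape[0] - 1, j, k, 0, 1)
               for j in range(shape[1]) for k in range(shape[2])]
    montage = Montage(np.array(faces_a), np.array(faces_b), current_mA=1.0,
                      name="plates")
    return labels, TensorField(tensors, units="S/m"), montage


@pytest.fixture()
def slab_setup():
    return slab()
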