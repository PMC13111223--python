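import numpy as np
import pytest

import voxstim as vx
from voxstim.grids import WHITE_MATTER


def plate_electrodes(volume, pad_mm=(20.0, 20.0), potential=1.0):
    """Copper plates flush on the +z / -z faces of a slab (no sponge)."""
    sz = volume.shape[2] * volume.spacing_mm[2]
    cx = volume.shape[0] * volume.spacing_mm[0] / 2.0
    cy = volume.shape[1] * volume.spacing_mm[1] / 2.0
    top = vx.ElectrodeSpec("anode", (cx, cy, sz), (0, 0, 1.0), pad_mm,
                           1.0, 0.0, potential)
    bot = vx.ElectrodeSpec("cathode", (cx, cy, 0.0), (0, 0, -1.0), pad_mm,
                           1.0, 0.0, -potential)
    return top, bot


def solved_uniform_slab(sigma_label="white_matter", potential=1.0):
    vol = vx.make_slab_phantom(1, [sigma_label], [20.0], (20.0, 20.0), 1.0)
    top, bot = plate_electrodes(vol, potential=potential)
    volE = vx.attach_electrodes(vol, [top, bot])
    model = vx.assign_isotropic(volE)
    phi, rep = vx.solve_potential(model, volE, [top, bot])
    return volE, model, (top, bot), phi, rep


@pytest.fixture(scope="session")
def uniform_slab():
    """Uniform white-matter slab, plates at +/-1 V across 20 mm."""
    return solved_uniform_slab()


@pytest.fixture(scope="session")
def uniform_slab_efield(uniform_slab):
    volE, model, electrodes, phi, rep = uniform_slab
    ef = vx.compute_efield(phi, volE)
    return volE, ef, rep


def random_efield(rng, shape=(6, 6, 6), mask_p=0.8):
    mask = rng.random(shape) < mask_p
    mask.flat[0] = True
    vals = rng.normal(0, 50.0, size=shape + (3,))
    return vx.FieldVolume("efield", np.where(mask[..., None], vals, 0.0),
                          mask, np.ones(3), np.eye(4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def wm_mask_of():
    def _get(volume):
        return volume.labels == WHITE_MATTER
    return _get
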