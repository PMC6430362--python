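"""Shared fixtures: small synthetic scenes and reference data.

All fixtures are generated programmatically and seeded, so the suite needs
no stored image data.
"""

import numpy as np
import pytest

from spectralbeads import SceneSpec, generate_scene
from spectralbeads.synth import default_reference_matrix, default_target_table


@pytest.fixture(scope="session")
def reference():
    return default_reference_matrix()


@pytest.fixture(scope="session")
def targets():
    return default_target_table()


@pytest.fixture(scope="session")
def small_scene():
    """One 480x480 file, 5 beads per code (240 beads), default noise."""
    spec = SceneSpec(
        image_shape=(480, 480), beads_per_code=5, n_beads=None, seed=42
    )
    images, manifest = generate_scene(spec)
    return spec, images, manifest


@pytest.fixture(scope="session")
def noiseless_single_bead_scene():
    """A single bead with zero noise for exact closure checks."""
    from spectralbeads.decode import TargetCodeTable

    targets = TargetCodeTable(
        ratios=np.array([[0.5, 0.2, 0.8]]),
        dimensions=["Dy.Eu", "Sm.Eu", "Tm.Eu"],
    )
    spec = SceneSpec(
        image_shape=(96, 96),
        n_beads=1,
        targets=targets,
        ratio_noise_frac=0.0,
        read_noise_sd=0.0,
        eu_level_sd=0.0,
        fluor_signal_sd=0.0,
        illumination_gradient=0.0,
        seed=7,
    )
    images, manifest = generate_scene(spec)
    return spec, images, manifest


def draw_ring(shape, center, radius, ring_width=2, background=200.0, ring=50.0,
              core=190.0):
    """Render one dark-ring bead into a fresh bright-field image."""
    img = np.full(shape, background)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    img[dist <= radius] = core
    img[(dist <= radius) & (dist > radius - ring_width)] = ring
    return img
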