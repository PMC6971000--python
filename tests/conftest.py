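"""Shared fixtures: small, geometry-controlled synthetic acquisitions.

Image sizes are chosen so that the jittered lattice never places a cell
centre on an image border or a zone boundary (half-height ≡ 12.5 mod 25 µm
at 1 µm/px), which makes count ground truth unambiguous.
"""

import numpy as np
import pytest

from sldt import SimConfig, generate_assay_image


def make_config(**kw) -> SimConfig:
    base = dict(
        image_height_px=425,
        image_width_px=600,
        pixel_size_um=1.0,
        lattice_spacing_um=25.0,
        max_transfer_halfwidth_um=150.0,
        coupling=0.7,
        dead_fraction=0.1,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noiseless_image():
    """One noiseless acquisition plus ground truth (segmentation oracle)."""
    return generate_assay_image(make_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_image():
    """Same geometry with SNR ≈ 10 Gaussian noise."""
    return generate_assay_image(make_config())
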