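"""Shared fixtures: deterministic synthetic images and the coordinate
convention sentinel used by every module's tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from spinefind.calibration_io import CalibratedImage
from spinefind.synthetic import SynthSpec, generate

SCALE = 15.0


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Pipeline warnings (flagged degenerate inputs) are expected in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def noiseless_spec() -> SynthSpec:
    """Four spines, two bumps, no noise: geometry is exactly recoverable."""
    return SynthSpec(
        n_spines=(4, 4), n_bumps=(2, 2), noise_gain=0.0, read_noise=0.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_image(noiseless_spec):
    return generate(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_image():
    return generate(SynthSpec(n_spines=(4, 4), n_bumps=(2, 2), seed=11))


@pytest.fixture(scope="session")
def short_spine_image():
    """All spines shorter than the 2 um minimum branch length, so every
    spine branch is trimmed off the backbone and every tip stays a clean
    geodesic maximum (the regime the cleanup stages are specified for)."""
    spec = SynthSpec(
        n_spines=(4, 4),
        stalk_um=(0.4, 1.0),
        head_radius_um=(0.2, 0.3),
        n_bumps=(2, 2),
        seed=11,
    )
    return generate(spec)


@pytest.fixture
def coordinate_sentinel():
    """An image with a single bright pixel at (row=3, col=10): every module
    must read it as row-major, 0-based, row 0 at the top."""
    px = np.zeros((32, 32))
    px[3, 10] = 1.0
    return CalibratedImage(px, SCALE, source_id="sentinel")


def tube_mask(shape: tuple[int, int], row: int, half_width: int) -> np.ndarray:
    """Horizontal bar spanning the full width (test geometry helper)."""
    m = np.zeros(shape, dtype=bool)
    m[row - half_width : row + half_width + 1, :] = True
    return m
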