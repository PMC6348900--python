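"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from skimage.transform import radon

from shgtensor.synthetic import SyntheticParams


def radon_orientation_oracle(image: np.ndarray, step_deg: float = 1.0) -> float:
    """Dominant structure orientation by exhaustive projections.

    For each candidate angle the image is projected (Radon transform) and
    the variance of the projection profile computed; integrating *along* the
    stripes gives the highest-contrast profile, so the argmax angle marks the
    structure direction.  In the display convention used here (y down,
    angles CCW from +x) the argmax t maps to a structure orientation of
    (90 + t) mod 180.  Completely independent of the gradient/tensor
    pathway.
    """
    from scipy import ndimage
    # high-pass at the ridge scale so large-scale amplitude modulation
    # (lamellar envelopes) does not dominate the projection variance
    img = image - ndimage.gaussian_filter(image, 8.0, mode="reflect")
    h, w = img.shape
    # restrict to the inscribed disc so every projection sees the same mass
    yy, xx = np.mgrid[0:h, 0:w]
    r = min(h, w) / 2.0 - 1
    mask = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2 <= r * r
    img = img * mask
    thetas = np.arange(0.0, 180.0, step_deg)
    sino = radon(img, theta=thetas, circle=True, preserve_range=True)
    variances = sino.var(axis=0)
    i = int(np.argmax(variances))
    n = len(variances)
    lo, ce, hi = variances[(i - 1) % n], variances[i], variances[(i + 1) % n]
    denom = lo - 2.0 * ce + hi
    shift = 0.5 * (lo - hi) / denom if denom != 0 else 0.0
    return float((90.0 + thetas[i] + shift * step_deg) % 180.0)


def circ_diff_deg(a: float, b: float, period: float = 180.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


@pytest.fixture
def stripe_params():
    """Noise-free perfectly parallel fibers at 30 degrees, 256 px."""
    return SyntheticParams(
        image_size_px=(256, 256), family_orientations_deg=(30.0,),
        concentration_kappa=np.inf, waviness_amplitude_um=0.0,
        patchiness=0.0, noise_scale=0.0, seed=7)


@pytest.fixture
def small_params():
    """Small dispersed single-family texture for fast tests."""
    return SyntheticParams(
        image_size_px=(192, 192), family_orientations_deg=(30.0,),
        concentration_kappa=4.0, seed=11)
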