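import numpy as np
import pytest
from scipy import ndimage, stats

from petbtv.phantom import FWHM_TO_SIGMA, PhantomSpec


@pytest.fixture(scope="session")
def default_phantom() -> PhantomSpec:
    return PhantomSpec(tbr_nominal=8.0)


def make_blurred_disk(
    internal_diameter: float,
    blur_fwhm: float,
    pixel: float,
    background: float = 3.0,
    hot: float = 24.0,
    pad_mm: float = 20.0,
) -> tuple[np.ndarray, int]:
    """A hot disk on warm background, Gaussian-blurred, centered on a pixel.

    Returns the 2D image and the center pixel index.
    """
    radius = internal_diameter / 2.0
    half = int(np.ceil((radius + pad_mm) / pixel))
    n = 2 * half + 1
    xs = (np.arange(n) - half) * pixel
    d2 = xs[:, None] ** 2 + xs[None, :] ** 2
    img = np.where(d2 <= radius**2, hot, background).astype(float)
    if blur_fwhm > 0:
        img = ndimage.gaussian_filter(
            img, blur_fwhm * FWHM_TO_SIGMA / pixel, mode="nearest"
        )
    return img, half


def disk_boundary_ts(
    radius: float, blur_fwhm: float, background: float = 3.0, hot: float = 24.0
) -> float:
    """Independent threshold oracle for a Gaussian-blurred disk.

    The blurred intensity at distance r from the center of a uniform disk
    of radius R is background + contrast * D(r), where D(r) is the mass of
    an isotropic 2D Gaussian centered at radius r that falls inside the
    disk -- a noncentral chi-square (df=2) probability.  The threshold that
    reproduces the true area places the contour at r = R, so the oracle TS
    is the boundary value as a percentage of the center (max) value.
    """
    sigma = blur_fwhm * FWHM_TO_SIGMA

    def response(r: float) -> float:
        return float(stats.ncx2.cdf((radius / sigma) ** 2, 2, (r / sigma) ** 2))

    contrast = hot - background
    boundary = background + contrast * response(radius)
    center = background + contrast * response(0.0)
    return 100.0 * boundary / center
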