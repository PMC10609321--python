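import numpy as np
import pytest
from hypothesis import settings

from cottonsect import CalibrationScale, Contour

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def unit_scale() -> CalibrationScale:
    return CalibrationScale.from_um_per_px(1.0)


@pytest.fixture
def unit_square() -> Contour:
    return Contour([(0, 0), (1, 0), (1, 1), (0, 1)])


def regular_polygon(n: int, radius: float, center=(0.0, 0.0)) -> Contour:
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.c_[center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)])


def star_polygon(rng: np.random.Generator, n: int = 12, radius: float = 1.0) -> Contour:
    """Random simple (star-shaped) polygon: sorted angles, random radii."""
    phi = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.4 * radius, radius, n)
    return Contour(np.c_[r * np.cos(phi), r * np.sin(phi)])


def annulus_image(
    shape=(400, 400), center=(200, 200), r_out=100, r_in=30, wall=200, background=30
) -> np.ndarray:
    """Clean two-level annulus micrograph (wall bright, lumen/bg dark)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    img = np.full(shape, background, dtype=np.uint8)
    img[(d2 <= r_out**2) & (d2 >= r_in**2)] = wall
    return img
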