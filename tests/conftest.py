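"""Shared test helpers.

The collinear-array volume oracle here is deliberately independent of
the package's inclusion–exclusion closed form: cross-sections of
collinear equal spheres perpendicular to the array axis are *concentric*
discs, so the area covered by at least k spheres in a slice is
π·(k-th largest disc radius)², and the coverage volumes follow by 1-D
quadrature along the axis.
"""

import numpy as np
import pytest
from scipy.integrate import simpson


def collinear_volume_oracle(m: int, d: float, r: float, n_slices: int = 40001):
    """(v_single, v_double, v_total) of m collinear spheres of radius r
    spaced d apart, by concentric-disc slice integration."""
    centers = np.arange(m) * d
    y = np.linspace(centers.min() - r, centers.max() + r, n_slices)
    rho_sq = np.maximum(r**2 - (y[:, None] - centers[None, :]) ** 2, 0.0)
    rho_sq.sort(axis=1)
    largest = rho_sq[:, -1]
    second = rho_sq[:, -2] if m >= 2 else np.zeros_like(largest)
    v_total = float(simpson(np.pi * largest, x=y))
    v_double = float(simpson(np.pi * second, x=y))
    return v_total - v_double, v_double, v_total


@pytest.fixture
def oracle():
    return collinear_volume_oracle
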