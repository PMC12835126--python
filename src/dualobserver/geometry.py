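"""Exact coverage geometry for linear electrode arrays.

An electrode observes a sphere of radius ``r`` (the observation radius)
around its center.  For an evenly spaced collinear array of ``m``
electrodes at pitch ``d``, the tissue volume covered by exactly one
sphere (``v_single``), by at least two spheres (``v_double``), and by
the union of all spheres (``v_total``) has a closed form built from the
equal-sphere intersection lens.  Higher-order intersections cancel from
the inclusion–exclusion series for collinear equal spheres: a triple
overlap A∩B∩C equals the second-neighbour overlap A∩C (A∩C ⊆ B), so
only first- and second-neighbour lens terms survive:

    v_double = (m-1)·V2(r, d) - (m-2)·V2(r, 2d)
    v_total  = m·V1(r) - (m-1)·V2(r, d)
    v_single = v_total - v_double

with V2 clipped to zero once the sphere pair no longer intersects.
All lengths are micrometres and all volumes cubic micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "VolumeDecomposition",
    "LinearArraySpec",
    "sphere_volume",
    "lens_volume",
    "linear_array_volumes",
]

#: conversion between the internal μm³ volumes and the per-mm³ unit
#: densities accepted and reported at the API boundary
UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class VolumeDecomposition:
    """Coverage volumes (μm³) of an electrode layout at one observation radius.

    Attributes
    ----------
    v_single : float
        Volume covered by exactly one observation sphere.
    v_double : float
        Volume covered by at least two observation spheres.
    v_total : float
        Volume of the union of all observation spheres;
        always ``v_single + v_double``.
    """

    v_single: float
    v_double: float
    v_total: float

    def __post_init__(self) -> None:
        if self.v_single < 0 or self.v_double < 0:
            raise ValueError(
                f"negative coverage volume: v_single={self.v_single}, "
                f"v_double={self.v_double}"
            )
        if not math.isclose(
            self.v_total, self.v_single + self.v_double, rel_tol=1e-9, abs_tol=1e-6
        ):
            raise ValueError(
                "v_total must equal v_single + v_double "
                f"({self.v_total} != {self.v_single} + {self.v_double})"
            )


@dataclass(frozen=True)
class LinearArraySpec:
    """An evenly spaced collinear array: ``m`` electrodes at pitch ``d`` (μm)."""

    m: int
    d: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"electrode count m must be >= 1, got {self.m}")
        if self.d <= 0:
            raise ValueError(f"inter-electrode distance d must be > 0, got {self.d}")


def sphere_volume(r: float) -> float:
    """Volume (μm³) of a single observation sphere of radius ``r`` μm.

    ``V1(r) = (4π/3) r³``.
    """
    if r < 0:
        raise ValueError(f"radius must be non-negative, got {r}")
    return (4.0 * math.pi / 3.0) * r**3


def lens_volume(r: float, d: float) -> float:
    """Intersection volume (μm³) of two equal spheres of radius ``r`` whose
    centers are ``d`` μm apart.

    The lens is a pair of spherical caps:
    ``V2(r, d) = (π/3)(4r³ - 3r²d + d³/4)`` for ``d < 2r``, and zero once
    the spheres are tangent or disjoint (``d >= 2r``).  Continuous and
    non-increasing in ``d``; at ``d = 0`` it equals ``sphere_volume(r)``.
    """
    if r < 0:
        raise ValueError(f"radius must be non-negative, got {r}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d >= 2.0 * r:
        return 0.0
    # near tangency the three terms cancel; clamp float round-off
    return max(0.0, (math.pi / 3.0) * (4.0 * r**3 - 3.0 * r**2 * d + d**3 / 4.0))


def linear_array_volumes(spec: LinearArraySpec, r: float) -> VolumeDecomposition:
    """Exact coverage decomposition of an evenly spaced collinear array.

    Because the second-neighbour lens ``V2(r, 2d)`` vanishes for
    ``d >= r`` and the first-neighbour lens for ``d >= 2r``, a single
    expression covers all three spacing regimes (no overlap, first
    neighbours only, first and second neighbours):

    - ``d >= 2r``: independent spheres, ``v_total = m·V1``, ``v_double = 0``;
    - ``2r > d >= r``: ``v_double = (m-1)·V2(r, d)``;
    - ``r > d``: second-neighbour correction ``-(m-2)·V2(r, 2d)`` applies.

    Degenerate counts ``m = 1`` (no pairs) and ``m = 2`` (no second
    neighbours) fall out of the ``max(m-1, 0)``/``max(m-2, 0)`` factors.
    """
    if r < 0:
        raise ValueError(f"radius must be non-negative, got {r}")
    m, d = spec.m, spec.d
    v1 = sphere_volume(r)
    v2_first = lens_volume(r, d)
    v2_second = lens_volume(r, 2.0 * d)
    n_first = max(m - 1, 0)
    n_second = max(m - 2, 0)
    v_double = max(0.0, n_first * v2_first - n_second * v2_second)
    v_total = m * v1 - n_first * v2_first
    v_single = max(0.0, v_total - v_double)
    return VolumeDecomposition(
        v_single=v_single, v_double=v_double, v_total=v_single + v_double
    )
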