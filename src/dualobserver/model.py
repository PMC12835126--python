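"""The dual observer model of spike-sorting unit yield.

The model links an electrode configuration to the expected number of
well-isolated single units through three parameters:

``r_obs``
    observation radius R (μm): spikes from neurons within R of an
    electrode reach the signal-to-noise ratio needed for sorting, so
    each electrode observes a sphere of radius R.
``g``
    gain factor G = p_double / (2 p_single): cooperation between
    electrodes in doubly observed tissue.  G = 0.5 means two electrodes
    are no better than one (independence), G > 1 means the second view
    more than compensates the volume lost to the overlap (synergy),
    G < 0.5 means interference.
``p_single``
    density (per mm³) of sortable units in singly observed tissue.

Expected yield:  N = p_single (V_single + 2 G V_double), with V_single
the volume covered by exactly one sphere and V_double by at least two.
Efficiency E = N / (p_single M V1) compares a configuration of M
electrodes to M independent ones; for a linear array it reduces to

    E = 1 + 2(G-1) (M-1)/M · V2(R,D)/V1(R)
          - (2G-1) (M-2)/M · V2(R,2D)/V1(R)

which for G > 1 has a unique interior maximum at

    D_opt = R sqrt( (4MG - 12G + 4) / (7MG - 3M - 15G + 7) )

(for M > 3).  At G = 1 the ratio is exactly 1 (D_opt = R); as G, M → ∞
it converges to sqrt(4/7) ≈ 0.76.  The peak efficiency is well
approximated by E_opt ≈ 0.76 G + 0.16, the figure used for tabulated
optimal-efficiency and optimal units/channel summaries; the exact value
from the efficiency formula at D_opt is reported alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import (
    UM3_PER_MM3,
    LinearArraySpec,
    VolumeDecomposition,
    lens_volume,
    linear_array_volumes,
    sphere_volume,
)

__all__ = [
    "DualObserverParams",
    "OptimumResult",
    "unit_yield",
    "efficiency",
    "units_per_channel",
    "optimal_distance",
    "optimal_efficiency",
    "optimum_summary",
]


@dataclass(frozen=True)
class DualObserverParams:
    """The model triple (R, G, p_single); densities are per mm³."""

    r_obs: float
    g: float
    p_single: float

    def __post_init__(self) -> None:
        if self.r_obs <= 0:
            raise ValueError(f"observation radius must be > 0, got {self.r_obs}")
        if self.g < 0:
            raise ValueError(f"gain factor must be >= 0, got {self.g}")
        if self.p_single < 0:
            raise ValueError(f"p_single must be >= 0, got {self.p_single}")

    @property
    def p_double(self) -> float:
        """Density (per mm³) of sortable units in doubly observed tissue."""
        return 2.0 * self.g * self.p_single


@dataclass(frozen=True)
class OptimumResult:
    """Optimal spacing and efficiency for a linear array of ``m`` electrodes.

    ``regime_flag`` is ``"interior_optimum"`` for g > 1 (a true peak at
    ``d_opt < r_obs``) or ``"boundary_g_le_1"`` for g <= 1, where every
    spacing ``d >= r_obs`` performs alike and ``d_opt`` is reported as
    the boundary value ``r_obs``.
    """

    d_opt: float
    e_opt_approx: float
    e_opt_exact: float
    opt_units_per_channel: float
    regime_flag: str


def unit_yield(volumes: VolumeDecomposition, params: DualObserverParams) -> float:
    """Expected number of well-isolated units for one coverage decomposition.

    ``N = p_single (v_single + 2 g v_double)``, converting the μm³
    volumes to mm³ to match the per-mm³ density.
    """
    v_mm3 = (volumes.v_single + 2.0 * params.g * volumes.v_double) / UM3_PER_MM3
    return params.p_single * v_mm3


def efficiency(m: int, r: float, d: float, g: float) -> float:
    """Spike-sorting efficiency of a linear array relative to independent
    electrodes.

    Continuous and piecewise in the spacing: exactly 1 for ``d >= 2r``
    (no overlaps, any g), first-neighbour lens term for ``2r > d >= r``,
    plus the second-neighbour correction for ``d < r``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    v1 = sphere_volume(r)
    term1 = 2.0 * (g - 1.0) * (m - 1) / m * lens_volume(r, d) / v1
    term2 = (2.0 * g - 1.0) * max(m - 2, 0) / m * lens_volume(r, 2.0 * d) / v1
    return 1.0 + term1 - term2


def units_per_channel(
    m: int, r: float, d: float, g: float, p_single: float
) -> float:
    """Expected units per channel, ``N / M``, for a linear array."""
    params = DualObserverParams(r_obs=r, g=g, p_single=p_single)
    volumes = linear_array_volumes(LinearArraySpec(m=m, d=d), r)
    return unit_yield(volumes, params) / m


def optimal_distance(m: int, r: float, g: float) -> tuple[float, str]:
    """Optimal inter-electrode distance for a linear array of ``m`` electrodes.

    Returns ``(d_opt, regime_flag)``.  For g > 1 the closed form

        d_opt = r sqrt((4mg - 12g + 4) / (7mg - 3m - 15g + 7))

    locates the unique interior maximum of the efficiency (valid for
    m > 3; the stationary point lies in the ``d < r`` regime).  For
    g <= 1 there is no interior peak — efficiency is flat at 1 for all
    ``d >= r`` — and ``d_opt = r`` is returned with the boundary flag.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if g <= 1.0:
        return r, "boundary_g_le_1"
    if m <= 3:
        raise ValueError(
            f"the closed-form optimum requires m > 3 (got m={m}); "
            "search the efficiency curve numerically for smaller arrays"
        )
    num = 4.0 * m * g - 12.0 * g + 4.0
    den = 7.0 * m * g - 3.0 * m - 15.0 * g + 7.0
    return r * math.sqrt(num / den), "interior_optimum"


def optimal_efficiency(m: int, r: float, g: float) -> tuple[float, float]:
    """Peak efficiency as ``(approximate, exact)``.

    The approximation ``0.76 g + 0.16`` (g > 1; exactly 1 for g <= 1) is
    the tabulation-compatible figure; the exact value evaluates the
    efficiency formula at ``d_opt``.
    """
    d_opt, flag = optimal_distance(m, r, g)
    if flag == "boundary_g_le_1":
        return 1.0, 1.0
    e_approx = 0.76 * g + 0.16
    e_exact = efficiency(m, r, d_opt, g)
    return e_approx, e_exact


def optimum_summary(m: int, params: DualObserverParams) -> OptimumResult:
    """Full optimum report for one parameter set and channel count.

    Optimal units/channel is defined as
    ``p_single · V1(r_obs) · e_opt_approx`` — the independent-electrode
    per-channel yield scaled by the approximate peak efficiency (by
    construction independent of m).
    """
    d_opt, flag = optimal_distance(m, params.r_obs, params.g)
    e_approx, e_exact = optimal_efficiency(m, params.r_obs, params.g)
    per_channel_indep = params.p_single * sphere_volume(params.r_obs) / UM3_PER_MM3
    return OptimumResult(
        d_opt=d_opt,
        e_opt_approx=e_approx,
        e_opt_exact=e_exact,
        opt_units_per_channel=per_channel_indep * e_approx,
        regime_flag=flag,
    )
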