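"""Synthetic units-per-channel datasets with the structure the fit assumes.

The generator stands in for a campaign of spike-sorted recordings: for
each electrode configuration it computes the model-expected unit yield
N = p_single (V_single + 2 G V_double) and then emits one
units-per-channel value per simulated recording under a configurable
noise model:

``lognormal``
    value = (N/M)·exp(ε), ε ~ Normal(0, σ²) — multiplicative
    recording-to-recording variability (default σ = 0.2, on the order
    of the spread seen between repeated recordings of one preparation).
``poisson``
    value = Poisson(N)/M — integer unit counts, appropriate for sparse
    configurations where N is a small number.
``none``
    the noise-free expectation N/M, repeated.

What it does NOT emulate: sorter-specific failure modes, electrode
defects, drift within a recording, or correlations between
configurations derived from the same underlying recording — real
medians inherit such structure, synthetic ones are i.i.d. per
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import Configuration, YieldDataset
from .layouts import ElectrodeLayout, preset_series
from .model import DualObserverParams, unit_yield
from .montecarlo import McSettings, hybrid_volumes

__all__ = ["SyntheticSpec", "generate", "expected_units_per_channel"]

NOISE_MODELS = ("none", "lognormal", "poisson")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``config_set`` is either a preset name (``"rodent"`` — the
    256/128/64/32/16-channel series, ``"human"`` — the
    192/96/64/48/38/19-channel series) or an explicit list of
    (label, layout) pairs.
    """

    true_params: DualObserverParams
    config_set: str | tuple[tuple[str, ElectrodeLayout], ...] = "rodent"
    n_recordings: int = 6
    noise_model: str = "lognormal"
    lognormal_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 1:
            raise ValueError(f"n_recordings must be >= 1, got {self.n_recordings}")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.lognormal_sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.lognormal_sigma}")

    def resolve_configs(self) -> list[tuple[str, ElectrodeLayout]]:
        if isinstance(self.config_set, str):
            return preset_series(self.config_set)
        return list(self.config_set)


def expected_units_per_channel(
    layout: ElectrodeLayout,
    params: DualObserverParams,
    mc: McSettings | None = None,
) -> float:
    """Model-expected units/channel for one layout (hybrid volume routine)."""
    dec = hybrid_volumes(layout, params.r_obs, mc or McSettings())
    return unit_yield(dec, params) / layout.m


def generate(spec: SyntheticSpec, mc: McSettings | None = None) -> YieldDataset:
    """Generate a units-per-channel dataset from the dual observer model.

    Deterministic given ``spec.seed`` (the Monte-Carlo settings carry
    their own seed for zig-zag coverage volumes).
    """
    mc = mc or McSettings()
    rng = np.random.default_rng(spec.seed)
    configs = []
    for label, layout in spec.resolve_configs():
        mean_upc = expected_units_per_channel(layout, spec.true_params, mc)
        n = spec.n_recordings
        if spec.noise_model == "none" or (
            spec.noise_model == "lognormal" and spec.lognormal_sigma == 0.0
        ):
            values = np.full(n, mean_upc)
        elif spec.noise_model == "lognormal":
            eps = rng.normal(0.0, spec.lognormal_sigma, size=n)
            values = mean_upc * np.exp(eps)
        else:  # poisson
            n_expected = mean_upc * layout.m
            values = rng.poisson(n_expected, size=n) / layout.m
        configs.append(
            Configuration(label=label, layout=layout, values=tuple(values))
        )
    return YieldDataset(tuple(configs))
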