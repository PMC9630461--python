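"""Analytic multiply-accumulate cost of convolution layers.

For an input feature map of spatial size Df x Df with M channels, a kernel of
spatial size Dk and N output channels (same padding, stride 1):

* standard convolution costs ``Df * Df * M * N * Dk * Dk`` MACs;
* a depthwise separable convolution costs
  ``Df * Df * M * Dk * Dk + Df * Df * M * N`` MACs
  (depthwise spatial filtering plus pointwise channel mixing),

so the separable/standard ratio is exactly ``1/N + 1/Dk**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError

__all__ = ["ConvCostSpec", "conv_cost", "cost_ratio"]


@dataclass(frozen=True)
class ConvCostSpec:
    Df: int  # spatial width/height of the input feature map
    M: int  # input channels
    N: int  # output channels
    Dk: int  # kernel spatial dimension

    def __post_init__(self) -> None:
        for field in ("Df", "M", "N", "Dk"):
            v = getattr(self, field)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(field, "must be a positive integer")


def conv_cost(spec: ConvCostSpec, kind: str) -> int:
    """Exact MAC count of one convolution layer of the given kind."""
    if kind == "conventional":
        return spec.Df * spec.Df * spec.M * spec.N * spec.Dk * spec.Dk
    if kind == "separable":
        return spec.Df * spec.Df * spec.M * spec.Dk * spec.Dk + spec.Df * spec.Df * spec.M * spec.N
    raise ConfigurationError("kind", "must be 'conventional' or 'separable'")


def cost_ratio(spec: ConvCostSpec) -> float:
    """Ratio separable/conventional; equals 1/N + 1/Dk**2."""
    return conv_cost(spec, "separable") / conv_cost(spec, "conventional")
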