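"""Greenwood frequency-position mapping at the level of the organ of Corti.

The characteristic frequency of the basilar membrane varies exponentially
with position: ``f = F (10^(a x) - k)`` where ``x`` is the relative
distance from the apex (``x = 0`` at the apex, ``x = 1`` at the base).
Low frequencies map to the apex, high frequencies to the base.  The human
constants (F = 165.4 Hz, a = 2.1, k = 0.88) give an audible range of
roughly 20 Hz to 20.7 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryConfig, angle_to_length, organ_of_corti_model

__all__ = [
    "GreenwoodParams",
    "greenwood_frequency",
    "greenwood_place",
    "place_frequency_at_angle",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the frequency-position function (human defaults)."""

    scale_f: float = 165.4  # Hz
    slope_a: float = 2.1
    offset_k: float = 0.88

    def __post_init__(self) -> None:
        if self.scale_f <= 0 or self.slope_a <= 0:
            raise ValueError("scale_f and slope_a must be positive")
        if not 0.0 <= self.offset_k < 1.0:
            raise ValueError("offset_k must lie in [0, 1)")

    @property
    def f_min(self) -> float:
        """Apical (x = 0) frequency — the lowest representable place frequency."""
        return self.scale_f * (1.0 - self.offset_k)


def greenwood_frequency(x, p: GreenwoodParams = GreenwoodParams()):
    """Characteristic frequency (Hz) at relative distance ``x`` from the apex."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise ValueError(f"relative place must lie in [0, 1], got {x!r}")
    f = p.scale_f * (np.power(10.0, p.slope_a * xa) - p.offset_k)
    return float(f) if np.isscalar(x) else f


def greenwood_place(f, p: GreenwoodParams = GreenwoodParams()):
    """Relative distance from the apex for frequency ``f`` (algebraic inverse)."""
    fa = np.asarray(f, dtype=float)
    if np.any(fa < p.f_min):
        raise ValueError(
            f"frequency below the apical minimum {p.f_min:.3f} Hz: {f!r}"
        )
    x = np.log10(fa / p.scale_f + p.offset_k) / p.slope_a
    if np.any(x > 1 + 1e-12):
        raise ValueError(f"frequency beyond the basal end of the map: {f!r}")
    x = np.clip(x, 0.0, 1.0)
    return float(x) if np.isscalar(f) else x


def place_frequency_at_angle(
    theta_deg,
    cdl: float,
    cfg: GeometryConfig = GeometryConfig(),
    p: GreenwoodParams = GreenwoodParams(),
):
    """Greenwood place frequency (Hz) at insertion angle ``theta_deg``.

    The angle is converted to a fraction of organ-of-Corti length traversed
    from the base using the organ-of-Corti spiral; the Greenwood function
    is then evaluated at ``x = 1 - fraction`` (distance from the apex).
    Monotonically decreasing in the angle: deeper contacts see lower
    frequencies.
    """
    oc = organ_of_corti_model(cdl, cfg)
    g = np.asarray(angle_to_length(theta_deg, oc)) / oc.total_length
    x = 1.0 - g
    f = greenwood_frequency(x, p)
    return float(f) if np.isscalar(theta_deg) else np.asarray(f)
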