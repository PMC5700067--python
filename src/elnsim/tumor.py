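"""Tumor radius dynamics coupled to the tumor-infiltrating lymphocyte count.

The tumor is a disc of radius R growing linearly at innate rate g and
shrinking in proportion to the number of TILs L it currently contains:

    R(t + dt) = R(t) + (g - k L) dt

so the net change is negative exactly when L exceeds g/k (133.33 cells at
the default rates).  The radius is clamped at zero, which we read as tumor
elimination; recording continues afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthParams", "TumorState", "update_radius", "contains"]


@dataclass(frozen=True)
class GrowthParams:
    g: float = 0.2       # innate radial growth rate, µm/min
    k: float = 0.0015    # radial kill rate per TIL, µm/min/cell

    def __post_init__(self) -> None:
        if self.g < 0 or self.k < 0:
            raise ValueError("growth and kill rates must be non-negative")

    @property
    def regression_threshold(self) -> float:
        """TIL count above which the net radial change is negative."""
        return np.inf if self.k == 0 else self.g / self.k


@dataclass
class TumorState:
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 200.0  # µm

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


def update_radius(radius: float, til_count: int, params: GrowthParams,
                  dt: float) -> float:
    """One explicit-Euler radius step, floored at zero."""
    if radius < 0 or til_count < 0:
        raise ValueError("radius and TIL count must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return max(0.0, radius + (params.g - params.k * til_count) * dt)


def contains(tumor: TumorState, points: np.ndarray) -> np.ndarray:
    """True where a point lies in the tumor disc (boundary inclusive)."""
    points = np.asarray(points, dtype=float)
    delta = points - np.asarray(tumor.center)
    return np.linalg.norm(delta, axis=-1) <= tumor.radius
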