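"""Negative-exponential distance-decay dispersal kernel.

The probability that the invader spreads from an occupied location to a
location ``x`` meters away is modelled as

    P(x) = min(1, exp(A - B*x)),   B > 0

The two free parameters are pinned by two (distance, probability)
calibration constraints — by default the kudzu literature pair: a 90%
chance of spreading 30 m (conservative vegetative spread by adults) and a
0.05% chance of spreading 1,610 m (rare long-range seed dispersal).  With
those constraints exp(A) slightly exceeds 1, so evaluated probabilities
are capped at 1; the cap only bites below ~8 m, far inside a grid cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationConstraint",
    "DispersalKernel",
    "calibrate_kernel",
    "DEFAULT_CONSTRAINTS",
]


@dataclass(frozen=True)
class CalibrationConstraint:
    """A (distance, probability) pair the calibrated kernel must pass through."""

    distance_m: float
    probability: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.distance_m) or self.distance_m < 0:
            raise ValueError(
                f"constraint distance must be finite and >= 0, got {self.distance_m}"
            )
        if not 0.0 < self.probability <= 1.0:
            raise ValueError(
                f"constraint probability must lie in (0, 1], got {self.probability}"
            )


#: Default calibration pair: 90% at 30 m, 0.05% at 1 mile.
DEFAULT_CONSTRAINTS: tuple[CalibrationConstraint, CalibrationConstraint] = (
    CalibrationConstraint(30.0, 0.90),
    CalibrationConstraint(1610.0, 0.0005),
)


@dataclass(frozen=True)
class DispersalKernel:
    """Calibrated kernel P(x) = min(1, exp(intercept - decay_per_m * x)).

    Attributes
    ----------
    intercept :
        Log-probability at zero distance (the model's ``A``), unitless.
    decay_per_m :
        Exponential decay rate per meter (the model's ``B``); must be
        positive so probability strictly decreases with distance.
    """

    intercept: float
    decay_per_m: float

    def __post_init__(self) -> None:
        if not (self.decay_per_m > 0) or not math.isfinite(self.decay_per_m):
            raise ValueError(f"decay rate must be positive, got {self.decay_per_m}")
        if not math.isfinite(self.intercept):
            raise ValueError(f"intercept must be finite, got {self.intercept}")

    def probability(self, distance_m):
        """Spread probability at one distance or an array of distances (m).

        Raises ``ValueError`` on negative distance.  Scalar in, scalar out.
        """
        d = np.asarray(distance_m, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        p = np.minimum(1.0, np.exp(self.intercept - self.decay_per_m * d))
        return float(p) if np.isscalar(distance_m) or d.ndim == 0 else p

    def max_effective_distance(self, p_floor: float) -> float:
        """Distance at which the uncapped kernel falls to ``p_floor``.

        Used as the neighbour-search cutoff radius in the simulator:
        beyond this distance colonization probability is below ``p_floor``
        and is treated as zero.
        """
        if not 0.0 < p_floor < 1.0:
            raise ValueError(f"p_floor must lie in (0, 1), got {p_floor}")
        return (self.intercept - math.log(p_floor)) / self.decay_per_m


def calibrate_kernel(
    c1: CalibrationConstraint, c2: CalibrationConstraint
) -> DispersalKernel:
    """Solve exactly for (A, B) so that exp(A - B*d_i) = p_i for both pairs.

    The system is linear in log space:

        B = ln(p1/p2) / (d2 - d1)
        A = ln(p1) + B * d1

    Raises
    ------
    ValueError
        If the two distances coincide (degenerate system) or if the
        resulting decay rate is not positive (probability would not
        decrease with distance).
    """
    if c1.distance_m == c2.distance_m:
        raise ValueError(
            "calibration constraints have equal distances "
            f"({c1.distance_m} m): system is degenerate"
        )
    b = math.log(c1.probability / c2.probability) / (c2.distance_m - c1.distance_m)
    a = math.log(c1.probability) + b * c1.distance_m
    if b <= 0:
        raise ValueError(
            "constraints imply non-decreasing probability with distance "
            f"(B = {b:g}); the farther constraint must have the smaller probability"
        )
    return DispersalKernel(intercept=a, decay_per_m=b)
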