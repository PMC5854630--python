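"""Astigmatism (cylinder) vector arithmetic in the double-angle representation.

A cylinder of magnitude ``m`` diopters at axis ``theta`` degrees maps to the
Cartesian point ``(m*cos(2*theta), m*sin(2*theta))``.  In that space cylinders
add componentwise, which is the standard cross-cylinder combination used for
corneal astigmatism and surgically induced astigmatism (SIA).

Axes follow clinical convention: degrees, half-open interval ``[0, 180)``.
A zero-magnitude cylinder has no meaningful axis and is normalized to axis 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CylinderVector",
    "corneal_cylinder",
    "add_cylinders",
    "cross_cylinder",
]

# Magnitudes below this are treated as exact cancellation.
_ZERO_MAGNITUDE = 1e-12


@dataclass(frozen=True)
class CylinderVector:
    """A cylinder as (magnitude in diopters, axis in degrees).

    Invariants: ``magnitude >= 0``; ``axis`` is reduced modulo 180; a
    zero-magnitude vector always carries axis 0.
    """

    magnitude: float
    axis: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude) or not math.isfinite(self.axis):
            raise ValueError("cylinder magnitude and axis must be finite")
        if self.magnitude < 0:
            raise ValueError(f"cylinder magnitude must be >= 0, got {self.magnitude}")
        if self.magnitude < _ZERO_MAGNITUDE:
            object.__setattr__(self, "magnitude", 0.0)
            object.__setattr__(self, "axis", 0.0)
        else:
            object.__setattr__(self, "axis", self.axis % 180.0)

    @classmethod
    def zero(cls) -> "CylinderVector":
        return cls(0.0, 0.0)

    def to_double_angle(self) -> tuple[float, float]:
        """Return the double-angle Cartesian form ``(m cos 2θ, m sin 2θ)``."""
        two_theta = math.radians(2.0 * self.axis)
        return (self.magnitude * math.cos(two_theta), self.magnitude * math.sin(two_theta))

    @classmethod
    def from_double_angle(cls, x: float, y: float) -> "CylinderVector":
        """Inverse of :meth:`to_double_angle`; axis lands in ``[0, 180)``."""
        magnitude = math.hypot(x, y)
        if magnitude < _ZERO_MAGNITUDE:
            return cls.zero()
        axis = math.degrees(math.atan2(y, x)) / 2.0
        return cls(magnitude, axis % 180.0)

    def negated(self) -> "CylinderVector":
        """Same magnitude at the perpendicular axis (additive inverse)."""
        if self.magnitude == 0.0:
            return self
        return CylinderVector(self.magnitude, (self.axis + 90.0) % 180.0)

    def __add__(self, other: "CylinderVector") -> "CylinderVector":
        return add_cylinders(self, other)


def corneal_cylinder(k_steep: float, k_flat: float, steep_axis: float) -> CylinderVector:
    """Corneal astigmatism from ordered keratometry readings.

    Parameters
    ----------
    k_steep, k_flat
        Steep and flat keratometry in diopters; ``k_steep >= k_flat > 0``.
    steep_axis
        Axis of the steep meridian in degrees (normalized modulo 180).
    """
    if k_flat <= 0:
        raise ValueError(f"keratometry must be positive, got k_flat={k_flat}")
    if k_steep < k_flat:
        raise ValueError(
            f"k_steep ({k_steep}) must be >= k_flat ({k_flat}); pass ordered readings"
        )
    return CylinderVector(k_steep - k_flat, steep_axis)


def add_cylinders(a: CylinderVector, b: CylinderVector) -> CylinderVector:
    """Vector sum of two cylinders in double-angle space."""
    ax, ay = a.to_double_angle()
    bx, by = b.to_double_angle()
    return CylinderVector.from_double_angle(ax + bx, ay + by)


def cross_cylinder(corneal: CylinderVector, sia: CylinderVector) -> CylinderVector:
    """Total astigmatism a toric IOL must correct: corneal cylinder plus SIA.

    With zero SIA the result equals the corneal cylinder exactly.
    """
    if sia.magnitude == 0.0:
        return corneal
    return add_cylinders(corneal, sia)
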