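"""SRK/T IOL sphere-power calculation and its inversion.

Implements the published 1990 SRK/T chain: keratometric radius 337.5/K,
corrected axial length, corneal width and height (with the square-root
guard), A-constant to ACD-constant conversion, retinal thickness term, and
thin-lens vergence with a 12 mm vertex distance.  Inversion finds the sphere
power whose predicted refraction hits a target (plano by default), rounded
to the commercial power step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .vectors import CylinderVector, corneal_cylinder

__all__ = [
    "BiometryCase",
    "IOLConstants",
    "SRKTDomainError",
    "srkt_elp",
    "srkt_predicted_refraction",
    "invert_for_target",
]

# Refractive indices and vertex distance of the published formula.
_NA = 1.336       # aqueous/vitreous
_NC_M1 = 0.333    # corneal index minus 1 (1.333 - 1)
_VERTEX_MM = 12.0

_POWER_LO = -10.0
_POWER_HI = 40.0


class SRKTDomainError(ValueError):
    """Raised when biometry falls outside the invertible power range."""


@dataclass(frozen=True)
class BiometryCase:
    """One eye's preoperative inputs.

    ``sia`` is the surgically induced astigmatism as a cylinder vector;
    ``target_refraction`` is the desired postoperative spherical equivalent
    (0 = plano).
    """

    axial_length: float
    k_flat: float
    k_steep: float
    steep_axis: float = 90.0
    sia: CylinderVector = field(default_factory=CylinderVector.zero)
    target_refraction: float = 0.0

    def __post_init__(self) -> None:
        if not 15.0 <= self.axial_length <= 35.0:
            raise ValueError(
                f"axial length {self.axial_length} mm outside sanity bounds [15, 35]"
            )
        if not 30.0 <= self.k_flat <= self.k_steep <= 60.0:
            raise ValueError(
                f"keratometry must satisfy 30 <= k_flat <= k_steep <= 60, "
                f"got flat={self.k_flat}, steep={self.k_steep}"
            )

    @property
    def mean_k(self) -> float:
        return 0.5 * (self.k_flat + self.k_steep)

    def corneal_cylinder(self) -> CylinderVector:
        return corneal_cylinder(self.k_steep, self.k_flat, self.steep_axis)


@dataclass(frozen=True)
class IOLConstants:
    """Lens-family constants: SRK/T A-constant and the commercial power step."""

    a_constant: float
    rounding_step: float = 0.5

    def __post_init__(self) -> None:
        if not 110.0 <= self.a_constant <= 125.0:
            raise ValueError(f"A-constant {self.a_constant} outside [110, 125]")
        if self.rounding_step <= 0:
            raise ValueError("rounding_step must be positive")


def srkt_elp(axial_length: float, mean_k: float, a_constant: float) -> float:
    """Estimated postoperative ELP (ACD estimate) in mm.

    Exposed separately because the vergence toricity model can reuse it.
    Clamps the corneal-height square root at zero for extreme K/AL
    combinations, emitting a warning.
    """
    r = 337.5 / mean_k
    if axial_length > 24.2:
        lcor = -3.446 + 1.715 * axial_length - 0.0237 * axial_length**2
    else:
        lcor = axial_length
    cw = -5.41 + 0.58412 * lcor + 0.098 * mean_k
    operand = r * r - cw * cw / 4.0
    if operand < 0.0:
        warnings.warn(
            "corneal height operand negative; clamped to 0 (extreme K/AL combination)",
            RuntimeWarning,
            stacklevel=2,
        )
        operand = 0.0
    h = r - math.sqrt(operand)
    acd_const = 0.62467 * a_constant - 68.747
    return h + (acd_const - 3.336)


def srkt_predicted_refraction(
    case: BiometryCase, iol_sphere: float, constants: IOLConstants
) -> float:
    """Predicted postoperative spherical-equivalent refraction in diopters."""
    if not _POWER_LO <= iol_sphere <= _POWER_HI:
        raise ValueError(f"IOL sphere {iol_sphere} outside [{_POWER_LO}, {_POWER_HI}]")
    k = case.mean_k
    al = case.axial_length
    r = 337.5 / k
    elp = srkt_elp(al, k, constants.a_constant)
    lopt = al + (0.65696 - 0.02029 * al)  # retinal-thickness-corrected length

    x1 = _NA * r - _NC_M1 * lopt
    x2 = _NA * r - _NC_M1 * elp
    p = iol_sphere
    num = 1000.0 * _NA * x1 - p * (lopt - elp) * x2
    den = _NA * (_VERTEX_MM * x1 + lopt * r) - 0.001 * p * (lopt - elp) * (
        _VERTEX_MM * x2 + elp * r
    )
    return num / den


def invert_for_target(case: BiometryCase, constants: IOLConstants) -> float:
    """IOL sphere power whose predicted refraction is closest to the target.

    Root-finds the continuous power (tolerance 1e-6 D) then rounds to
    ``constants.rounding_step``.  Raises :class:`SRKTDomainError` when no
    bracket exists inside the commercial power range.
    """

    def f(p: float) -> float:
        return srkt_predicted_refraction(case, p, constants) - case.target_refraction

    f_lo, f_hi = f(_POWER_LO), f(_POWER_HI)
    # predicted refraction is strictly decreasing in power, so f must change
    # sign on the bracket for a solution to exist
    if f_lo * f_hi > 0:
        raise SRKTDomainError(
            f"no IOL power in [{_POWER_LO}, {_POWER_HI}] D reaches target "
            f"{case.target_refraction} D for AL={case.axial_length}, mean K={case.mean_k}"
        )
    p_exact = brentq(f, _POWER_LO, _POWER_HI, xtol=1e-6)
    step = constants.rounding_step
    return round(p_exact / step) * step
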