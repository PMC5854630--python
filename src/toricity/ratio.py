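"""Toricity-ratio extraction from a calculator's printed inputs and outputs.

A toric calculator corrects a cross-cylinder ``C_c`` (diopters at the corneal
plane) with a lens of cylinder ``L_c`` at the IOL plane and reports a residual
astigmatism.  The residual is signed by its axis: unchanged axis means
under-correction (positive ``r``), a 90-degree flip means over-correction
(negative ``r``).  The toricity ratio is then

    tau = L_c / (C_c - r)

and ``C_c - r`` is the lens's astigmatism-correcting effect at the corneal
plane.  The forward model ``r = C_c - L_c / tau`` is the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vectors import CylinderVector

__all__ = [
    "ExtractionError",
    "ObliqueResidualError",
    "NonPhysicalExtractionError",
    "ExtractionInput",
    "ToricityRatio",
    "signed_residual",
    "extract_toricity",
    "predict_residual",
]

#: Angular tolerance (degrees) when matching the residual axis to the
#: cross-cylinder axis or its perpendicular.
AXIS_TOLERANCE_DEG = 5.0


class ExtractionError(ValueError):
    """Base class for extraction failures."""


class ObliqueResidualError(ExtractionError):
    """Residual axis is neither aligned with nor perpendicular to the target."""


class NonPhysicalExtractionError(ExtractionError):
    """The signed residual implies a non-positive corneal-plane correction."""


@dataclass(frozen=True)
class ExtractionInput:
    """Printable fields taken from one calculator run for one lens."""

    lens_cylinder_iol_plane: float
    cross_cylinder: CylinderVector
    residual_magnitude: float
    residual_axis: float

    def __post_init__(self) -> None:
        if self.lens_cylinder_iol_plane <= 0:
            raise ValueError("lens cylinder at the IOL plane must be positive")
        if self.residual_magnitude < 0:
            raise ValueError("residual magnitude must be >= 0")


@dataclass(frozen=True)
class ToricityRatio:
    """An extracted ratio plus the corneal-plane toricity it implies."""

    value: float
    corneal_plane_toricity: float

    @property
    def display_value(self) -> float:
        """The ratio at the two-decimal precision calculators print."""
        return round(self.value, 2)


def _axis_distance(a: float, b: float) -> float:
    """Smallest angular distance between two cylinder axes (period 180)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def signed_residual(
    residual_magnitude: float,
    residual_axis: float,
    corneal_steep_axis: float,
    tolerance_deg: float = AXIS_TOLERANCE_DEG,
) -> float:
    """Attach a sign to a residual magnitude from its reported axis.

    Positive when the residual axis matches the target steep axis
    (under-correction), negative when it is shifted 90 degrees
    (over-correction).  Zero magnitude carries no sign.  An axis in neither
    window, beyond ``tolerance_deg``, raises :class:`ObliqueResidualError`.
    """
    if residual_magnitude < 0:
        raise ValueError("residual magnitude must be >= 0")
    if residual_magnitude == 0:
        return 0.0
    d = _axis_distance(residual_axis, corneal_steep_axis)
    if d <= tolerance_deg:
        return +residual_magnitude
    if abs(d - 90.0) <= tolerance_deg:
        return -residual_magnitude
    raise ObliqueResidualError(
        f"oblique residual axis ({residual_axis} deg vs steep axis "
        f"{corneal_steep_axis} deg) - vector extraction required"
    )


def extract_toricity(inp: ExtractionInput) -> ToricityRatio:
    """Extract the toricity ratio from one lens's calculator output.

    Signs the residual against the cross-cylinder axis, then evaluates
    ``tau = L_c / (C_c - r)``.  Full precision is retained; use
    :attr:`ToricityRatio.display_value` for the printed two-decimal form.
    """
    r = signed_residual(
        inp.residual_magnitude, inp.residual_axis, inp.cross_cylinder.axis
    )
    corneal_plane = inp.cross_cylinder.magnitude - r
    if corneal_plane <= 0:
        raise NonPhysicalExtractionError(
            "non-physical extraction: residual >= attempted correction "
            f"(C_c={inp.cross_cylinder.magnitude}, r={r})"
        )
    return ToricityRatio(
        value=inp.lens_cylinder_iol_plane / corneal_plane,
        corneal_plane_toricity=corneal_plane,
    )


def predict_residual(
    lens_cylinder_iol_plane: float, cross_cylinder_magnitude: float, tau: float
) -> float:
    """Forward model: signed residual ``r = C_c - L_c / tau``.

    Positive means under-correction (axis unchanged); negative means
    over-correction (axis flips 90 degrees).
    """
    if tau <= 0:
        raise ValueError("toricity ratio must be positive")
    return cross_cylinder_magnitude - lens_cylinder_iol_plane / tau
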