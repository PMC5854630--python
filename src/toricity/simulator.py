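"""Forward simulator of a toric IOL calculator.

Given biometry, a lens catalog, and a toricity model (constant, tabulated,
or vergence-derived), the simulator reproduces what a commercial web
calculator shows: recommended lenses ranked by predicted residual
astigmatism, each with a residual magnitude and axis.  The printable output
is the black-box surface the extractor consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ratio import predict_residual
from .srkt import BiometryCase, IOLConstants, invert_for_target, srkt_elp
from .vectors import CylinderVector, cross_cylinder

__all__ = [
    "LensModel",
    "LensCatalog",
    "ToricityModel",
    "RecommendedLens",
    "CalculatorResult",
    "tau_for_case",
    "simulate_calculator",
]

_N_AQUEOUS = 1.336


@dataclass(frozen=True)
class LensModel:
    """One toric lens: cylinder at the IOL plane and its sphere-power range."""

    name: str
    cylinder_iol_plane: float
    sphere_min: float
    sphere_max: float
    a_constant: float

    def __post_init__(self) -> None:
        if self.cylinder_iol_plane <= 0:
            raise ValueError(f"{self.name}: cylinder at the IOL plane must be positive")
        if self.sphere_min > self.sphere_max:
            raise ValueError(f"{self.name}: sphere_min > sphere_max")


@dataclass(frozen=True)
class LensCatalog:
    lenses: tuple[LensModel, ...]

    def __post_init__(self) -> None:
        names = [lens.name for lens in self.lenses]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate lens names in catalog: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.lenses)

    def __iter__(self):
        return iter(self.lenses)

    def __getitem__(self, name: str) -> LensModel:
        for lens in self.lenses:
            if lens.name == name:
                return lens
        raise KeyError(name)


@dataclass(frozen=True)
class ToricityModel:
    """A rule mapping biometry to a toricity ratio.

    kind = "constant": always ``constant_value``.
    kind = "table": bilinear interpolation over an (axial length, mean K)
    grid, clamped at the edges.
    kind = "vergence": meridional thin-lens vergence at lens/cornea
    separation ELP; the ELP is either a fixed ``elp_mm`` or derived from the
    SRK/T internals via ``elp_a_constant``.
    """

    kind: str
    constant_value: Optional[float] = None
    table_axial_lengths: Optional[tuple[float, ...]] = None
    table_mean_ks: Optional[tuple[float, ...]] = None
    table_values: Optional[tuple[tuple[float, ...], ...]] = None  # [mean_k][al]
    elp_mm: Optional[float] = None
    elp_a_constant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.constant_value is None or self.constant_value <= 0:
                raise ValueError("constant model requires a positive constant_value")
        elif self.kind == "table":
            if not self.table_values or not self.table_axial_lengths or not self.table_mean_ks:
                raise ValueError("table model requires a non-empty table")
            vals = np.asarray(self.table_values, dtype=float)
            if vals.shape != (len(self.table_mean_ks), len(self.table_axial_lengths)):
                raise ValueError("table shape must be (len(mean_ks), len(axial_lengths))")
            if not ((vals > 1.0) & (vals < 3.0)).all():
                raise ValueError("table toricity ratios must lie in (1, 3)")
        elif self.kind == "vergence":
            if (self.elp_mm is None) == (self.elp_a_constant is None):
                raise ValueError("vergence model needs exactly one of elp_mm / elp_a_constant")
        else:
            raise ValueError(f"unknown toricity model kind: {self.kind!r}")

    @classmethod
    def constant(cls, value: float) -> "ToricityModel":
        return cls(kind="constant", constant_value=value)

    @classmethod
    def from_table(
        cls,
        axial_lengths: Sequence[float],
        mean_ks: Sequence[float],
        values: Sequence[Sequence[float]],
    ) -> "ToricityModel":
        return cls(
            kind="table",
            table_axial_lengths=tuple(axial_lengths),
            table_mean_ks=tuple(mean_ks),
            table_values=tuple(tuple(row) for row in values),
        )

    @classmethod
    def vergence(
        cls, elp_mm: Optional[float] = None, elp_a_constant: Optional[float] = None
    ) -> "ToricityModel":
        return cls(kind="vergence", elp_mm=elp_mm, elp_a_constant=elp_a_constant)


def _interp_table(model: ToricityModel, al: float, mean_k: float) -> float:
    als = np.asarray(model.table_axial_lengths, dtype=float)
    ks = np.asarray(model.table_mean_ks, dtype=float)
    vals = np.asarray(model.table_values, dtype=float)
    al = float(np.clip(al, als[0], als[-1]))
    mean_k = float(np.clip(mean_k, ks[0], ks[-1]))
    # interpolate along AL within each mean-K row, then across mean K
    row_vals = np.array([np.interp(al, als, row) for row in vals])
    return float(np.interp(mean_k, ks, row_vals))


def _vergence_tau(k_flat: float, k_steep: float, elp_mm: float) -> float:
    """Ratio of meridional IOL-plane to corneal-plane cylinder powers.

    For each meridian the IOL-plane power contribution behind a cornea of
    power K at separation ELP is -n / (n/K - ELP) plus an axial term common
    to both meridians, so the cylinder ratio reduces to the difference of
    the meridional terms over the corneal cylinder.  At ELP = 0 this is
    exactly 1.
    """
    elp_m = elp_mm / 1000.0
    n = _N_AQUEOUS

    def meridian_term(k: float) -> float:
        d = n / k - elp_m
        if d <= 0:
            raise ValueError("ELP exceeds the corneal focal distance; non-physical")
        return n / d

    return (meridian_term(k_steep) - meridian_term(k_flat)) / (k_steep - k_flat)


def tau_for_case(
    model: ToricityModel, case: BiometryCase, elp_mm: Optional[float] = None
) -> float:
    """Evaluate a toricity model for one biometry case.

    ``elp_mm`` overrides the model's configured ELP (vergence kind only).
    """
    if model.kind == "constant":
        return float(model.constant_value)
    if model.kind == "table":
        return _interp_table(model, case.axial_length, case.mean_k)
    # vergence
    if elp_mm is None:
        if model.elp_mm is not None:
            elp_mm = model.elp_mm
        else:
            elp_mm = srkt_elp(case.axial_length, case.mean_k, model.elp_a_constant)
    if case.k_steep == case.k_flat:
        # degenerate spherical cornea: take the limit at a nominal 1 D cylinder
        return _vergence_tau(case.mean_k - 0.5, case.mean_k + 0.5, elp_mm)
    return _vergence_tau(case.k_flat, case.k_steep, elp_mm)


@dataclass(frozen=True)
class RecommendedLens:
    """One row of simulator output, with the signed residual kept internal."""

    lens: LensModel
    residual: CylinderVector
    signed_residual_exact: float

    def printed(self) -> dict:
        """The fields a web calculator displays (residual at 2 decimals)."""
        return {
            "lens": self.lens.name,
            "cylinder_iol_plane_D": self.lens.cylinder_iol_plane,
            "residual_D": round(self.residual.magnitude, 2),
            "residual_axis_deg": self.residual.axis,
        }


@dataclass(frozen=True)
class CalculatorResult:
    recommended: tuple[RecommendedLens, ...]
    cross_cylinder: CylinderVector
    tau: float = field(repr=False, default=float("nan"))
    sphere_power: Optional[float] = None

    @property
    def selected(self) -> Optional[RecommendedLens]:
        return self.recommended[0] if self.recommended else None

    def printed(self) -> list[dict]:
        return [rec.printed() for rec in self.recommended]


def simulate_calculator(
    case: BiometryCase,
    catalog: LensCatalog,
    model: ToricityModel,
    max_recommendations: Optional[int] = None,
    policy: str = "min_residual",
) -> CalculatorResult:
    """Run the simulated calculator on one case.

    Computes the cross cylinder, evaluates the toricity model, predicts each
    eligible lens's residual ``r = C_c - L_c / tau``, and ranks lenses by
    residual magnitude (ties broken toward the lower cylinder, i.e.
    under-correction).  A lens is eligible when its sphere range covers the
    inverted SRK/T power for its own A-constant.

    ``policy`` selects the ranking rule: ``"min_residual"`` (smallest
    residual magnitude first) or ``"avoid_flip"`` (under-correcting lenses
    first, as some commercial calculators never recommend a lens that flips
    the astigmatic axis when an under-correcting alternative exists).
    """
    if policy not in ("min_residual", "avoid_flip"):
        raise ValueError(f"unknown selection policy: {policy!r}")
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    cc = cross_cylinder(case.corneal_cylinder(), case.sia)
    tau = tau_for_case(model, case)

    sphere_by_a: dict[float, float] = {}
    rows: list[RecommendedLens] = []
    sphere_used: Optional[float] = None
    for lens in catalog:
        if lens.a_constant not in sphere_by_a:
            sphere_by_a[lens.a_constant] = invert_for_target(
                case, IOLConstants(a_constant=lens.a_constant)
            )
        sphere = sphere_by_a[lens.a_constant]
        if not (lens.sphere_min <= sphere <= lens.sphere_max):
            continue
        sphere_used = sphere
        r = predict_residual(lens.cylinder_iol_plane, cc.magnitude, tau)
        axis = cc.axis if r >= 0 else (cc.axis + 90.0) % 180.0
        rows.append(
            RecommendedLens(
                lens=lens,
                residual=CylinderVector(abs(r), axis),
                signed_residual_exact=r,
            )
        )
    if not rows:
        warnings.warn(
            f"no lens in the catalog covers the required sphere power for "
            f"AL={case.axial_length}, mean K={case.mean_k}",
            RuntimeWarning,
            stacklevel=2,
        )
    if policy == "avoid_flip":
        rows.sort(
            key=lambda rec: (
                rec.signed_residual_exact < 0,
                abs(rec.signed_residual_exact),
                rec.lens.cylinder_iol_plane,
            )
        )
    else:
        rows.sort(
            key=lambda rec: (abs(rec.signed_residual_exact), rec.lens.cylinder_iol_plane)
        )
    if max_recommendations is not None:
        rows = rows[:max_recommendations]
    return CalculatorResult(
        recommended=tuple(rows), cross_cylinder=cc, tau=tau, sphere_power=sphere_used
    )
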