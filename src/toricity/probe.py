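"""Grid probing of a black-box toric calculator.

Builds a grid of (axial length, mean K) test cases with a fixed test
cylinder split about the mean, runs one calculator query per cell, extracts
a toricity ratio from the lens with the smallest predicted residual, and
classifies the resulting matrix as constant or variable.

The "calculator" is any callable taking a :class:`~toricity.srkt.BiometryCase`
and returning printable rows (lens name, cylinder at the IOL plane, residual
magnitude, residual axis) — the simulator, or a transcript of a real web
calculator's outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .ratio import ExtractionError, ExtractionInput, extract_toricity
from .srkt import BiometryCase, IOLConstants, invert_for_target
from .vectors import CylinderVector

__all__ = [
    "ProbeGrid",
    "CellProvenance",
    "ToricityMatrix",
    "build_cases",
    "probe",
    "classify",
    "transcript_calculator",
    "CLASSIFICATION_TOLERANCE",
]

#: Default constant/variable threshold: one unit in the second decimal on
#: each side, absorbing display rounding.
CLASSIFICATION_TOLERANCE = 0.02


@dataclass(frozen=True)
class ProbeGrid:
    axial_lengths: tuple[float, ...] = (21.0, 24.0, 27.0)
    mean_ks: tuple[float, ...] = (39.0, 43.0, 47.0)
    test_cylinder: float = 4.0
    steep_axis: float = 90.0

    def __post_init__(self) -> None:
        for name, seq in (("axial_lengths", self.axial_lengths), ("mean_ks", self.mean_ks)):
            if len(seq) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.test_cylinder <= 0:
            raise ValueError("test_cylinder must be positive")

    def case_for(self, axial_length: float, mean_k: float) -> BiometryCase:
        half = self.test_cylinder / 2.0
        return BiometryCase(
            axial_length=axial_length,
            k_flat=mean_k - half,
            k_steep=mean_k + half,
            steep_axis=self.steep_axis,
        )


@dataclass(frozen=True)
class CellProvenance:
    lens_name: str
    lens_cylinder: float
    residual_magnitude: float
    residual_axis: float
    error: Optional[str] = None


@dataclass
class ToricityMatrix:
    """Extracted ratios on the probe grid.

    ``values`` has shape (len(mean_ks), len(axial_lengths)) with rows in
    *descending* mean-K order (the conventional table orientation: flattest
    corneas at the bottom, axial length increasing left to right).  Invalid
    cells are NaN with the reason recorded in provenance.
    """

    axial_lengths: tuple[float, ...]
    mean_ks_desc: tuple[float, ...]
    values: np.ndarray
    provenance: list[list[Optional[CellProvenance]]] = field(default_factory=list)
    classification: Optional[str] = None
    constant_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mean_ks_desc), len(self.axial_lengths)):
            raise ValueError("matrix shape must be (len(mean_ks), len(axial_lengths))")

    def valid_values(self) -> np.ndarray:
        flat = self.values.ravel()
        return flat[~np.isnan(flat)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ToricityMatrix):
            return NotImplemented
        return (
            self.axial_lengths == other.axial_lengths
            and self.mean_ks_desc == other.mean_ks_desc
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.classification == other.classification
            and (
                (self.constant_value is None and other.constant_value is None)
                or (
                    self.constant_value is not None
                    and other.constant_value is not None
                    and math.isclose(self.constant_value, other.constant_value)
                )
            )
        )


def build_cases(
    grid: ProbeGrid, constants: IOLConstants
) -> list[tuple[BiometryCase, float]]:
    """One (case, inverted sphere power) pair per grid cell.

    Iterates mean K descending (rows) then axial length ascending (columns),
    matching the matrix orientation.
    """
    out = []
    for mean_k in sorted(grid.mean_ks, reverse=True):
        for al in grid.axial_lengths:
            case = grid.case_for(al, mean_k)
            out.append((case, invert_for_target(case, constants)))
    return out


def probe(
    calculator: Callable[[BiometryCase], Sequence[dict]],
    grid: ProbeGrid,
    tolerance: float = CLASSIFICATION_TOLERANCE,
) -> ToricityMatrix:
    """Probe a calculator over the grid and classify the resulting matrix.

    Per cell the calculator's recommendations are taken; the lens predicting
    the smallest residual astigmatism is chosen and its printed fields are
    fed through the extraction formula.  Cells where extraction fails are
    marked invalid; the matrix is still returned.
    """
    mean_ks_desc = tuple(sorted(grid.mean_ks, reverse=True))
    shape = (len(mean_ks_desc), len(grid.axial_lengths))
    values = np.full(shape, np.nan)
    provenance: list[list[Optional[CellProvenance]]] = [
        [None] * shape[1] for _ in range(shape[0])
    ]
    for i, mean_k in enumerate(mean_ks_desc):
        for j, al in enumerate(grid.axial_lengths):
            case = grid.case_for(al, mean_k)
            rows = list(calculator(case))
            if not rows:
                provenance[i][j] = CellProvenance("", float("nan"), float("nan"),
                                                  float("nan"), error="no recommendation")
                continue
            best = min(rows, key=lambda row: row["residual_D"])
            prov = CellProvenance(
                lens_name=best["lens"],
                lens_cylinder=best["cylinder_iol_plane_D"],
                residual_magnitude=best["residual_D"],
                residual_axis=best["residual_axis_deg"],
            )
            try:
                result = extract_toricity(
                    ExtractionInput(
                        lens_cylinder_iol_plane=best["cylinder_iol_plane_D"],
                        cross_cylinder=CylinderVector(
                            grid.test_cylinder, grid.steep_axis
                        ),
                        residual_magnitude=best["residual_D"],
                        residual_axis=best["residual_axis_deg"],
                    )
                )
            except ExtractionError as exc:
                provenance[i][j] = CellProvenance(
                    prov.lens_name, prov.lens_cylinder, prov.residual_magnitude,
                    prov.residual_axis, error=str(exc),
                )
                continue
            values[i, j] = result.value
            provenance[i][j] = prov
    matrix = ToricityMatrix(
        axial_lengths=tuple(grid.axial_lengths),
        mean_ks_desc=mean_ks_desc,
        values=values,
        provenance=provenance,
    )
    classify(matrix, tolerance=tolerance)
    return matrix


def classify(
    matrix: ToricityMatrix, tolerance: float = CLASSIFICATION_TOLERANCE
) -> tuple[str, Optional[float]]:
    """Label a matrix constant or variable; updates the matrix in place.

    Constant iff (max - min) over valid cells is within ``tolerance``, in
    which case the constant value is the cell median.  Fewer than two valid
    cells is indeterminate.
    """
    valid = matrix.valid_values()
    if valid.size < 2:
        matrix.classification = "indeterminate"
        matrix.constant_value = None
        return "indeterminate", None
    if float(valid.max() - valid.min()) <= tolerance:
        matrix.classification = "constant"
        matrix.constant_value = float(np.median(valid))
    else:
        matrix.classification = "variable"
        matrix.constant_value = None
    return matrix.classification, matrix.constant_value


def transcript_calculator(
    cells: dict[tuple[float, float], Sequence[dict]],
) -> Callable[[BiometryCase], Sequence[dict]]:
    """Adapt manually transcribed calculator outputs to the probe interface.

    ``cells`` maps (axial_length, mean_k) to the printed rows recorded from
    a real web calculator; probing a cell that was not transcribed returns
    no recommendation.
    """

    def calculator(case: BiometryCase) -> Sequence[dict]:
        key = (case.axial_length, case.mean_k)
        for (al, k), rows in cells.items():
            if math.isclose(al, key[0], abs_tol=1e-9) and math.isclose(k, key[1], abs_tol=1e-9):
                return rows
        return []

    return calculator
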