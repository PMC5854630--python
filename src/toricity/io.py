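"""Readers and writers: lens catalogs, toricity matrices, transcripts."""

from __future__ import annotations

import csv
import json
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .probe import CellProvenance, ToricityMatrix
from .simulator import LensCatalog, LensModel

__all__ = [
    "CatalogFormatError",
    "read_catalog",
    "shipped_catalog",
    "shipped_catalog_names",
    "write_matrix",
    "read_matrix",
    "read_transcript",
]

_CATALOG_COLUMNS = ["name", "cylinder_iol_plane_D", "sphere_min_D", "sphere_max_D", "a_constant"]
_TRANSCRIPT_COLUMNS = [
    "axial_length_mm", "mean_k_D", "lens", "cylinder_iol_plane_D",
    "residual_D", "residual_axis_deg",
]


class CatalogFormatError(ValueError):
    pass


def read_catalog(path: Union[str, Path]) -> LensCatalog:
    """Read a lens catalog CSV (columns: name, cylinder, sphere range, A)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CATALOG_COLUMNS:
            raise CatalogFormatError(
                f"{path}: header must be {','.join(_CATALOG_COLUMNS)}, got {reader.fieldnames}"
            )
        lenses = []
        for lineno, row in enumerate(reader, start=2):
            try:
                lenses.append(
                    LensModel(
                        name=row["name"].strip(),
                        cylinder_iol_plane=float(row["cylinder_iol_plane_D"]),
                        sphere_min=float(row["sphere_min_D"]),
                        sphere_max=float(row["sphere_max_D"]),
                        a_constant=float(row["a_constant"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise CatalogFormatError(f"{path}: row {lineno}: {exc}") from exc
    if not lenses:
        warnings.warn(f"{path}: catalog is empty", RuntimeWarning, stacklevel=2)
    return LensCatalog(lenses=tuple(lenses))


def shipped_catalog_names() -> list[str]:
    data = resources.files("toricity") / "data"
    return sorted(p.name[: -len(".csv")] for p in data.iterdir() if p.name.endswith(".csv"))


def shipped_catalog(name: str) -> LensCatalog:
    """Load a catalog shipped with the package (e.g. ``alcon_acrysof``)."""
    ref = resources.files("toricity") / "data" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return read_catalog(path)


def write_matrix(matrix: ToricityMatrix, path: Union[str, Path], fmt: str = "csv") -> None:
    """Serialize a toricity matrix; invalid cells render as NA.

    CSV carries values only (full precision, table orientation); JSON
    additionally carries per-cell provenance and the classification.
    """
    path = Path(path)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mean_K_D"] + [f"AL_{al:g}" for al in matrix.axial_lengths])
            for i, mean_k in enumerate(matrix.mean_ks_desc):
                row = [f"{mean_k:g}"]
                for j in range(len(matrix.axial_lengths)):
                    v = matrix.values[i, j]
                    row.append("NA" if math.isnan(v) else repr(float(v)))
                writer.writerow(row)
    elif fmt == "json":
        payload = {
            "axial_lengths_mm": list(matrix.axial_lengths),
            "mean_ks_D_descending": list(matrix.mean_ks_desc),
            "values": [
                [None if math.isnan(v) else float(v) for v in row]
                for row in matrix.values
            ],
            "classification": matrix.classification,
            "constant_value": matrix.constant_value,
            "provenance": [
                [None if p is None else vars(p) for p in row]
                for row in matrix.provenance
            ] if matrix.provenance else None,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown matrix format: {fmt!r}")


def read_matrix(path: Union[str, Path], fmt: Optional[str] = None) -> ToricityMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "csv"
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        header = rows[0]
        axial_lengths = tuple(float(c[len("AL_"):]) for c in header[1:])
        mean_ks = tuple(float(r[0]) for r in rows[1:])
        values = np.array(
            [[float("nan") if c == "NA" else float(c) for c in r[1:]] for r in rows[1:]]
        )
        return ToricityMatrix(axial_lengths=axial_lengths, mean_ks_desc=mean_ks, values=values)
    if fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        values = np.array(
            [[float("nan") if v is None else v for v in row] for row in payload["values"]]
        )
        provenance = []
        if payload.get("provenance"):
            for row in payload["provenance"]:
                provenance.append(
                    [None if p is None else CellProvenance(**p) for p in row]
                )
        matrix = ToricityMatrix(
            axial_lengths=tuple(payload["axial_lengths_mm"]),
            mean_ks_desc=tuple(payload["mean_ks_D_descending"]),
            values=values,
            provenance=provenance,
        )
        matrix.classification = payload.get("classification")
        matrix.constant_value = payload.get("constant_value")
        return matrix
    raise ValueError(f"unknown matrix format: {fmt!r}")


def read_transcript(path: Union[str, Path]) -> dict[tuple[float, float], list[dict]]:
    """Read manually transcribed calculator outputs, one row per lens per cell.

    Columns: axial_length_mm, mean_k_D, lens, cylinder_iol_plane_D,
    residual_D, residual_axis_deg.  Returns the cell map consumed by
    :func:`toricity.probe.transcript_calculator`.
    """
    path = Path(path)
    cells: dict[tuple[float, float], list[dict]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _TRANSCRIPT_COLUMNS:
            raise CatalogFormatError(
                f"{path}: header must be {','.join(_TRANSCRIPT_COLUMNS)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (float(row["axial_length_mm"]), float(row["mean_k_D"]))
                cells.setdefault(key, []).append(
                    {
                        "lens": row["lens"].strip(),
                        "cylinder_iol_plane_D": float(row["cylinder_iol_plane_D"]),
                        "residual_D": float(row["residual_D"]),
                        "residual_axis_deg": float(row["residual_axis_deg"]),
                    }
                )
            except (TypeError, ValueError) as exc:
                raise CatalogFormatError(f"{path}: row {lineno}: {exc}") from exc
    return cells
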