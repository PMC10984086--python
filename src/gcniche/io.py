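"""Readers and writers for the package's file contracts.

Formats: cell tables and GC polygons as CSV/TSV; nuclear images and label
masks as single-channel 16-bit TIFF; expression as TSV (genes in rows,
samples in columns) with a sidecar design TSV; gene sets as GMT; results as
JSON.  The separator is inferred from the file suffix (``.tsv`` → tab,
anything else → comma).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile

from .containers import CELL_COLUMNS, CellMap, ExpressionMatrix, GeneSignature

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_polygon",
    "write_polygon",
    "read_expression",
    "write_expression",
    "read_design",
    "read_gmt",
    "write_gmt",
    "read_image",
    "write_image",
    "write_json",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_polygon(path: str | Path) -> shapely.Polygon:
    """Polygon vertices from a CSV/TSV with columns x_um, y_um."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    for c in ("x_um", "y_um"):
        if c not in df.columns:
            raise ValueError(f"polygon file is missing column {c!r}")
    return shapely.Polygon(df[["x_um", "y_um"]].to_numpy(dtype=float))


def write_polygon(polygon: shapely.Polygon, path: str | Path) -> None:
    path = Path(path)
    xy = np.asarray(polygon.exterior.coords)[:-1]
    pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]}).to_csv(
        path, sep=_sep(path), index=False, float_format="%.17g"
    )


def read_cell_table(path: str | Path, polygon_path: str | Path | None = None) -> CellMap:
    """Load a cell table (CSV/TSV) into a :class:`CellMap`.

    Required columns: ``cell_id``, ``x_um``, ``y_um``, ``phenotype``.  The
    GC polygon is read from ``polygon_path`` when given; otherwise the
    convex hull of the points (padded by 1 μm) stands in.  Duplicate ids
    and non-numeric coordinates are rejected with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path.name} is missing column(s): {missing}")
    for c in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(
                f"non-numeric coordinate in column {c!r} at row {row}: {df[c].iloc[row]!r}"
            )
        df[c] = coerced.astype(float)
    if polygon_path is not None:
        polygon = read_polygon(polygon_path)
    else:
        pts = shapely.MultiPoint(df[["x_um", "y_um"]].to_numpy(dtype=float))
        polygon = pts.convex_hull.buffer(1.0)
    return CellMap(df, polygon)


def write_cell_table(cellmap: CellMap, path: str | Path) -> None:
    # %.17g round-trips float64 exactly, so a reloaded map reproduces
    # downstream statistics bit for bit
    path = Path(path)
    cellmap.cells.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def read_expression(path: str | Path, design_path: str | Path | None = None) -> ExpressionMatrix:
    """Genes × samples TSV (first column = gene id) plus optional design TSV.

    Duplicate gene rows are an error; ragged rows are rejected by the
    parser.
    """
    path = Path(path)
    values = pd.read_csv(path, sep=_sep(path), index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path.name}")
    design = pd.DataFrame()
    if design_path is not None:
        dp = Path(design_path)
        design = pd.read_csv(dp, sep=_sep(dp), index_col=0)
    return ExpressionMatrix(values, design)


def write_expression(expr: ExpressionMatrix, path: str | Path, design_path: str | Path | None = None) -> None:
    path = Path(path)
    expr.values.to_csv(path, sep=_sep(path), index_label="gene")
    if design_path is not None and len(expr.design):
        dp = Path(design_path)
        expr.design.to_csv(dp, sep=_sep(dp), index_label="sample")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """GMT lines: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sigs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno} has no genes: {line[:60]!r}")
        name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"GMT set {name!r} (line {lineno}) is empty")
        sigs.append(GeneSignature(name=name, genes=genes))
    return sigs


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.name] + list(s.genes)) for s in signatures]
    Path(path).write_text("\n".join(lines) + "\n")


def read_image(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {arr.shape}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path: str | Path) -> None:
    """Write any result object (dataclasses included) as sorted-key JSON."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
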