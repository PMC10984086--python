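"""Shared in-memory containers for germinal-center niche analyses.

The package moves three kinds of data between modules:

* :class:`CellMap` — a 2-D point pattern of cells (μm coordinates) with
  phenotype labels and the germinal-center (GC) boundary polygon;
* :class:`ExpressionMatrix` — a genes × samples matrix of log2 expression
  values with a sample-level design table (paired regions of interest, or
  cohort membership);
* :class:`GeneSignature` — a named gene set, optionally with per-gene
  directions.

All downstream statistics consume these containers rather than raw files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "CellMap",
    "ExpressionMatrix",
    "GeneSignature",
    "substream",
]

CELL_COLUMNS = ("cell_id", "x_um", "y_um", "phenotype")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, independent random stream derived from ``seed``.

    Every stochastic stage draws from its own stream so that stages can be
    re-run (or reordered) without perturbing each other's randomness.  The
    stream is keyed by a CRC of its name, folded into a
    :class:`numpy.random.SeedSequence` together with the top-level seed.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class CellMap:
    """Point pattern of cells inside a GC region-of-interest polygon.

    Parameters
    ----------
    cells
        One row per cell with columns ``cell_id``, ``x_um``, ``y_um``,
        ``phenotype`` and optionally ``compartment_true`` (``"DZ"``/``"LZ"``,
        known for simulated data only).
    polygon
        The GC boundary as a shapely polygon, in μm.
    """

    cells: pd.DataFrame
    polygon: shapely.Polygon

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table is missing column(s): {missing}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        for c in ("x_um", "y_um"):
            if not np.issubdtype(self.cells[c].dtype, np.number):
                raise ValueError(f"column {c!r} must be numeric")
        self.cells = self.cells.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    def points(self, phenotype: str | None = None, compartment: str | None = None) -> np.ndarray:
        """(n, 2) array of coordinates, optionally filtered by phenotype
        and/or true compartment label."""
        df = self.cells
        if phenotype is not None:
            df = df[df["phenotype"] == phenotype]
        if compartment is not None:
            if "compartment_true" not in df.columns:
                raise ValueError("cell table has no compartment_true column")
            df = df[df["compartment_true"] == compartment]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.cells["phenotype"].unique())

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression with sample-level design metadata.

    ``values`` is indexed by gene id with one column per sample; ``design``
    is indexed by sample id and carries whatever grouping columns the
    analysis needs (``pair``/``zone`` for matched DZ–LZ regions, ``cohort``
    for tumor datasets, known latent variables for simulations).
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(self.design):
            if not self.design.index.equals(pd.Index(self.values.columns)):
                missing = set(self.values.columns) ^ set(self.design.index)
                raise ValueError(
                    f"design rows do not match sample columns (mismatch: {sorted(missing)[:5]})"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        found = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[found], self.design)


@dataclass
class GeneSignature:
    """A named gene set; ``directions`` optionally maps gene → ±1."""

    name: str
    genes: list[str]
    directions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
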