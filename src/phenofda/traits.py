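"""Trait extraction from segmented masks and assembly of the analysis matrix.

Plant height and width are the inclusive row/column extents of the foreground
bounding box (a single pixel has extent 1) scaled by the physical pixel size;
plant size is the foreground area.  Per-plant, per-day records are pivoted
into a plants x union-day-grid matrix with explicit missing entries, since
imaging schedules are typically irregular and not every plant is observed on
every day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PixelScale",
    "TraitRecord",
    "TraitMatrix",
    "extract_pheno",
    "assemble_trait_matrix",
    "records_to_frame",
    "frame_to_records",
    "TRAIT_NAMES",
]

TRAIT_NAMES = ("height", "width", "size")


@dataclass(frozen=True)
class PixelScale:
    """Physical size of one pixel: Xsize mm horizontally, Ysize mm vertically."""

    Xsize: float = 1.0
    Ysize: float = 1.0

    def __post_init__(self):
        if self.Xsize <= 0 or self.Ysize <= 0:
            raise ValueError("pixel sizes must be positive")


@dataclass(frozen=True)
class TraitRecord:
    plant_id: str
    genotype: str
    block: str
    day: float
    height: float
    width: float
    size: float


@dataclass
class TraitMatrix:
    """One trait on the union day grid with explicit missingness.

    ``values`` is (n_plants, n_days) with NaN marking unobserved cells;
    ``days`` is strictly increasing; ``meta`` carries one row per plant
    (plant_id, genotype, block) in the same order as ``values``.
    """

    values: np.ndarray
    days: np.ndarray
    meta: pd.DataFrame
    trait: str = "size"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.days = np.asarray(self.days, dtype=np.float64)
        if self.values.shape != (len(self.meta), self.days.size):
            raise ValueError("values shape does not match meta/days")
        if self.days.size > 1 and not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            raise ValueError("every plant needs at least one observed entry")

    @property
    def n_plants(self) -> int:
        return self.values.shape[0]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)


def extract_pheno(mask: np.ndarray, scale: PixelScale = PixelScale()):
    """Extract (height, width, size) from a segmented mask.

    height = inclusive row extent * Ysize, width = inclusive column extent *
    Xsize, size = foreground pixel count * Xsize * Ysize.  An empty mask
    yields (0, 0, 0) with a warning so failed segmentations survive batch
    runs and show up as zeros.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        warnings.warn("extract_pheno: empty mask, returning zeros", stacklevel=2)
        return 0.0, 0.0, 0.0
    height = float(rows.max() - rows.min() + 1) * scale.Ysize
    width = float(cols.max() - cols.min() + 1) * scale.Xsize
    size = float(rows.size) * scale.Xsize * scale.Ysize
    return height, width, size


def records_to_frame(records) -> pd.DataFrame:
    """Flat CSV-ready table: plant_id, genotype, block, day, height, width, size."""
    return pd.DataFrame(
        [
            (r.plant_id, r.genotype, r.block, r.day, r.height, r.width, r.size)
            for r in records
        ],
        columns=["plant_id", "genotype", "block", "day", *TRAIT_NAMES],
    )


def frame_to_records(df: pd.DataFrame):
    return [
        TraitRecord(
            str(row.plant_id), str(row.genotype), str(row.block),
            float(row.day), float(row.height), float(row.width), float(row.size),
        )
        for row in df.itertuples(index=False)
    ]


def assemble_trait_matrix(records, trait: str = "size") -> TraitMatrix:
    """Pivot trait records into a plants x union-day-grid matrix.

    Columns are the sorted union of observed days; a cell is NaN when that
    plant was not imaged that day.  Duplicate (plant_id, day) pairs and empty
    record lists are errors.
    """
    if trait not in TRAIT_NAMES:
        raise ValueError(f"unknown trait {trait!r}, expected one of {TRAIT_NAMES}")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(list(records))
    if len(df) == 0:
        raise ValueError("no trait records")
    dup = df.duplicated(subset=["plant_id", "day"])
    if dup.any():
        pairs = df.loc[dup, ["plant_id", "day"]].values.tolist()
        raise ValueError(f"duplicate (plant_id, day) pairs: {pairs}")
    geno = df.groupby("plant_id", sort=False).agg(genotype=("genotype", "nunique"), block=("block", "nunique"))
    if (geno > 1).any().any():
        raise ValueError("a plant_id maps to more than one genotype or block")

    wide = df.pivot(index="plant_id", columns="day", values=trait)
    wide = wide.reindex(index=pd.unique(df["plant_id"]), columns=sorted(df["day"].unique()))
    meta = (
        df.drop_duplicates("plant_id")[["plant_id", "genotype", "block"]]
        .set_index("plant_id")
        .loc[wide.index]
        .reset_index()
    )
    return TraitMatrix(wide.to_numpy(), np.asarray(wide.columns, dtype=float), meta, trait)
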