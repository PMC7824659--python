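"""CSV readers and writers for flow tables, kernels, and population vectors.

Two origin–destination dialects are supported:

* **long**: header ``origin,dest,count``, one row per zone pair; zone ids
  are opaque strings ordered by first appearance; missing pairs are zero
  flows; duplicate pairs are summed with a warning.
* **wide**: a square matrix whose first column holds origin ids and whose
  remaining column headers are destination ids.

Everything is written back as wide CSV with zone ids preserved in input
order.  Numbers are formatted with ``repr`` (17 significant digits) so a
write/read round trip is bit-identical.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FlowMatrix, ModelError, PopulationVector, SpatialKernel

logger = logging.getLogger(__name__)


def _read_long(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, dtype={"origin": str, "dest": str}, float_precision="round_trip")
    expected = {"origin", "dest", "count"}
    if not expected.issubset(df.columns):
        raise ModelError(f"long OD file needs columns {sorted(expected)}, got {list(df.columns)}")
    if (df["count"] < 0).any():
        raise ModelError("negative counts in OD file")
    zones: list[str] = []
    seen = set()
    for z in pd.concat([df["origin"], df["dest"]]):
        if z not in seen:
            seen.add(z)
            zones.append(z)
    index = {z: i for i, z in enumerate(zones)}
    counts = np.zeros((len(zones), len(zones)))
    dupes = df.duplicated(subset=["origin", "dest"]).sum()
    if dupes:
        logger.warning("OD file %s: %d duplicate origin-dest pair(s) summed", path, dupes)
    for _, row in df.iterrows():
        counts[index[row["origin"]], index[row["dest"]]] += float(row["count"])
    return counts, tuple(zones)


def _read_wide(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ModelError(f"ragged or incomplete wide matrix in {path}")
    zone_ids = tuple(str(z) for z in df.columns)
    row_ids = tuple(str(z) for z in df.index)
    if row_ids != zone_ids:
        raise ModelError(
            f"wide matrix row ids {row_ids[:3]}... do not match column ids {zone_ids[:3]}..."
        )
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ModelError("negative counts in OD file")
    return values, zone_ids


def read_flows(path: str | Path, dialect: str = "long", window_years: int = 1) -> FlowMatrix:
    """Read an origin–destination flow table (``dialect`` = long | wide)."""
    path = Path(path)
    if dialect == "long":
        counts, zone_ids = _read_long(path)
    elif dialect == "wide":
        counts, zone_ids = _read_wide(path)
    else:
        raise ModelError(f"unknown OD dialect {dialect!r}")
    return FlowMatrix(counts, window_years=window_years, zone_ids=zone_ids)


def read_kernel(path: str | Path, zero_diagonal: bool = False) -> SpatialKernel:
    """Read a spatial kernel from a wide CSV matrix."""
    values, zone_ids = _read_wide(Path(path))
    return SpatialKernel(values, zone_ids=zone_ids, zero_diagonal=zero_diagonal)


def read_population(path: str | Path) -> PopulationVector:
    """Read a ``zone,population`` CSV."""
    df = pd.read_csv(path, dtype={"zone": str}, float_precision="round_trip")
    if not {"zone", "population"}.issubset(df.columns):
        raise ModelError("population file needs columns zone,population")
    return PopulationVector(
        df["population"].to_numpy(dtype=float), zone_ids=tuple(df["zone"])
    )


def write_matrix(path: str | Path, obj: FlowMatrix | SpatialKernel | np.ndarray,
                 zone_ids: Sequence[str] | None = None) -> None:
    """Write a square matrix as wide CSV with zone ids, round-trip exact."""
    if isinstance(obj, FlowMatrix):
        values, ids = obj.counts, obj.zone_ids
    elif isinstance(obj, SpatialKernel):
        values, ids = obj.h, obj.zone_ids
    else:
        values = np.asarray(obj, dtype=float)
        if values.size == 0:
            raise ModelError("refusing to write an empty matrix")
        if zone_ids is None:
            raise ModelError("raw arrays need explicit zone ids")
        ids = tuple(zone_ids)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["zone", *ids])
        for zid, row in zip(ids, values):
            writer.writerow([zid, *[repr(float(v)) for v in row]])


def write_vector(path: str | Path, obj: PopulationVector | np.ndarray,
                 zone_ids: Sequence[str] | None = None,
                 value_header: str = "value") -> None:
    """Write a per-zone vector as ``zone,<value_header>`` CSV."""
    if isinstance(obj, PopulationVector):
        values, ids = obj.values, obj.zone_ids
    else:
        values = np.asarray(obj, dtype=float)
        if values.size == 0:
            raise ModelError("refusing to write an empty vector")
        if zone_ids is None:
            raise ModelError("raw arrays need explicit zone ids")
        ids = tuple(zone_ids)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["zone", value_header])
        for zid, v in zip(ids, values):
            writer.writerow([zid, repr(float(v))])
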