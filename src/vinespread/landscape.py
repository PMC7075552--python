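"""Grid data model: rasterization of presence points, distances, masks, areas.

Coordinates are planar meters on a projected grid; there is no geodesy.
Cells are indexed 0-based, row-major from the north-west corner.  A cell's
spatial extent is the half-open square [x0, x0+s) x (y0-s, y0] (x0 = west
edge, y0 = north edge), so every point maps to exactly one cell and a
point on a shared edge belongs to the cell whose extent includes it under
that convention.

Grids are exchanged on disk as plain-text ESRI ASCII grids (ncols/nrows/
xllcorner/yllcorner/cellsize/NODATA_value header followed by row-major
values, north row first).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "OccupancyGrid",
    "PresencePointSet",
    "RasterizeReport",
    "rasterize_points",
    "centroid_distance",
    "cell_area_acres",
    "infested_area_acres",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_points_csv",
    "write_points_csv",
    "occupied_cells_geojson",
    "SQ_METERS_PER_ACRE",
]

#: International acre.
SQ_METERS_PER_ACRE = 4046.8564224


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid.

    ``origin_x``/``origin_y`` are the coordinates (m) of the *centroid* of
    the north-west cell; ``cell_size_m`` defaults to the 500 m cells used
    for timberland accounting (each cell is 25 ha ~ 61.78 acres).
    """

    n_rows: int
    n_cols: int
    cell_size_m: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def west_edge(self) -> float:
        return self.origin_x - self.cell_size_m / 2.0

    @property
    def north_edge(self) -> float:
        return self.origin_y + self.cell_size_m / 2.0

    def cell_centroid(self, row: int, col: int) -> tuple[float, float]:
        self._check_index(row, col)
        return (
            self.origin_x + col * self.cell_size_m,
            self.origin_y - row * self.cell_size_m,
        )

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its (row, col), or None if outside the grid.

        Under the half-open extent [x0, x0+s) x (y0-s, y0] this is plain
        floor division: a cell's west and north edges are inclusive, its
        east and south edges belong to the neighbouring cell.
        """
        s = self.cell_size_m
        col = int(np.floor((x - self.west_edge) / s))
        row = int(np.floor((self.north_edge - y) / s))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def _check_index(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(
                f"cell ({row}, {col}) outside grid of shape {self.shape}"
            )


@dataclass
class PresencePointSet:
    """Planar presence coordinates (m), optionally labelled by source."""

    points: np.ndarray  # shape (n, 2)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("presence point coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class OccupancyGrid:
    """Binary presence/absence over a grid, restricted to a binary mask.

    ``cells`` holds 1 where the invader is present; ``mask`` holds 1 where
    a cell is eligible (timberland).  Occupied cells are always a subset
    of masked cells.
    """

    spec: GridSpec
    cells: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        for name, arr in (("cells", self.cells), ("mask", self.mask)):
            if arr.shape != self.spec.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.spec.shape}")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be strictly binary")
        if np.any(self.cells & ~self.mask):
            raise ValueError("occupied cells must be a subset of masked cells")

    @property
    def n_occupied(self) -> int:
        return int(self.cells.sum())

    def infested_acres(self) -> float:
        return infested_area_acres(self.n_occupied, self.spec)


@dataclass(frozen=True)
class RasterizeReport:
    """Audit counts from point-to-grid rasterization."""

    n_points: int
    n_outside_grid: int
    n_off_mask: int
    n_occupied_cells: int


def rasterize_points(
    points: PresencePointSet, spec: GridSpec, mask: np.ndarray
) -> tuple[OccupancyGrid, RasterizeReport]:
    """Burn presence points onto the masked grid.

    A cell becomes 1 iff at least one point falls inside its extent and
    the cell is masked.  Points outside the grid or on unmasked cells are
    counted in the report (and trigger a warning), never an error; an
    empty point set yields a valid all-zero grid.
    """
    mask = np.asarray(mask, dtype=np.uint8)
    cells = np.zeros(spec.shape, dtype=np.uint8)
    n_outside = 0
    n_off_mask = 0
    for x, y in points.points:
        rc = spec.point_to_cell(x, y)
        if rc is None:
            n_outside += 1
            continue
        if not mask[rc]:
            n_off_mask += 1
            continue
        cells[rc] = 1
    if len(points) == 0:
        warnings.warn("empty presence point set: occupancy grid is all-zero")
    if n_outside or n_off_mask:
        warnings.warn(
            f"dropped {n_outside} point(s) outside the grid and "
            f"{n_off_mask} off-mask point(s) during rasterization"
        )
    report = RasterizeReport(
        n_points=len(points),
        n_outside_grid=n_outside,
        n_off_mask=n_off_mask,
        n_occupied_cells=int(cells.sum()),
    )
    return OccupancyGrid(spec=spec, cells=cells, mask=mask), report


def centroid_distance(
    spec: GridSpec, cell_i: tuple[int, int], cell_j: tuple[int, int]
) -> float:
    """Euclidean distance (m) between two cell centroids."""
    xi, yi = spec.cell_centroid(*cell_i)
    xj, yj = spec.cell_centroid(*cell_j)
    return float(np.hypot(xi - xj, yi - yj))


def cell_area_acres(spec: GridSpec) -> float:
    """Area of one cell in acres (61.7763 acres for 500 m cells)."""
    return spec.cell_size_m**2 / SQ_METERS_PER_ACRE


def infested_area_acres(n_cells: int, spec: GridSpec) -> float:
    """Total area (acres) of ``n_cells`` grid cells."""
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    return n_cells * cell_area_acres(spec)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    spec: GridSpec,
    nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (north row first)."""
    values = np.asarray(values)
    if values.shape != spec.shape:
        raise ValueError(f"array shape {values.shape} != grid {spec.shape}")
    s = spec.cell_size_m
    yll = spec.north_edge - spec.n_rows * s
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.west_edge:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {s:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in values:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (values, spec, nodata)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"ASCII grid {path} missing header keys: {sorted(missing)}")
    values = np.asarray(rows, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"ASCII grid {path}: data shape {values.shape} != header "
            f"({n_rows}, {n_cols})"
        )
    s = header["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_m=s,
        origin_x=header["xllcorner"] + s / 2.0,
        origin_y=header["yllcorner"] + n_rows * s - s / 2.0,
    )
    return values, spec, header.get("nodata_value", -9999.0)


def write_points_csv(path: str | Path, points: PresencePointSet) -> None:
    """Write presence points as CSV with header ``x,y[,label]``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if points.labels is None:
            writer.writerow(["x", "y"])
            writer.writerows((f"{x:.3f}", f"{y:.3f}") for x, y in points.points)
        else:
            writer.writerow(["x", "y", "label"])
            writer.writerows(
                (f"{x:.3f}", f"{y:.3f}", lab)
                for (x, y), lab in zip(points.points, points.labels)
            )


def read_points_csv(path: str | Path) -> PresencePointSet:
    """Read a presence-points CSV with header ``x,y[,label]`` (meters)."""
    xs: list[list[float]] = []
    labels: list[str] = []
    has_labels = False
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        cols = [c.strip().lower() for c in header]
        if cols[:2] != ["x", "y"]:
            raise ValueError(f"points CSV {path} must have header x,y[,label]")
        has_labels = len(cols) >= 3 and cols[2] == "label"
        for rec in reader:
            if not rec:
                continue
            xs.append([float(rec[0]), float(rec[1])])
            if has_labels:
                labels.append(rec[2] if len(rec) > 2 else "")
    return PresencePointSet(
        points=np.asarray(xs, dtype=float).reshape(-1, 2),
        labels=labels if has_labels else None,
    )


def occupied_cells_geojson(grid: OccupancyGrid) -> dict:
    """Occupied cells as a GeoJSON FeatureCollection of square polygons."""
    spec = grid.spec
    s = spec.cell_size_m
    features = []
    for row, col in zip(*np.nonzero(grid.cells)):
        cx, cy = spec.cell_centroid(int(row), int(col))
        x0, x1 = cx - s / 2, cx + s / 2
        y0, y1 = cy - s / 2, cy + s / 2
        features.append(
            {
                "type": "Feature",
                "properties": {"row": int(row), "col": int(col)},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                    ],
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
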