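"""Domain types and raster/vector/tabular I/O shared by all pipeline stages.

Rasters are single-band, north-up grids addressed by 0-based (row, col) with
cell-centre georeferencing; supported on disk as GeoTIFF (via tifffile with
GeoTIFF tags) and ESRI ASCII grid. Tabular inputs (backscatter samples,
ground-truth points) are plain CSV with a header row.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

#: The seven habitat class labels used throughout the pipeline.
CLASS_LABELS = ("MB", "INV", "MRI", "NVB", "MBI", "MBMR", "MGI")

DEFAULT_NODATA = -9999.0


class FormatError(ValueError):
    """Raised when an on-disk artefact violates its format contract."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns or has bad labels."""


class AlignmentError(ValueError):
    """Raised when rasters that must be co-registered are not."""


@dataclass(frozen=True)
class BackscatterSample:
    """One calibrated per-beam backscatter measurement.

    ``angle`` is the incidence angle in degrees, 0 at nadir. By default angles
    are stored unsigned (port/starboard folded); readers accept signed input
    behind a flag. ``level`` is backscatter strength in dB (typically negative).
    """

    ping_id: int
    beam_id: int
    x: float
    y: float
    depth: float
    angle: float
    level: float
    line_id: int = 0

    def is_valid(self) -> bool:
        return (
            0.0 <= self.angle <= 90.0
            and math.isfinite(self.level)
            and math.isfinite(self.x)
            and math.isfinite(self.y)
        )


@dataclass(frozen=True)
class GroundTruthPoint:
    """A georeferenced habitat observation with a train/test split tag."""

    x: float
    y: float
    label: str
    split: str = "train"

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise SchemaError(
                f"unknown habitat label {self.label!r}; valid labels: {', '.join(CLASS_LABELS)}"
            )
        if self.split not in ("train", "test"):
            raise SchemaError(f"split must be 'train' or 'test', got {self.split!r}")


@dataclass
class RasterGrid:
    """Georeferenced single-band grid — the common currency of all layers.

    ``origin_x``/``origin_y`` are the coordinates of the grid's upper-left
    corner; row index increases southward (north-up convention). Values equal
    to ``nodata`` are masked.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask()] = np.nan
        return out

    def same_geometry(self, other: "RasterGrid", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol, abs_tol=1e-9)
        )

    def cell_of(self, x, y):
        """(row, col) of the cell containing point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def cell_centre(self, row, col):
        """(x, y) of the centre of cell (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def in_bounds(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same geometry and different values."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SegmentSet:
    """Contiguous labelled regions of a mosaic.

    ``label_raster`` holds integer segment ids (nodata where the mosaic had
    none); ``areas`` maps segment id to pixel count; ``polygons`` (optional)
    maps segment id to a shapely geometry produced by vectorisation.
    """

    label_raster: RasterGrid
    areas: dict[int, int]
    polygons: dict[int, object] = field(default_factory=dict)

    @property
    def segment_ids(self) -> list[int]:
        return sorted(self.areas)

    def __len__(self) -> int:
        return len(self.areas)


@dataclass
class FeatureStack:
    """An ordered, co-registered collection of named raster layers."""

    names: list[str]
    layers: list[RasterGrid]

    def __post_init__(self):
        if len(self.names) != len(self.layers):
            raise ValueError("names and layers must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[self.names.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_raster(grid: RasterGrid, path: str) -> None:
    """Write a RasterGrid to GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    elif ext in (".asc", ".txt"):
        _write_ascii_grid(grid, path)
    else:
        raise FormatError(f"unsupported raster extension {ext!r} (use .tif or .asc)")


def read_raster(path: str) -> RasterGrid:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return _read_geotiff(path)
    if ext in (".asc", ".txt"):
        return _read_ascii_grid(path)
    raise FormatError(f"unsupported raster extension {ext!r} (use .tif or .asc)")


def _write_geotiff(grid: RasterGrid, path: str) -> None:
    import tifffile

    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        # tie raster corner (0,0) to the world upper-left corner
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(
        path,
        grid.values.astype(np.float64),
        extratags=extratags,
        description=json.dumps({"crs_tag": grid.crs_tag}),
    )


def _read_geotiff(path: str) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags:
            raise FormatError("GeoTIFF missing ModelPixelScale tag (cell size)")
        if _TAG_MODEL_TIEPOINT not in tags:
            raise FormatError("GeoTIFF missing ModelTiepoint tag (origin)")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs_tag = ""
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs_tag = json.loads(desc.value).get("crs_tag", "")
            except (ValueError, AttributeError):
                pass
    return RasterGrid(
        values=np.asarray(values, dtype=float),
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        cell_size=float(scale[0]),
        nodata=nodata,
        crs_tag=crs_tag,
    )


def _write_ascii_grid(grid: RasterGrid, path: str) -> None:
    # ESRI convention references the lower-left corner
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: str) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    idx = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"malformed ASCII grid header field {parts[0]!r}") from exc
            idx += 1
        else:
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"ASCII grid header missing field(s): {', '.join(missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.loadtxt(lines[idx:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"malformed ASCII grid data block: {exc}") from exc
    if values.shape != (n_rows, n_cols):
        raise FormatError(
            f"ASCII grid data shape {values.shape} does not match header "
            f"({n_rows} rows x {n_cols} cols)"
        )
    cell = header["cellsize"]
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ("ping_id", "beam_id", "x", "y", "depth", "angle", "level")


def read_samples(path: str, signed_angles: bool = False) -> tuple[list[BackscatterSample], int]:
    """Read per-beam backscatter samples from CSV.

    Returns (samples, n_rejected). Rows violating sample invariants are
    dropped and counted rather than raising. With ``signed_angles`` the
    angle column may be negative (port side) and is folded to unsigned.
    """
    samples: list[BackscatterSample] = []
    rejected = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("sample CSV is empty (no header row)")
        missing = [c for c in _SAMPLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"sample CSV missing column(s): {', '.join(missing)}")
        has_line = "line_id" in reader.fieldnames
        for row in reader:
            try:
                angle = float(row["angle"])
                if signed_angles:
                    angle = abs(angle)
                s = BackscatterSample(
                    ping_id=int(row["ping_id"]),
                    beam_id=int(row["beam_id"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    depth=float(row["depth"]),
                    angle=angle,
                    level=float(row["level"]),
                    line_id=int(row["line_id"]) if has_line else 0,
                )
            except (ValueError, KeyError):
                rejected += 1
                continue
            if s.is_valid():
                samples.append(s)
            else:
                rejected += 1
    return samples, rejected


def write_samples(samples: list[BackscatterSample], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SAMPLE_COLUMNS + ("line_id",))
        for s in samples:
            writer.writerow(
                [int(s.ping_id), int(s.beam_id), repr(float(s.x)), repr(float(s.y)),
                 repr(float(s.depth)), repr(float(s.angle)), repr(float(s.level)), int(s.line_id)]
            )


def read_ground_truth(path: str) -> list[GroundTruthPoint]:
    """Read ground-truth observation points from CSV (columns x, y, label[, split])."""
    points: list[GroundTruthPoint] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("ground-truth CSV is empty (no header row)")
        missing = [c for c in ("x", "y", "label") if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"ground-truth CSV missing column(s): {', '.join(missing)}")
        has_split = "split" in reader.fieldnames
        for row in reader:
            points.append(
                GroundTruthPoint(
                    x=float(row["x"]),
                    y=float(row["y"]),
                    label=row["label"],
                    split=row["split"] if has_split else "train",
                )
            )
    return points


def write_ground_truth(points: list[GroundTruthPoint], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "label", "split"])
        for p in points:
            writer.writerow([repr(float(p.x)), repr(float(p.y)), p.label, p.split])


# ---------------------------------------------------------------------------
# Layer stacking
# ---------------------------------------------------------------------------


def stack_layers(named_grids: dict[str, RasterGrid]) -> FeatureStack:
    """Assemble co-registered grids into a FeatureStack; raise on misalignment."""
    names = list(named_grids)
    layers = [named_grids[n] for n in names]
    if not layers:
        raise ValueError("cannot stack zero layers")
    ref = layers[0]
    for name, grid in zip(names[1:], layers[1:]):
        if not ref.same_geometry(grid):
            raise AlignmentError(
                f"layer {name!r} is not co-registered with {names[0]!r}: "
                f"shape {grid.shape} vs {ref.shape}, origin "
                f"({grid.origin_x}, {grid.origin_y}) vs ({ref.origin_x}, {ref.origin_y}), "
                f"cell {grid.cell_size} vs {ref.cell_size}"
            )
    return FeatureStack(names=names, layers=layers)


def sample_stack(stack: FeatureStack, points: list[tuple[float, float]]):
    """Extract one feature row per point from the stack.

    Returns (table, valid) where table is (n_points, n_layers) float array and
    valid flags rows whose cells hold data in every layer. Points outside the
    raster bounds raise ValueError.
    """
    ref = stack.layers[0]
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    inb = ref.in_bounds(xs, ys)
    if not np.all(inb):
        bad = int(np.argmin(inb))
        raise ValueError(f"point {bad} at ({xs[bad]}, {ys[bad]}) is outside raster bounds")
    rows, cols = ref.cell_of(xs, ys)
    table = np.empty((len(points), len(stack.layers)), dtype=float)
    valid = np.ones(len(points), dtype=bool)
    for j, grid in enumerate(stack.layers):
        vals = grid.values[rows, cols]
        table[:, j] = vals
        valid &= grid.mask()[rows, cols]
    return table, valid
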