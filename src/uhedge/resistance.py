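"""Categorical landcover rasters and resistance surfaces.

A landcover mosaic assigns each cell of a regular projected grid exactly one
class (buildings, gardens, roads, ...).  Under a named movement hypothesis each
class maps either to a finite per-cell resistance (>= 1) or to an absolute
barrier: a cell an animal cannot traverse at all.  The NULL (isolation by
distance) hypothesis gives every traversable cell resistance 1; the empirical
hypothesis (EMP) uses literature-derived values; single-landcover hypotheses
set one feature group to 1 or 100 against the opposite background.

Rasters are stored row-major with cell (0, 0) at the top-left corner; cell
centres sit at ``origin + ((col + 0.5), -(row + 0.5)) * resolution`` in
projected metres.  Grid I/O uses the plain-text ESRI ASCII grid format with a
JSON sidecar legend mapping integer codes to class names.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

UNCLASSIFIED = "Unclassified"

#: landcover groups used by the single-feature hypotheses and the urban mask
CLASS_GROUPS = {
    "rail": {"Railways"},
    "road": {"Highways", "Large street", "Small street"},
    "green": {
        "Parks and Playspace",
        "Cemeteries",
        "Allotments",
        "Private Garden",
        "Lawn",
        "Amenity",
        "Woodland",
    },
    "farm": {"Farmland"},
    "water": {"Linear Water", "Wetland"},
}

#: classes counted as urban when computing urban-proportion buffers
URBAN_CLASSES = {
    "Buildings",
    "Highways",
    "Large street",
    "Small street",
    "Railways",
    "Impervious",
}


class GridError(ValueError):
    """Raised for malformed grids or grid-geometry mismatches."""


@dataclass
class LandcoverRaster:
    """Integer class codes on a regular grid of square cells.

    Parameters
    ----------
    codes
        2-D integer array of legend codes, row 0 at the top (north).
    resolution
        Cell edge length in metres.
    origin
        Projected ``(x, y)`` of the grid's top-left corner.
    legend
        Mapping from integer code to class name.  Code 0 is reserved for
        ``Unclassified`` and is always present.
    """

    codes: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise GridError("landcover codes must be a 2-D array")
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        self.legend = dict(self.legend)
        self.legend.setdefault(0, UNCLASSIFIED)
        present = set(np.unique(self.codes))
        missing = present - set(self.legend)
        if missing:
            raise GridError(f"codes without a legend entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def class_name(self, code: int) -> str:
        return self.legend[int(code)]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.resolution,
            y0 - (row + 0.5) * self.resolution,
        )

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing the projected point."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.resolution))
        row = int(math.floor((y0 - y) / self.resolution))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise GridError(f"point ({x}, {y}) outside raster bounds")
        return row, col

    def class_mask(self, names) -> np.ndarray:
        """Boolean mask of cells whose class name is in ``names``."""
        if isinstance(names, str):
            names = {names}
        codes = {c for c, n in self.legend.items() if n in set(names)}
        return np.isin(self.codes, sorted(codes))


@dataclass
class PrecedenceTable:
    """Ordered class list, highest priority first (buildings before gardens)."""

    order: list[str]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("precedence table contains duplicate classes")

    def rank(self, name: str) -> int:
        return self.order.index(name)


@dataclass
class ResistanceHypothesis:
    """Named class -> resistance map with a set of absolute-barrier classes."""

    name: str
    resistance: dict[str, float]
    barriers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.barriers = set(self.barriers)
        overlap = self.barriers & set(self.resistance)
        if overlap:
            raise ValueError(f"classes both mapped and barrier: {sorted(overlap)}")
        bad = {k: v for k, v in self.resistance.items() if v < 1}
        if bad:
            raise ValueError(f"resistances must be >= 1, got {bad}")


@dataclass
class ResistanceSurface:
    """Per-cell movement cost on a grid; barrier cells are non-traversable."""

    resistance: np.ndarray  # finite >= 1 on traversable cells, nan on barriers
    barrier: np.ndarray  # boolean
    hypothesis: str
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.resistance = np.asarray(self.resistance, dtype=float)
        self.barrier = np.asarray(self.barrier, dtype=bool)
        if self.resistance.shape != self.barrier.shape:
            raise GridError("resistance and barrier grids differ in shape")
        if not (~self.barrier).any():
            raise GridError("surface has no traversable cell")
        trav = self.resistance[~self.barrier]
        if not np.all(np.isfinite(trav) & (trav >= 1)):
            raise GridError("traversable resistances must be finite and >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.resistance.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.resolution,
            y0 - (row + 0.5) * self.resolution,
        )


def mosaic_with_precedence(
    masks: dict[str, np.ndarray],
    precedence: PrecedenceTable,
    resolution: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandcoverRaster:
    """Combine per-class 0/1 masks into one raster, first class in the
    precedence order winning where masks overlap; uncovered cells become
    Unclassified."""
    if not masks:
        raise GridError("no class masks supplied")
    shapes = {np.asarray(m).shape for m in masks.values()}
    if len(shapes) != 1:
        raise GridError(f"class masks disagree on grid shape: {shapes}")
    unknown = set(masks) - set(precedence.order)
    if unknown:
        raise GridError(f"masks without a precedence entry: {sorted(unknown)}")
    shape = shapes.pop()
    codes = np.zeros(shape, dtype=np.int32)
    legend = {0: UNCLASSIFIED}
    # walk lowest priority first so higher-priority classes overwrite
    ranked = sorted(masks, key=precedence.rank, reverse=True)
    code_of = {name: i + 1 for i, name in enumerate(precedence.order)}
    for name in ranked:
        m = np.asarray(masks[name], dtype=bool)
        codes[m] = code_of[name]
        legend[code_of[name]] = name
    return LandcoverRaster(codes, resolution, origin, legend)


def buffer_linear_class(mask: np.ndarray, buffer_m: float, resolution: float) -> np.ndarray:
    """Dilate a 0/1 mask by ceil(buffer_m / resolution) cells (chessboard
    metric), so thin linear features survive rasterisation."""
    if buffer_m < 0:
        raise ValueError("buffer must be nonnegative")
    cells = math.ceil(buffer_m / resolution)
    mask = np.asarray(mask, dtype=bool)
    if cells == 0:
        return mask.copy()
    size = 2 * cells + 1
    return ndimage.binary_dilation(mask, structure=np.ones((size, size), dtype=bool))


def build_resistance_surface(
    lc: LandcoverRaster,
    hyp: ResistanceHypothesis,
    barrier_resistance: float | None = None,
) -> ResistanceSurface:
    """Cell-wise lookup of the hypothesis map over the landcover legend.

    Every class present in the legend must be mapped by the hypothesis, either
    to a finite resistance or to the barrier set.  ``barrier_resistance``
    substitutes a finite value for barriers (sensitivity checks only).
    """
    present = {lc.legend[c] for c in np.unique(lc.codes)}
    unmapped = present - set(hyp.resistance) - hyp.barriers
    if unmapped:
        raise GridError(
            f"hypothesis {hyp.name!r} does not map classes: {sorted(unmapped)}"
        )
    res = np.full(lc.shape, np.nan)
    barrier = np.zeros(lc.shape, dtype=bool)
    for code in np.unique(lc.codes):
        name = lc.legend[code]
        cells = lc.codes == code
        if name in hyp.barriers:
            if barrier_resistance is not None:
                res[cells] = barrier_resistance
            else:
                barrier[cells] = True
        else:
            res[cells] = hyp.resistance[name]
    return ResistanceSurface(res, barrier, hyp.name, lc.resolution, lc.origin)


def urban_proportion(
    lc: LandcoverRaster,
    point: tuple[float, float],
    radius_m: float,
    urban_classes: set[str] | None = None,
) -> float:
    """Fraction of urban cells among cells whose centre lies within
    ``radius_m`` of ``point``; buffers clipped at the raster edge use only
    in-bounds cells."""
    urban_classes = URBAN_CLASSES if urban_classes is None else set(urban_classes)
    nr, nc = lc.shape
    x0, y0 = lc.origin
    px, py = point
    cols = x0 + (np.arange(nc) + 0.5) * lc.resolution
    rows = y0 - (np.arange(nr) + 0.5) * lc.resolution
    d2 = (rows[:, None] - py) ** 2 + (cols[None, :] - px) ** 2
    inside = d2 <= radius_m**2
    n = int(inside.sum())
    if n == 0:
        # fall back to the containing cell for sub-cell radii
        row, col = lc.cell_at(px, py)
        inside = np.zeros(lc.shape, dtype=bool)
        inside[row, col] = True
        n = 1
    urban = lc.class_mask(urban_classes)
    return float(urban[inside].sum()) / n


def resample_majority(lc: LandcoverRaster, factor: int) -> LandcoverRaster:
    """Coarsen by an integer factor using majority rule (ties -> lowest code).

    Mirrors the coarse regional-scale grid used for diversity buffers; the
    connectivity analysis stays on the native grid.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = lc.shape
    out = np.zeros((math.ceil(nr / factor), math.ceil(nc / factor)), dtype=np.int32)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = lc.codes[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            vals, counts = np.unique(block, return_counts=True)
            out[i, j] = vals[np.argmax(counts)]
    return LandcoverRaster(out, lc.resolution * factor, lc.origin, lc.legend)


def clip(lc: LandcoverRaster, row0: int, row1: int, col0: int, col1: int) -> LandcoverRaster:
    """Clip to a row/col window, keeping georeferencing consistent."""
    x0, y0 = lc.origin
    origin = (x0 + col0 * lc.resolution, y0 - row0 * lc.resolution)
    return LandcoverRaster(lc.codes[row0:row1, col0:col1], lc.resolution, origin, lc.legend)


# ---------------------------------------------------------------------------
# packaged hypotheses (Zurich radio-tracking EMP values + single-feature sets)
# ---------------------------------------------------------------------------

def load_hypotheses(path: str | Path | None = None) -> dict[str, ResistanceHypothesis]:
    """Load named hypotheses from YAML (the packaged defaults if no path)."""
    if path is None:
        text = resources.files("uhedge").joinpath("hypotheses.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        out[name] = ResistanceHypothesis(
            name=name,
            resistance={k: float(v) for k, v in spec.get("resistance", {}).items()},
            barriers=set(spec.get("barriers", [])),
        )
    return out


def default_precedence() -> PrecedenceTable:
    """The canonical class priority: buildings first, gardens last."""
    return PrecedenceTable(
        [
            "Buildings",
            "Path",
            "Waterbodies",
            "Railways",
            "Small street",
            "Highways",
            "Large street",
            "Linear Water",
            "Wetland",
            "Impervious",
            "Woodland",
            "Lawn",
            "Amenity",
            "Parks and Playspace",
            "Cemeteries",
            "Allotments",
            "Farmland",
            "Private Garden",
        ]
    )


# ---------------------------------------------------------------------------
# text raster I/O (ESRI ASCII grid + JSON legend)
# ---------------------------------------------------------------------------

def write_ascii_grid(
    array: np.ndarray,
    resolution: float,
    origin: tuple[float, float],
    path: str | Path,
    nodata: float = -9999,
) -> None:
    array = np.asarray(array)
    nr, nc = array.shape
    x0, y0 = origin
    vals = np.where(np.isfinite(array.astype(float)), array, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {x0}\n")
        fh.write(f"yllcorner {y0 - nr * resolution}\n")
        fh.write(f"cellsize {resolution}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in vals:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Return (array with nan at nodata, resolution, top-left origin, nodata)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise GridError(f"ASCII grid header incomplete: {sorted(set(header))}")
    arr = np.array(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridError("ASCII grid body does not match declared dimensions")
    nodata = header.get("nodata_value", -9999.0)
    arr[arr == nodata] = np.nan
    res = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + arr.shape[0] * res)
    return arr, res, origin, nodata


def write_landcover(lc: LandcoverRaster, path: str | Path) -> None:
    """Write a landcover raster as .asc plus a .legend.json sidecar."""
    path = Path(path)
    write_ascii_grid(lc.codes, lc.resolution, lc.origin, path)
    sidecar = path.with_suffix(path.suffix + ".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in lc.legend.items()}, indent=1))


def read_landcover(path: str | Path) -> LandcoverRaster:
    path = Path(path)
    arr, res, origin, _ = read_ascii_grid(path)
    sidecar = path.with_suffix(path.suffix + ".legend.json")
    legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LandcoverRaster(np.nan_to_num(arr, nan=0).astype(np.int32), res, origin, legend)
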