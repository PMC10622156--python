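"""Shared spatial containers and file interchange.

All grids live on a north-up raster lattice: the origin is the north-west
corner, rows run southward, columns eastward, and every polygon-to-pixel
assignment in the package uses cell-*center* containment (a cell belongs to a
polygon iff its center point falls inside). Rasters are interchanged as plain
multiband TIFF with a YAML sidecar carrying the georeferencing; vectors as
GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

# Pinned value table for collapsed (general) class maps, written into raster
# metadata so files are bit-exact interchangeable between tools.
NO_DATA = 0
LAND = 1
NO_SEAGRASS = 2
SEAGRASS = 3
GENERAL_CLASSES = ("no_data", "land", "no_seagrass", "seagrass")

# WorldView-2/3-like band centers (nm): coastal, blue, green, yellow, red,
# red edge, NIR1, NIR2.
DEFAULT_WAVELENGTHS_NM = (427.0, 478.0, 546.0, 608.0, 659.0, 724.0, 831.0, 908.0)


class ParameterError(ValueError):
    """A parameter violates an operation precondition."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete configuration (missing spectra, unmapped class...)."""


class ProcessingError(RuntimeError):
    """A stage cannot proceed on this input (e.g. no water pixels)."""


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a raster lattice.

    ``origin_x``/``origin_y`` locate the north-west corner of the grid; cells
    are square with side ``cell_size`` (m). Cell (row, col) has its center at
    ``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``.
    """

    width: int
    height: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local-cartesian-m"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ParameterError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each of shape (height, width)."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; may fall outside the grid."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)

    def cell_box(self, row: int, col: int) -> shapely.Geometry:
        x0 = self.origin_x + col * self.cell_size
        y1 = self.origin_y - row * self.cell_size
        return shapely.box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class ClassMap:
    """Per-pixel categorical map on a georeferenced lattice.

    ``labels`` holds integer codes indexing ``catalog`` (scene-specific class
    names). ``collapse_table`` maps each scene class onto one of the four
    general classes. A map whose catalog *is* the general catalog (in pinned
    code order) is called collapsed.
    """

    labels: np.ndarray
    grid: GridSpec
    catalog: tuple[str, ...]
    collapse_table: dict[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ParameterError("label grid does not match grid_spec dimensions")
        if self.labels.size and self.labels.max() >= len(self.catalog):
            raise ConfigurationError("label code outside catalog")

    @property
    def is_general(self) -> bool:
        return self.catalog == GENERAL_CLASSES

    def code_of(self, name: str) -> int:
        return self.catalog.index(name)

    def counts(self) -> dict[str, int]:
        n = np.bincount(self.labels.ravel(), minlength=len(self.catalog))
        return {name: int(c) for name, c in zip(self.catalog, n)}


@dataclass
class ReferenceFeature:
    ref_id: str
    geometry: shapely.Geometry
    attrs: dict


@dataclass
class ReferenceSet:
    """Reference seagrass data in one of the four field dialects.

    dialect ∈ {presence_polygons, presence_points, cover_points,
    density_polygons}; features carry the dialect's label column
    (``presence`` 0/1, ``cover_pct`` float, or ``dens_cls`` str).
    """

    dialect: str
    features: list[ReferenceFeature]
    crs: str = "local-cartesian-m"
    metadata: dict = field(default_factory=dict)

    DIALECTS = ("presence_polygons", "presence_points", "cover_points", "density_polygons")

    def __post_init__(self) -> None:
        if self.dialect not in self.DIALECTS:
            raise ConfigurationError(f"unknown reference dialect: {self.dialect!r}")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class DensityScheme:
    """Ordered ordinal percent-cover classes; cover below the lowest bound is
    not delineated by the reference program."""

    name: str
    classes: tuple[tuple[str, float, float], ...]  # (label, lower, upper) in percent

    def __post_init__(self) -> None:
        prev_upper = None
        for label, lo, hi in self.classes:
            if not (0 <= lo < hi <= 100):
                raise ConfigurationError(f"class {label!r} bounds invalid: [{lo}, {hi}]")
            if prev_upper is not None and lo < prev_upper:
                raise ConfigurationError("class bounds overlap or are out of order")
            prev_upper = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.classes)

    @property
    def lowest_bound(self) -> float:
        return self.classes[0][1]

    def classify(self, cover_pct: float) -> str | None:
        """Class label containing cover_pct, or None below the lowest bound.

        Percent cover sitting exactly on a shared boundary goes to the upper
        class (the schemes quote e.g. patchy 25-75, continuous 75-100)."""
        if cover_pct < self.lowest_bound:
            return None
        chosen = None
        for label, lo, hi in self.classes:
            if lo <= cover_pct <= hi:
                chosen = label  # later classes win shared boundaries
        return chosen


# Reference programs' published density schemes.
TAMPA_SCHEME = DensityScheme("tampa", (("patchy", 25.0, 75.0), ("continuous", 75.0, 100.0)))
BACK_SOUND_SCHEME = DensityScheme("backsound", (("patchy", 5.0, 70.0), ("continuous", 70.0, 100.0)))
CHESAPEAKE_SCHEME = DensityScheme(
    "chesapeake",
    (
        ("1-10%", 1.0, 10.0),
        ("11-40%", 11.0, 40.0),
        ("41-70%", 41.0, 70.0),
        ("71-100%", 71.0, 100.0),
    ),
)
SCHEMES = {s.name: s for s in (TAMPA_SCHEME, BACK_SOUND_SCHEME, CHESAPEAKE_SCHEME)}


def scheme_from_config(spec) -> DensityScheme:
    """Resolve a scheme from a name, a YAML path, or a mapping."""
    if isinstance(spec, DensityScheme):
        return spec
    if isinstance(spec, str):
        if spec in SCHEMES:
            return SCHEMES[spec]
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    return DensityScheme(
        spec.get("name", "custom"),
        tuple((c["label"], float(c["lower"]), float(c["upper"])) for c in spec["classes"]),
    )


# ---------------------------------------------------------------------------
# Raster interchange: multiband TIFF + YAML sidecar with the grid spec.
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_raster(
    path,
    data: np.ndarray,
    grid: GridSpec,
    *,
    wavelengths: Sequence[float] | None = None,
    value_table: dict[int, str] | None = None,
    metadata: dict | None = None,
) -> None:
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.shape[1:] != grid.shape:
        raise ParameterError("raster does not match grid_spec dimensions")
    tifffile.imwrite(path, data)
    side = {"grid": grid.to_dict()}
    if wavelengths is not None:
        side["wavelengths_nm"] = [float(w) for w in wavelengths]
    if value_table is not None:
        side["value_table"] = {int(k): v for k, v in value_table.items()}
    if metadata:
        side["metadata"] = metadata
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=True)


def read_raster(path) -> tuple[np.ndarray, GridSpec, dict]:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    with open(_sidecar(path)) as fh:
        side = yaml.safe_load(fh)
    return data, GridSpec.from_dict(side["grid"]), side


def write_classmap(path, cmap: ClassMap) -> None:
    if not cmap.is_general:
        raise ConfigurationError("only collapsed (general) class maps are written to raster")
    write_raster(
        path,
        cmap.labels.astype(np.uint8),
        cmap.grid,
        value_table={i: name for i, name in enumerate(GENERAL_CLASSES)},
        metadata=cmap.metadata or None,
    )


def read_classmap(path) -> ClassMap:
    data, grid, side = read_raster(path)
    return ClassMap(
        labels=data[0].astype(np.int16),
        grid=grid,
        catalog=GENERAL_CLASSES,
        metadata=side.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Vector interchange: GeoJSON.
# ---------------------------------------------------------------------------

def write_geojson(path, ref: ReferenceSet) -> None:
    fc = {
        "type": "FeatureCollection",
        "seagrassmap": {"dialect": ref.dialect, "crs": ref.crs, **ref.metadata},
        "features": [
            {
                "type": "Feature",
                "geometry": geom_mapping(f.geometry),
                "properties": {"ref_id": f.ref_id, **f.attrs},
            }
            for f in ref.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, sort_keys=True)


def read_geojson(path, dialect: str | None = None) -> ReferenceSet:
    with open(path) as fh:
        fc = json.load(fh)
    meta = fc.get("seagrassmap", {})
    dialect = dialect or meta.get("dialect")
    if dialect is None:
        raise ConfigurationError(f"{path}: no reference dialect recorded or supplied")
    feats = []
    for i, f in enumerate(fc["features"]):
        props = dict(f.get("properties") or {})
        ref_id = str(props.pop("ref_id", i))
        feats.append(ReferenceFeature(ref_id, geom_shape(f["geometry"]), props))
    crs = meta.get("crs", "local-cartesian-m")
    extra = {k: v for k, v in meta.items() if k not in ("dialect", "crs")}
    return ReferenceSet(dialect=dialect, features=feats, crs=crs, metadata=extra)
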