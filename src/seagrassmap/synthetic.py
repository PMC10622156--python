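"""Synthetic scenes, truth cover fields, classifier-error realizations, and
reference datasets in all four field dialects.

Real seagrass mapping campaigns pair a commercial multispectral scene with
agency reference delineations; neither can be redistributed, so this module
emulates the full chain at desk scale. The truth field is a spatially
autocorrelated fractional-cover surface: Gaussian-smoothed white noise is
rank-transformed to a U-shaped Beta marginal whose mean is exactly the target
cover — one knob (``patch_scale``) moves the field between sparse, patchy
beds and dense, continuous meadows. Scenes are
rendered as cover-weighted linear mixtures of seagrass and bare-substrate
endmember spectra plus band noise; classifier error is emulated directly by a
miss/false-alarm process so the agreement stages can be tested in isolation;
and reference delineation behaviors (polygon amalgamation over patchy beds,
point transects, ordinal density tiling) produce the four reference dialects.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata
from skimage.morphology import closing as binary_closing
from skimage.morphology import disk

from .classification import ROISet
from .core import (
    DEFAULT_WAVELENGTHS_NM,
    GENERAL_CLASSES,
    LAND,
    NO_DATA,
    NO_SEAGRASS,
    SEAGRASS,
    ClassMap,
    ConfigurationError,
    DensityScheme,
    GridSpec,
    ParameterError,
    ReferenceFeature,
    ReferenceSet,
)
from .radiometry import RrsScene


@dataclass
class TruthField:
    """True fractional seagrass cover on a georeferenced lattice."""

    cover: np.ndarray
    grid: GridSpec
    land_mask: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=np.float64)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.cover.shape != self.grid.shape or self.land_mask.shape != self.grid.shape:
            raise ParameterError("grids do not match grid_spec dimensions")
        if self.cover.min() < 0 or self.cover.max() > 1:
            raise ParameterError("cover values must lie in [0, 1]")
        if np.any(self.cover[self.land_mask] != 0):
            raise ParameterError("cover must be zero on land")

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask


@dataclass(frozen=True)
class SceneSpectra:
    """Endmember spectra for scene rendering: one 8-band mean per class."""

    class_means: dict[str, np.ndarray]
    noise_sd: np.ndarray
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    depth_attenuation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for cls, mu in self.class_means.items():
            mu = np.asarray(mu, dtype=np.float64)
            if mu.shape != (len(self.wavelengths),):
                raise ConfigurationError(f"spectrum for {cls!r} needs one value per band")
            if np.any(mu < 0):
                raise ConfigurationError(f"negative mean reflectance for {cls!r}")
            object.__getattribute__(self, "class_means")[cls] = mu
        sd = np.asarray(self.noise_sd, dtype=np.float64)
        if sd.ndim == 0:
            sd = np.full(len(self.wavelengths), float(sd))
        if np.any(sd < 0):
            raise ConfigurationError("noise_sd must be non-negative")
        object.__setattr__(self, "noise_sd", sd)


def default_spectra(noise_sd: float = 0.0010) -> SceneSpectra:
    """Plausible shallow-water Rrs endmembers (sr⁻¹) for a WorldView-like band set.

    Submerged seagrass is dark with a green peak and near-zero NIR; bare sand
    is brighter across the visible; emergent land is bright with the
    vegetation NIR plateau.
    """
    return SceneSpectra(
        class_means={
            "seagrass": np.array([0.008, 0.010, 0.016, 0.008, 0.005, 0.003, 0.001, 0.0005]),
            "bare": np.array([0.016, 0.022, 0.032, 0.030, 0.026, 0.015, 0.004, 0.002]),
            "land": np.array([0.050, 0.060, 0.080, 0.090, 0.100, 0.200, 0.350, 0.330]),
        },
        noise_sd=np.full(8, noise_sd),
    )


@dataclass(frozen=True)
class ErrorModel:
    """Miss/false-alarm process standing in for an imperfect classifier.

    A pixel is "seagrass-dominated" when its cover exceeds
    ``dominance_threshold`` — below that, other constituents of the pixel
    outweigh the seagrass signal. A spatially correlated no-data mask emulates
    turbidity/cloud dropout.
    """

    p_miss: float = 0.0
    p_false_alarm: float = 0.0
    dominance_threshold: float = 0.5
    nodata_fraction: float = 0.0
    nodata_patchiness: float = 20.0  # correlation length, m

    def __post_init__(self) -> None:
        if not (0 <= self.p_miss <= 1 and 0 <= self.p_false_alarm <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")
        if not (0 < self.dominance_threshold < 1):
            raise ParameterError("dominance_threshold must lie in (0, 1)")
        if not (0 <= self.nodata_fraction < 1):
            raise ParameterError("nodata_fraction must lie in [0, 1)")


def _smooth_noise(shape: tuple[int, int], sigma_cells: float, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return noise


def generate_truth_field(
    width: int,
    height: int,
    cell_size: float,
    patch_scale: float = 10.0,
    target_cover: float = 0.4,
    land_band_width: int = 0,
    seed: int = 0,
    origin_x: float = 0.0,
    origin_y: float | None = None,
    marginal_concentration: float = 0.15,
    trend_scale: float | None = None,
    trend_weight: float = 0.7,
) -> TruthField:
    """Spatially autocorrelated cover field with mean water-area cover ≈ target.

    ``patch_scale`` (m) sets the autocorrelation length; small values give
    sparse, discontinuous beds, large values continuous meadows. A land strip
    ``land_band_width`` cells wide runs along the northern edge.

    The marginal is Beta(tκ, (1−t)κ) with t = target_cover and
    κ = ``marginal_concentration``: its mean is exactly t, and for small κ it
    is U-shaped — cells are mostly nearly vegetated or nearly bare, matching
    how percent cover arises in real meadows as the areal fraction of
    vegetated bottom. Smoothed noise is rank-mapped through the Beta quantile
    function, which is pointwise non-decreasing in t for a fixed seed.

    ``trend_scale`` (m), if given, superimposes a broad bed-scale gradient on
    the within-bed patchiness: the rank-mapped noise becomes a
    ``trend_weight``-weighted mixture of fields smoothed at ``trend_scale``
    and ``patch_scale`` — emulating the depth/energy gradients along which
    real meadows thin out from continuous to sparse.
    """
    if width < 16 or height < 16:
        raise ParameterError("width and height must be at least 16")
    if cell_size <= 0 or patch_scale <= 0:
        raise ParameterError("cell_size and patch_scale must be positive")
    if not (0 <= target_cover <= 1):
        raise ParameterError("target_cover must lie in [0, 1]")
    if not (0 <= land_band_width < height):
        raise ParameterError("land_band_width must lie in [0, height)")
    if origin_y is None:
        origin_y = height * cell_size
    grid = GridSpec(width=width, height=height, cell_size=cell_size,
                    origin_x=origin_x, origin_y=origin_y)
    rng = np.random.default_rng(seed)
    land_mask = np.zeros((height, width), dtype=bool)
    land_mask[:land_band_width, :] = True

    noise = _smooth_noise((height, width), patch_scale / cell_size, rng)
    if trend_scale is not None:
        if not (0 <= trend_weight <= 1):
            raise ParameterError("trend_weight must lie in [0, 1]")
        trend = _smooth_noise((height, width), trend_scale / cell_size, rng)
        noise = trend_weight * trend / trend.std() + (1 - trend_weight) * noise / noise.std()
    cover = np.zeros((height, width))
    water = ~land_mask
    if target_cover >= 1.0:
        cover[water] = 1.0
    elif target_cover > 0:
        u = (rankdata(noise[water]) - 0.5) / water.sum()
        kappa = marginal_concentration
        cover[water] = beta_dist.ppf(
            u, target_cover * kappa, (1.0 - target_cover) * kappa
        )
    return TruthField(
        cover=cover,
        grid=grid,
        land_mask=land_mask,
        seed=seed,
        params={
            "patch_scale": patch_scale,
            "target_cover": target_cover,
            "land_band_width": land_band_width,
        },
    )


def _select_roi_blocks(
    eligible: np.ndarray, rng, n_rois: int, block: int
) -> list[tuple[int, int]]:
    """Top-left corners of up to n_rois disjoint block×block all-eligible squares."""
    ok = ndimage.minimum_filter(eligible.astype(np.uint8), size=block,
                                mode="constant", cval=0).astype(bool)
    # minimum_filter is centered; shift to top-left corner convention
    half = block // 2
    corners = [(r - half, c - half) for r, c in zip(*np.nonzero(ok))]
    corners = [(r, c) for r, c in corners if r >= 0 and c >= 0]
    rng.shuffle(corners)
    chosen: list[tuple[int, int]] = []
    for r, c in corners:
        if all(abs(r - r2) > block or abs(c - c2) > block for r2, c2 in chosen):
            chosen.append((r, c))
        if len(chosen) == n_rois:
            break
    return chosen


def render_scene(
    truth: TruthField,
    spectra: SceneSpectra | None = None,
    seed: int = 0,
    roi_purity: float = 0.9,
    roi_block: int = 3,
    n_rois: int = 6,
) -> tuple[RrsScene, ROISet]:
    """Render an 8-band scene from the truth field and emit training ROIs.

    Each water pixel's expected spectrum is the cover-weighted mixture of the
    seagrass and bare-substrate endmembers (land pixels use the land
    spectrum), plus Gaussian band noise. ROIs are disjoint rectangles drawn
    where cover ≥ ``roi_purity`` (seagrass), ≤ 1−``roi_purity`` (bare), or on
    land; at least three per class are required.
    """
    spectra = spectra or default_spectra()
    for cls in ("seagrass", "bare", "land"):
        if cls not in spectra.class_means:
            raise ConfigurationError(f"missing spectrum for class {cls!r}")
    rng = np.random.default_rng(seed)
    h, w = truth.grid.shape
    n_bands = len(spectra.wavelengths)
    sg = spectra.class_means["seagrass"][:, None, None]
    bare = spectra.class_means["bare"][:, None, None]
    c = truth.cover[None, :, :]
    bands = c * sg + (1.0 - c) * bare
    if spectra.depth_attenuation is not None:
        bands = bands * spectra.depth_attenuation[None, :, :]
    bands = np.where(truth.land_mask[None, :, :],
                     spectra.class_means["land"][:, None, None], bands)
    bands = bands + spectra.noise_sd[:, None, None] * rng.standard_normal((n_bands, h, w))
    scene = RrsScene(
        bands=bands,
        wavelengths=tuple(spectra.wavelengths),
        grid=truth.grid,
        metadata={"seed": seed, "source": "synthetic-render"},
    )

    regions: list[tuple[shapely.Geometry, str]] = []
    eligibility = {
        "seagrass": (truth.cover >= roi_purity) & truth.water_mask,
        "bare": (truth.cover <= 1.0 - roi_purity) & truth.water_mask,
        "land": truth.land_mask,
    }
    for cls, mask in eligibility.items():
        blocks = _select_roi_blocks(mask, rng, n_rois, roi_block)
        if len(blocks) < 3:
            raise ConfigurationError(
                f"cannot place 3 disjoint {roi_block}x{roi_block} ROIs for class "
                f"{cls!r}; only {len(blocks)} eligible blocks found"
            )
        for r, cidx in blocks:
            x0 = truth.grid.origin_x + cidx * truth.grid.cell_size
            y1 = truth.grid.origin_y - r * truth.grid.cell_size
            side = roi_block * truth.grid.cell_size
            regions.append((shapely.box(x0, y1 - side, x0 + side, y1), cls))
    rois = ROISet(regions=regions, catalog=("seagrass", "bare", "land"))
    return scene, rois


def degrade_to_classmap(truth: TruthField, error: ErrorModel, seed: int = 0) -> ClassMap:
    """Apply the miss/false-alarm/no-data process directly to the truth field.

    Bypasses rendering and classification so the agreement stages can be
    exercised against known error rates. No-data never asserts absence: the
    correlated no-data mask simply overwrites water labels.
    """
    rng = np.random.default_rng(seed)
    labels = np.full(truth.grid.shape, NO_SEAGRASS, dtype=np.int16)
    labels[truth.land_mask] = LAND
    dominated = (truth.cover >= error.dominance_threshold) & truth.water_mask
    draw = rng.random(truth.grid.shape)
    labels[dominated & (draw >= error.p_miss)] = SEAGRASS
    sparse = truth.water_mask & ~dominated
    labels[sparse & (draw < error.p_false_alarm)] = SEAGRASS

    if error.nodata_fraction > 0:
        field_nd = _smooth_noise(truth.grid.shape,
                                 error.nodata_patchiness / truth.grid.cell_size, rng)
        water_vals = field_nd[truth.water_mask]
        cut = np.quantile(water_vals, error.nodata_fraction)
        labels[truth.water_mask & (field_nd <= cut)] = NO_DATA
    return ClassMap(
        labels=labels,
        grid=truth.grid,
        catalog=GENERAL_CLASSES,
        metadata={"seed": seed, "error_model": {
            "p_miss": error.p_miss,
            "p_false_alarm": error.p_false_alarm,
            "dominance_threshold": error.dominance_threshold,
            "nodata_fraction": error.nodata_fraction,
        }},
    )


def _cells_to_polygons(mask: np.ndarray, grid: GridSpec) -> list[shapely.Geometry]:
    """One polygon per connected component of true cells (unions of cell boxes)."""
    labeled, n = ndimage.label(mask)
    polys = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labeled == comp)
        boxes = [grid.cell_box(r, c) for r, c in zip(rows, cols)]
        polys.append(shapely.union_all(boxes))
    return polys


def delineate_reference(
    truth: TruthField,
    dialect: str,
    scheme: DensityScheme | None = None,
    presence_threshold: float = 0.5,
    amalgamation_radius: float = 0.0,
    n_points: int = 50,
    polygon_size: int = 8,
    seed: int = 0,
) -> ReferenceSet:
    """Emulate a reference program delineating the truth field in one dialect.

    presence_polygons: connected components of (cover ≥ presence_threshold)
    after morphological closing with ``amalgamation_radius`` (m) — closing
    emulates programs that amalgamate seagrass and interstitial bare sand
    into one bed outline, the behavior that drives sensitivity below
    specificity on patchy beds.

    presence_points / cover_points: ``n_points`` random water locations
    labeled with presence at threshold, or with the cell's true cover ×100.

    density_polygons: the water area tiled into ``polygon_size``-cell squares,
    each labeled with the scheme class containing its mean water-cell cover
    ×100; tiles below the scheme's lowest bound are not delineated.
    """
    if dialect not in ReferenceSet.DIALECTS:
        raise ConfigurationError(f"unknown reference dialect: {dialect!r}")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    feats: list[ReferenceFeature] = []

    if dialect == "presence_polygons":
        mask = (truth.cover >= presence_threshold) & truth.water_mask
        radius_cells = int(round(amalgamation_radius / grid.cell_size))
        if radius_cells > 0:
            mask = binary_closing(mask, disk(radius_cells)).astype(bool) & truth.water_mask
        for i, poly in enumerate(_cells_to_polygons(mask, grid)):
            feats.append(ReferenceFeature(f"pp{i}", poly, {"presence": 1}))

    elif dialect in ("presence_points", "cover_points"):
        rows, cols = np.nonzero(truth.water_mask)
        if rows.size == 0:
            raise ConfigurationError("truth field has no water cells")
        pick = rng.choice(rows.size, size=min(n_points, rows.size), replace=False)
        jitter = rng.random((pick.size, 2))
        for i, (k, (jx, jy)) in enumerate(zip(pick, jitter)):
            r, c = int(rows[k]), int(cols[k])
            x = grid.origin_x + (c + jx) * grid.cell_size
            y = grid.origin_y - (r + jy) * grid.cell_size
            if dialect == "presence_points":
                attrs = {"presence": int(truth.cover[r, c] >= presence_threshold)}
            else:
                attrs = {"cover_pct": float(truth.cover[r, c] * 100.0)}
            feats.append(ReferenceFeature(f"pt{i}", shapely.Point(x, y), attrs))

    else:  # density_polygons
        if scheme is None:
            raise ConfigurationError("density_polygons dialect requires a DensityScheme")
        i = 0
        for r0 in range(0, grid.height, polygon_size):
            for c0 in range(0, grid.width, polygon_size):
                tile_water = truth.water_mask[r0:r0 + polygon_size, c0:c0 + polygon_size]
                if not tile_water.any():
                    continue
                tile_cover = truth.cover[r0:r0 + polygon_size, c0:c0 + polygon_size]
                mean_pct = float(tile_cover[tile_water].mean() * 100.0)
                label = scheme.classify(mean_pct)
                if label is None:
                    continue
                r1 = min(r0 + polygon_size, grid.height)
                c1 = min(c0 + polygon_size, grid.width)
                poly = shapely.box(
                    grid.origin_x + c0 * grid.cell_size,
                    grid.origin_y - r1 * grid.cell_size,
                    grid.origin_x + c1 * grid.cell_size,
                    grid.origin_y - r0 * grid.cell_size,
                )
                feats.append(ReferenceFeature(f"dp{i}", poly, {"dens_cls": label}))
                i += 1

    return ReferenceSet(
        dialect=dialect,
        features=feats,
        crs=grid.crs,
        metadata={"seed": seed, "scheme": scheme.name if scheme else None},
    )
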