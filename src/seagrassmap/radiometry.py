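"""Radiometric calibration and a simplified power-law atmospheric correction.

Raw digital numbers are first scaled to top-of-atmosphere (TOA) reflectance
with the conventional linear calibration. The atmospheric path signal is then
estimated per scene by a dark-object method: over water pixels, the
``dark_percentile`` statistic of the near-infrared reference band is taken as
the path signal there (water absorbs strongly in the NIR, so the darkest
water pixels carry essentially pure atmosphere), extrapolated to each band λ
with the Rayleigh power law (λ_ref/λ)^exponent, and subtracted. The exponent
defaults to 4.75 for clear conditions; haze mode uses 4, the limit in which
scattering is dominated by larger particles. The corrected signal is divided
by π to express remote sensing reflectance Rrs (sr⁻¹); negative values are
clipped to zero and the clipped fraction recorded.

This stage is optional — the pipeline accepts pre-corrected Rrs rasters or
even pre-classified maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfigurationError, GridSpec, ParameterError, ProcessingError


@dataclass(frozen=True)
class AtmosphericConfig:
    rayleigh_exponent: float = 4.75
    haze_mode: bool = False
    reference_band_nm: float = 908.0
    dark_percentile: float = 1.0

    def __post_init__(self) -> None:
        if self.rayleigh_exponent <= 0:
            raise ParameterError("rayleigh_exponent must be positive")
        if not (0 < self.dark_percentile <= 50):
            raise ParameterError("dark_percentile must lie in (0, 50]")

    @property
    def effective_exponent(self) -> float:
        return 4.0 if self.haze_mode else self.rayleigh_exponent


@dataclass
class RrsScene:
    """Multiband reflectance scene on a georeferenced lattice.

    ``bands`` has shape (n_bands, height, width); ``valid_mask`` flags pixels
    with a usable water-or-land signal. Values are Rrs in sr⁻¹ once the
    atmospheric stage has run (TOA reflectance before it).
    """

    bands: np.ndarray
    wavelengths: tuple[float, ...]
    grid: GridSpec
    valid_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.wavelengths):
            raise ParameterError("need one band grid per wavelength")
        if self.bands.shape[1:] != self.grid.shape:
            raise ParameterError("band grids do not match grid_spec dimensions")
        if any(b <= a for a, b in zip(self.wavelengths, self.wavelengths[1:])):
            raise ParameterError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not np.all(np.isfinite(self.bands[:, self.valid_mask])):
            raise ParameterError("non-finite band values inside valid_mask")

    def band(self, wavelength_nm: float) -> np.ndarray:
        try:
            i = self.wavelengths.index(wavelength_nm)
        except ValueError:
            raise ConfigurationError(f"no band at {wavelength_nm} nm") from None
        return self.bands[i]


def calibrate(
    dn: np.ndarray,
    gains: Sequence[float],
    offsets: Sequence[float],
    solar_irradiance: Sequence[float],
    solar_zenith_deg: float,
    earth_sun_distance_au: float = 1.0,
) -> np.ndarray:
    """Linear DN → TOA reflectance: ρ = π d² (gain·DN + offset) / (E_sun cosθ_s)."""
    dn = np.asarray(dn, dtype=np.float64)
    n_bands = dn.shape[0]
    if not (len(gains) == len(offsets) == len(solar_irradiance) == n_bands):
        raise ConfigurationError("need one gain/offset/irradiance per band")
    mu0 = np.cos(np.deg2rad(solar_zenith_deg))
    if mu0 <= 0:
        raise ParameterError("sun below the horizon: cos(solar zenith) must be > 0")
    g = np.asarray(gains, dtype=np.float64)[:, None, None]
    o = np.asarray(offsets, dtype=np.float64)[:, None, None]
    e = np.asarray(solar_irradiance, dtype=np.float64)[:, None, None]
    return np.pi * earth_sun_distance_au**2 * (g * dn + o) / (e * mu0)


def rayleigh_scale(wavelength_nm, reference_nm: float, exponent: float) -> np.ndarray:
    """Path-signal scaling from the reference band to wavelength λ: (λ_ref/λ)^exp."""
    return (reference_nm / np.asarray(wavelength_nm, dtype=np.float64)) ** exponent


def add_path_signal(
    bands: np.ndarray,
    wavelengths: Sequence[float],
    path_at_reference: float,
    config: AtmosphericConfig,
) -> np.ndarray:
    """Forward model: add a flat Rayleigh-law path signal (for simulation/tests)."""
    scale = rayleigh_scale(list(wavelengths), config.reference_band_nm, config.effective_exponent)
    return np.asarray(bands, dtype=np.float64) + path_at_reference * scale[:, None, None]


def atmospheric_correct(
    scene: RrsScene,
    config: AtmosphericConfig = AtmosphericConfig(),
    water_mask: np.ndarray | None = None,
) -> RrsScene:
    """Dark-object power-law correction; output is Rrs (sr⁻¹).

    ``water_mask`` restricts the dark statistic to water pixels; by default
    every valid pixel is eligible. Subtraction happens before the π
    normalization, so the correction never increases any band value.
    """
    ref = scene.band(config.reference_band_nm)
    mask = scene.valid_mask if water_mask is None else (water_mask & scene.valid_mask)
    if not mask.any():
        raise ProcessingError("no water pixels available for the dark-object statistic")
    # order statistic (no interpolation): a true dark pixel yields a zero path
    path_ref = float(np.percentile(ref[mask], config.dark_percentile, method="lower"))
    path_ref = max(path_ref, 0.0)
    scale = rayleigh_scale(list(scene.wavelengths), config.reference_band_nm,
                           config.effective_exponent)
    corrected = (scene.bands - path_ref * scale[:, None, None]) / np.pi
    clipped_fraction = float(np.mean(corrected[:, mask] < 0))
    corrected = np.clip(corrected, 0.0, None)
    return RrsScene(
        bands=corrected,
        wavelengths=scene.wavelengths,
        grid=scene.grid,
        valid_mask=scene.valid_mask,
        metadata={
            **scene.metadata,
            "atmospheric_correction": {
                "rayleigh_exponent": config.effective_exponent,
                "haze_mode": config.haze_mode,
                "reference_band_nm": config.reference_band_nm,
                "dark_percentile": config.dark_percentile,
                "path_at_reference": path_ref,
                "clipped_negative_fraction": clipped_fraction,
            },
        },
    )
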