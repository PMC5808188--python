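"""Radiometric conversions and the analytical shallow-water column model.

The core model relates at-water-surface reflectance ``R`` to bottom
reflectance ``Rb`` over a water column of depth ``Z``::

    R(band) = R_inf(band) + (Rb(band) - R_inf(band)) * exp(-2 * Kd(band) * Z)

where ``R_inf`` is the reflectance of an infinitely deep column and ``Kd`` an
operational attenuation coefficient combining the up- and down-welling
streams.  The module provides the forward evaluation, its algebraic inverse
(water-column correction), the remote-sensing-reflectance conversion
``Rrs = t * R / Q`` and deep-water masking / estimation utilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely

from .rasters import (
    STAGE_BOTTOM,
    STAGE_RRS,
    STAGE_SURFACE,
    DepthRaster,
    ReflectanceScene,
    require_same_grid,
)

__all__ = [
    "OpticalConstants",
    "DeepWaterEstimate",
    "surface_to_rrs",
    "estimate_deep_reflectance",
    "forward_shallow_reflectance",
    "correct_water_column",
    "apply_deep_mask",
    "DEFAULT_DEEP_LIMIT_M",
]

logger = logging.getLogger(__name__)

#: Optically-deep cutoff (m): below this the surface signal carries no usable
#: bottom contribution at these wavelengths.
DEFAULT_DEEP_LIMIT_M = 16.5


@dataclass(frozen=True)
class OpticalConstants:
    """Per-band water-column constants plus the air-water factors.

    Defaults are operational values for a clear Mediterranean coastal site at
    band centres 475/555/658 nm: ``Kd`` in 1/m, ``r_inf`` unitless, ``t`` the
    air-water transmittance (0.54) and ``q`` the upwelling
    irradiance-to-radiance ratio (pi for a Lambertian bottom).
    """

    bands: tuple[float, ...] = (475.0, 555.0, 658.0)
    kd: tuple[float, ...] = (0.067, 0.078, 0.134)
    r_inf: tuple[float, ...] = (0.033, 0.024, 0.017)
    t: float = 0.54
    q: float = math.pi

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(float(b) for b in self.bands))
        object.__setattr__(self, "kd", tuple(float(k) for k in self.kd))
        object.__setattr__(self, "r_inf", tuple(float(r) for r in self.r_inf))
        if not (len(self.bands) == len(self.kd) == len(self.r_inf)):
            raise ValueError("bands, kd and r_inf must have equal length")
        if any(k <= 0 for k in self.kd):
            raise ValueError("Kd must be positive in every band")
        if any(not (0 <= r < 1) for r in self.r_inf):
            raise ValueError("r_inf must lie in [0, 1)")
        if not (0 < self.t <= 1):
            raise ValueError("t must lie in (0, 1]")
        if self.q <= 0:
            raise ValueError("q must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def to_dict(self) -> dict:
        return {
            "bands": list(self.bands),
            "kd": list(self.kd),
            "r_inf": list(self.r_inf),
            "t": self.t,
            "q": self.q,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConstants":
        return cls(
            bands=tuple(d.get("bands", cls.bands)),
            kd=tuple(d.get("kd", cls.kd)),
            r_inf=tuple(d.get("r_inf", cls.r_inf)),
            t=float(d.get("t", cls.t)),
            q=float(d.get("q", cls.q)),
        )

    def _check_scene(self, scene: ReflectanceScene) -> None:
        if scene.bands != self.bands:
            raise ValueError(
                f"scene bands {scene.bands} do not match optics bands {self.bands}"
            )

    def _cols(self) -> tuple[np.ndarray, np.ndarray]:
        """Kd and r_inf as (n_bands, 1, 1) arrays for broadcasting."""
        kd = np.asarray(self.kd)[:, None, None]
        rinf = np.asarray(self.r_inf)[:, None, None]
        return kd, rinf


@dataclass(frozen=True)
class DeepWaterEstimate:
    """Per-band mean reflectance over a deep-water region."""

    r_inf: tuple[float, ...]
    n_pixels: int


def _require_stage(scene: ReflectanceScene, stage: str) -> None:
    if scene.stage != stage:
        raise ValueError(f"expected a {stage!r} scene, got {scene.stage!r}")


def surface_to_rrs(scene: ReflectanceScene, optics: OpticalConstants) -> ReflectanceScene:
    """Convert at-surface reflectance R to remote-sensing reflectance.

    ``Rrs = t * R / Q`` per pixel and band; the mask is propagated unchanged.
    """
    _require_stage(scene, STAGE_SURFACE)
    optics._check_scene(scene)
    return scene.with_values(scene.values * (optics.t / optics.q), STAGE_RRS)


def estimate_deep_reflectance(scene: ReflectanceScene, polygon) -> DeepWaterEstimate:
    """Mean per-band reflectance of unmasked pixels whose centres fall inside
    ``polygon`` (a shapely geometry); the standard way to obtain ``r_inf``
    from an optically deep region of the image itself.
    """
    xs, ys = scene.grid.pixel_centers()
    inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel()).reshape(xs.shape)
    sel = inside & ~scene.mask
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError("polygon intersects no unmasked pixel")
    means = tuple(float(scene.values[b][sel].mean()) for b in range(scene.n_bands))
    logger.info("deep-water estimate from %d pixels: %s", n, means)
    return DeepWaterEstimate(r_inf=means, n_pixels=n)


def forward_shallow_reflectance(
    bottom: ReflectanceScene, depth: DepthRaster, optics: OpticalConstants
) -> ReflectanceScene:
    """Evaluate the shallow-water model forward: bottom + depth -> surface R."""
    _require_stage(bottom, STAGE_BOTTOM)
    optics._check_scene(bottom)
    require_same_grid(bottom, depth)
    mask = bottom.mask | depth.mask
    if np.any(depth.values[~mask] < 0):
        raise ValueError("negative depth at unmasked pixels")
    kd, rinf = optics._cols()
    z = np.where(mask, 0.0, depth.values)[None, :, :]
    r = rinf + (bottom.values - rinf) * np.exp(-2.0 * kd * z)
    r = np.where(mask[None], 0.0, r)
    return bottom.with_values(r, STAGE_SURFACE, mask=mask)


def correct_water_column(
    surface: ReflectanceScene,
    depth: DepthRaster,
    optics: OpticalConstants,
    out_of_range: str = "clamp",
) -> ReflectanceScene:
    """Invert the shallow-water model: surface R + depth -> bottom Rb.

    ``Rb = r_inf + (R - r_inf) * exp(+2 * Kd * Z)`` per pixel and band.
    Pixels whose inverted reflectance leaves [0, 1] in any band are counted
    and, per ``out_of_range``, either clamped into range (``"clamp"``, the
    default) or masked out (``"mask"``).
    """
    _require_stage(surface, STAGE_SURFACE)
    optics._check_scene(surface)
    require_same_grid(surface, depth)
    if out_of_range not in ("clamp", "mask"):
        raise ValueError("out_of_range must be 'clamp' or 'mask'")
    missing = depth.mask & ~surface.mask
    if missing.any():
        raise ValueError(
            f"depth missing at {int(missing.sum())} unmasked reflectance pixels"
        )
    mask = surface.mask.copy()
    if np.any(depth.values[~mask] < 0):
        raise ValueError("negative depth at unmasked pixels")
    kd, rinf = optics._cols()
    z = np.where(mask, 0.0, depth.values)[None, :, :]
    rb = rinf + (surface.values - rinf) * np.exp(2.0 * kd * z)
    out = (rb < 0.0) | (rb > 1.0)
    out &= ~mask[None]
    n_out = int(out.any(axis=0).sum())
    if n_out:
        logger.info(
            "water-column correction: %d pixels outside [0, 1] (%s)", n_out, out_of_range
        )
    if out_of_range == "clamp":
        rb = np.clip(rb, 0.0, 1.0)
    else:
        mask = mask | out.any(axis=0)
    rb = np.where(mask[None], 0.0, rb)
    return surface.with_values(rb, STAGE_BOTTOM, mask=mask)


def apply_deep_mask(
    scene: ReflectanceScene, depth: DepthRaster, limit_m: float = DEFAULT_DEEP_LIMIT_M
) -> ReflectanceScene:
    """Mask pixels deeper than ``limit_m`` (or with no depth); values of the
    remaining pixels are untouched."""
    if limit_m <= 0:
        raise ValueError("limit_m must be positive")
    require_same_grid(scene, depth)
    deep = depth.mask | (depth.values > limit_m)
    mask = scene.mask | deep
    logger.info("deep mask at %.1f m: %d pixels masked", limit_m, int(deep.sum()))
    return scene.with_values(scene.values.copy(), scene.stage, mask=mask)
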