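"""Band log-ratio satellite-derived bathymetry.

Depth is modelled as a low-order polynomial of the log-ratio of two
remote-sensing-reflectance bands, ``x = ln(Rrs(num) / Rrs(den))``, calibrated
against in-situ depth points, applied per pixel, and optionally smoothed with
a low-pass moving-average filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .rasters import STAGE_RRS, DepthRaster, Grid, ReflectanceScene, sample_at_points

__all__ = [
    "BathymetryModel",
    "DepthValidation",
    "log_ratio",
    "fit_depth_polynomial",
    "predict_depth",
    "smooth_depth",
    "validate_depth",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BathymetryModel:
    """Polynomial depth model ``Z = a_n x^n + ... + a_1 x + a_0``.

    ``coefficients`` are in numpy ``polyval`` order (highest power first).
    """

    coefficients: tuple[float, ...]
    num_band: float | None = None
    den_band: float | None = None
    n_points: int = 0
    r_squared: float = float("nan")
    residual_sd: float = float("nan")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, x)

    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "num_band": self.num_band,
            "den_band": self.den_band,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BathymetryModel":
        return cls(
            coefficients=tuple(float(c) for c in d["coefficients"]),
            num_band=d.get("num_band"),
            den_band=d.get("den_band"),
            n_points=int(d.get("n_points", 0)),
            r_squared=float(d.get("r_squared", float("nan"))),
            residual_sd=float(d.get("residual_sd", float("nan"))),
        )


@dataclass(frozen=True)
class DepthValidation:
    r_squared: float
    rmse_m: float
    n: int


def log_ratio(
    rrs: ReflectanceScene, num_band: float = 475.0, den_band: float = 555.0
) -> np.ndarray:
    """Per-pixel ``ln(Rrs(num) / Rrs(den))``; NaN where masked or nonpositive.

    Nonpositive reflectance in either band is not fatal: the pixel is set to
    NaN and the count is logged.
    """
    if rrs.stage != STAGE_RRS:
        raise ValueError(f"expected an Rrs scene, got {rrs.stage!r}")
    num = rrs.band(num_band)
    den = rrs.band(den_band)
    bad = (num <= 0) | (den <= 0)
    n_bad = int(np.count_nonzero(bad & ~rrs.mask))
    if n_bad:
        logger.info("log_ratio: %d unmasked pixels with nonpositive Rrs", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.log(num / den)
    x[bad | rrs.mask] = np.nan
    return x


def fit_depth_polynomial(x, depth_m, degree: int = 2) -> BathymetryModel:
    """Ordinary-least-squares polynomial of depth against the log-ratio.

    Requires at least ``degree + 1`` points with more than ``degree`` distinct
    abscissae.  Reported diagnostics: ``r_squared = 1 - SS_res / SS_tot`` and
    the residual standard deviation with ``n - (degree + 1)`` degrees of
    freedom (0 when the fit is an exact interpolation).
    """
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(depth_m, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError("x and depth_m must have the same length")
    ok = np.isfinite(x) & np.isfinite(z)
    x, z = x[ok], z[ok]
    n = x.size
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points, got {n}")
    if np.unique(x).size <= degree:
        raise ValueError("design is rank deficient: too few distinct x values")
    coeffs = np.polyfit(x, z, degree)
    resid = z - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = n - (degree + 1)
    sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    return BathymetryModel(
        coefficients=tuple(float(c) for c in coeffs),
        n_points=n,
        r_squared=r2,
        residual_sd=sd,
    )


def predict_depth(model: BathymetryModel, ratio_field: np.ndarray, grid: Grid) -> DepthRaster:
    """Evaluate the model per pixel.  NaN ratios stay masked; negative depth
    predictions are clamped to 0 (count logged)."""
    ratio_field = np.asarray(ratio_field, dtype=float)
    if ratio_field.shape != grid.shape:
        raise ValueError("ratio field shape does not match grid")
    mask = ~np.isfinite(ratio_field)
    z = np.where(mask, 0.0, np.polyval(model.coefficients, np.where(mask, 0.0, ratio_field)))
    neg = (z < 0) & ~mask
    if neg.any():
        logger.info("predict_depth: %d negative predictions clamped to 0", int(neg.sum()))
        z = np.where(neg, 0.0, z)
    return DepthRaster(values=z, grid=grid, mask=mask, smoothed=False)


def smooth_depth(depth: DepthRaster, window: int = 5, mode: str = "reflect") -> DepthRaster:
    """Moving-average low-pass filter over unmasked neighbours.

    Masked pixels stay masked and do not contribute to their neighbours'
    averages (normalised convolution).  ``mode`` sets the edge policy of the
    underlying uniform filter (default reflect padding; ``"wrap"`` preserves
    the global mean exactly on fully unmasked rasters).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    valid = (~depth.mask).astype(float)
    num = ndimage.uniform_filter(np.where(depth.mask, 0.0, depth.values), size=window, mode=mode)
    den = ndimage.uniform_filter(valid, size=window, mode=mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    out = np.where(depth.mask, 0.0, out)
    return DepthRaster(values=out, grid=depth.grid, mask=depth.mask.copy(), smoothed=True)


def validate_depth(predicted: DepthRaster, points) -> DepthValidation:
    """Compare a depth raster against in-situ points ``(x, y, depth_m)``.

    Points off-grid or on masked pixels are dropped (logged).  Returns the
    r-squared of the OLS of predicted on observed depth and the RMSE of
    (predicted - observed).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, depth_m)")
    pred, usable = sample_at_points(
        predicted.values, predicted.grid, pts[:, 0], pts[:, 1], mask=predicted.mask
    )
    n_drop = int(np.count_nonzero(~usable))
    if n_drop:
        logger.info("validate_depth: %d points dropped (off grid or masked)", n_drop)
    obs = pts[usable, 2]
    pred = pred[usable]
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 usable validation points")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r2 = 1.0 if np.allclose(pred - obs, (pred - obs)[0]) else 0.0
    else:
        r2 = float(stats.linregress(obs, pred).rvalue ** 2)
    return DepthValidation(r_squared=r2, rmse_m=rmse, n=n)
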