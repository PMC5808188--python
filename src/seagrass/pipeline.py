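"""End-to-end pipeline drivers.

Two entry points:

* :func:`run_scene_analysis` — in-memory analysis of one synthetic scene:
  Rrs conversion, band-ratio bathymetry calibrated from a point subset,
  low-pass smoothing, optically-deep masking, water-column inversion,
  random-forest classification and error-matrix accuracy assessment.
* :func:`run_timeseries` / :func:`run_pipeline` — multi-epoch analysis with
  one shared bathymetry from a designated reference epoch, per-epoch
  classification and accuracy, per-class areas, OLS trends and gain/loss
  change maps; ``run_pipeline`` is the file-based variant driven by a YAML
  config and writes a product manifest.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .accuracy import AccuracyReport, ErrorMatrix, accuracy_report, build_error_matrix
from .bathymetry import (
    BathymetryModel,
    DepthValidation,
    fit_depth_polynomial,
    log_ratio,
    predict_depth,
    smooth_depth,
    validate_depth,
)
from .change import area_series, area_trend, change_map
from .classification import (
    GroundTruthPoints,
    RFConfig,
    classify_scene,
    extract_features,
    train_classifier,
    warn_on_geographic_split,
)
from .optics import (
    DEFAULT_DEEP_LIMIT_M,
    OpticalConstants,
    apply_deep_mask,
    correct_water_column,
    surface_to_rrs,
)
from .rasters import DepthRaster, HabitatMap, ReflectanceScene, sample_at_points
from .synthetic import SceneSpec, SyntheticScene, make_scene, noise_free

__all__ = [
    "SceneAnalysis",
    "TimeseriesResult",
    "PipelineConfig",
    "EpochInput",
    "derive_bathymetry",
    "run_scene_analysis",
    "run_timeseries",
    "run_pipeline",
    "bathymetry_error_bound",
]

logger = logging.getLogger(__name__)

#: Bands of the depth log-ratio (numerator, denominator).
RATIO_BANDS = (475.0, 555.0)


@dataclass
class SceneAnalysis:
    """Products of a single-scene run."""

    scene: SyntheticScene
    model: BathymetryModel
    sdb: DepthRaster
    depth_validation: DepthValidation | None
    bottom: ReflectanceScene
    habitat: HabitatMap
    error_matrix: ErrorMatrix
    report: AccuracyReport


@dataclass
class TimeseriesResult:
    years: list[int]
    analyses: dict[int, SceneAnalysis]
    areas: "object"  # tidy DataFrame (class, year, area_ha)
    trends: dict[int, object]
    change_maps: dict[int, object]


def derive_bathymetry(
    surface: ReflectanceScene,
    optics: OpticalConstants,
    calibration_points: np.ndarray,
    window: int = 5,
) -> tuple[BathymetryModel, DepthRaster]:
    """Fit the log-ratio depth polynomial and predict + smooth the full map.

    ``calibration_points`` is an (n, 3) array of (x, y, depth_m).
    """
    rrs = surface_to_rrs(surface, optics)
    x_field = log_ratio(rrs, *RATIO_BANDS)
    pts = np.asarray(calibration_points, dtype=float)
    x_at, usable = sample_at_points(x_field, surface.grid, pts[:, 0], pts[:, 1])
    model = fit_depth_polynomial(x_at[usable], pts[usable, 2])
    model = BathymetryModel(
        coefficients=model.coefficients,
        num_band=RATIO_BANDS[0],
        den_band=RATIO_BANDS[1],
        n_points=model.n_points,
        r_squared=model.r_squared,
        residual_sd=model.residual_sd,
    )
    sdb = smooth_depth(predict_depth(model, x_field, surface.grid), window=window)
    return model, sdb


def _classify_epoch(
    surface: ReflectanceScene,
    sdb: DepthRaster,
    optics: OpticalConstants,
    train_points: GroundTruthPoints,
    val_points: GroundTruthPoints,
    rf: RFConfig,
    mask_limit: float,
) -> tuple[ReflectanceScene, HabitatMap, ErrorMatrix, AccuracyReport]:
    masked = apply_deep_mask(surface, sdb, mask_limit)
    bottom = correct_water_column(masked, sdb, optics)
    X, y = extract_features(bottom, train_points)
    clf = train_classifier(X, y, rf)
    habitat = classify_scene(clf, bottom)
    matrix = build_error_matrix(habitat, val_points)
    return bottom, habitat, matrix, accuracy_report(matrix)


def run_scene_analysis(
    spec: SceneSpec,
    rf_seed: int = 42,
    n_calibration: int = 32,
    mask_limit: float = DEFAULT_DEEP_LIMIT_M,
) -> SceneAnalysis:
    """Full single-scene pipeline on a synthetic scene.

    The first ``n_calibration`` depth points calibrate the bathymetry model;
    the remainder validate it (skipped if fewer than 2 remain usable).
    """
    scene = make_scene(spec)
    optics = spec.optics
    calib = scene.depth_points[:n_calibration]
    val = scene.depth_points[n_calibration:]
    model, sdb = derive_bathymetry(scene.surface, optics, calib)
    depth_val = validate_depth(sdb, val) if len(val) >= 2 else None
    if spec.geographic_split:
        warn_on_geographic_split(scene.train_points, scene.val_points)
    bottom, habitat, matrix, report = _classify_epoch(
        scene.surface,
        sdb,
        optics,
        scene.train_points,
        scene.val_points,
        RFConfig(rng_seed=rf_seed),
        mask_limit,
    )
    return SceneAnalysis(
        scene=scene,
        model=model,
        sdb=sdb,
        depth_validation=depth_val,
        bottom=bottom,
        habitat=habitat,
        error_matrix=matrix,
        report=report,
    )


def bathymetry_error_bound(
    spec: SceneSpec,
    n_calibration: int = 32,
    noise_sigmas: float = 3.0,
) -> float:
    """Brute-force RMSE bound for the satellite-derived bathymetry.

    Decomposes the error into (a) the deterministic part, measured by running
    the identical pipeline on the noise-free twin of the scene (same seed, so
    the same bottom draws and points), and (b) the sensor-noise part, bounded
    per validation point by re-inverting the polynomial with each ratio band
    perturbed by ``noise_sigmas`` standard deviations in the worst direction.
    By the triangle inequality the noisy-pipeline RMSE at the validation
    points cannot exceed (a) + RMS of (b) except for noise realisations past
    ``noise_sigmas`` sigma.
    """
    clean_spec = noise_free(spec)
    scene = make_scene(clean_spec)
    optics = clean_spec.optics
    calib = scene.depth_points[:n_calibration]
    val = scene.depth_points[n_calibration:]
    model, sdb = derive_bathymetry(scene.surface, optics, calib)
    rmse_clean = validate_depth(sdb, val).rmse_m

    rrs = surface_to_rrs(scene.surface, optics)
    num = rrs.band(RATIO_BANDS[0])
    den = rrs.band(RATIO_BANDS[1])
    n_at, _ = sample_at_points(num, rrs.grid, val[:, 0], val[:, 1])
    d_at, _ = sample_at_points(den, rrs.grid, val[:, 0], val[:, 1])
    ok = np.isfinite(n_at) & np.isfinite(d_at) & (n_at > 0) & (d_at > 0)
    n_at, d_at = n_at[ok], d_at[ok]
    # sensor noise lives on R; the Rrs-space sd is scaled by t/Q
    sd = spec.sensor_noise_sd * optics.t / optics.q * noise_sigmas
    z0 = model(np.log(n_at / d_at))
    gain = np.zeros_like(z0)
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            num_p = np.maximum(n_at + s1 * sd, 1e-12)
            den_p = np.maximum(d_at + s2 * sd, 1e-12)
            gain = np.maximum(gain, np.abs(model(np.log(num_p / den_p)) - z0))
    return float(rmse_clean + np.sqrt(np.mean(gain**2)))


def run_timeseries(
    spec: SceneSpec,
    years: list[int],
    rf_seed: int = 42,
    n_calibration: int = 32,
    mask_limit: float = DEFAULT_DEEP_LIMIT_M,
    reference_year: int | None = None,
    target_classes: tuple[int, ...] = (1, 2),
) -> TimeseriesResult:
    """Multi-epoch synthetic analysis with a single shared bathymetry.

    Each year gets its own habitat realisation (seed offset by the epoch
    index) over a common depth surface; bathymetry is derived once from the
    reference epoch (default: the last year, the one closest to the depth
    survey) and reused for every epoch's masking and inversion.
    """
    from dataclasses import replace

    if len(years) != len(set(years)):
        raise ValueError("years must be unique")
    reference_year = reference_year if reference_year is not None else years[-1]
    if reference_year not in years:
        raise ValueError("reference_year must be one of the epochs")

    scenes: dict[int, SyntheticScene] = {}
    for i, year in enumerate(sorted(years)):
        scenes[year] = make_scene(replace(spec, rng_seed=spec.rng_seed + i))

    ref = scenes[reference_year]
    optics = spec.optics
    model, sdb = derive_bathymetry(
        ref.surface, optics, ref.depth_points[:n_calibration]
    )

    analyses: dict[int, SceneAnalysis] = {}
    maps: dict[int, HabitatMap] = {}
    for year in sorted(years):
        sc = scenes[year]
        bottom, habitat, matrix, report = _classify_epoch(
            sc.surface, sdb, optics, sc.train_points, sc.val_points,
            RFConfig(rng_seed=rf_seed), mask_limit,
        )
        val = sc.depth_points[n_calibration:]
        depth_val = validate_depth(sdb, val) if len(val) >= 2 else None
        analyses[year] = SceneAnalysis(
            scene=sc, model=model, sdb=sdb, depth_validation=depth_val,
            bottom=bottom, habitat=habitat, error_matrix=matrix, report=report,
        )
        maps[year] = habitat

    areas = area_series(maps)
    trends: dict[int, object] = {}
    cmaps: dict[int, object] = {}
    if len(years) >= 2:
        y0, y1 = min(years), max(years)
        for c in target_classes:
            sub = areas[areas["class"] == c]
            trends[c] = area_trend(sub["year"].to_numpy(), sub["area_ha"].to_numpy())
            cmaps[c] = change_map(maps[y0], maps[y1], c, year_start=y0, year_end=y1)
    else:
        warnings.warn("single epoch: change detection skipped", stacklevel=2)

    return TimeseriesResult(
        years=sorted(years), analyses=analyses, areas=areas, trends=trends, change_maps=cmaps
    )


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class EpochInput:
    year: int
    surface: str
    train_points: str
    val_points: str


@dataclass
class PipelineConfig:
    """YAML-backed configuration of the file-based pipeline."""

    epochs: list[EpochInput]
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    depth_points: str | None = None
    n_calibration: int = 32
    depth_raster: str | None = None
    coefficients: tuple[float, ...] | None = None
    reference_year: int | None = None
    mask_limit: float = DEFAULT_DEEP_LIMIT_M
    rf: RFConfig = field(default_factory=RFConfig)
    out_dir: str = "products"
    seed: int = 0
    target_classes: tuple[int, ...] = (1, 2)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = sio.load_yaml(path)
        base = Path(path).parent

        def _p(v):
            return str(base / v) if v is not None else None

        epochs = [
            EpochInput(
                year=int(e["year"]),
                surface=_p(e["surface"]),
                train_points=_p(e["train_points"]),
                val_points=_p(e["val_points"]),
            )
            for e in d["epochs"]
        ]
        return cls(
            epochs=epochs,
            optics=OpticalConstants.from_dict(d.get("optics", {})),
            depth_points=_p(d.get("depth_points")),
            n_calibration=int(d.get("n_calibration", 32)),
            depth_raster=_p(d.get("depth_raster")),
            coefficients=tuple(d["coefficients"]) if d.get("coefficients") else None,
            reference_year=d.get("reference_year"),
            mask_limit=float(d.get("mask_limit", DEFAULT_DEEP_LIMIT_M)),
            rf=RFConfig.from_dict(d.get("rf", {})),
            out_dir=str(d.get("out_dir", "products")),
            seed=int(d.get("seed", 0)),
            target_classes=tuple(d.get("target_classes", (1, 2))),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all epochs from files and write products plus a manifest.

    Bathymetry comes from, in order of preference: a supplied depth raster, a
    supplied coefficient set (applied to the reference epoch's ratio field),
    or a fit against the calibration subset of the supplied depth points on
    the reference epoch.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    years = [e.year for e in config.epochs]
    if len(set(years)) != len(years):
        raise ValueError("epoch years must be unique")
    ref_year = config.reference_year if config.reference_year is not None else max(years)
    by_year = {e.year: e for e in config.epochs}
    if ref_year not in by_year:
        raise ValueError(f"reference year {ref_year} is not an epoch")

    surfaces = {y: sio.read_raster(by_year[y].surface) for y in years}
    for y in years:
        if surfaces[y].grid != surfaces[years[0]].grid:
            raise ValueError("all epochs must share one grid (no resampling is performed)")

    model = None
    depth_validation = None
    if config.depth_raster:
        sdb = sio.read_raster(config.depth_raster)
    else:
        ref_surface = surfaces[ref_year]
        if config.coefficients:
            rrs = surface_to_rrs(ref_surface, config.optics)
            x_field = log_ratio(rrs, *RATIO_BANDS)
            model = BathymetryModel(
                coefficients=config.coefficients,
                num_band=RATIO_BANDS[0],
                den_band=RATIO_BANDS[1],
            )
            sdb = smooth_depth(predict_depth(model, x_field, ref_surface.grid))
        else:
            if not config.depth_points:
                raise ValueError(
                    "config must supply depth_raster, coefficients or depth_points"
                )
            pts = sio.read_depth_points_csv(config.depth_points)
            model, sdb = derive_bathymetry(
                ref_surface, config.optics, pts[: config.n_calibration]
            )
            if len(pts) - config.n_calibration >= 2:
                depth_validation = validate_depth(sdb, pts[config.n_calibration :])

    manifest: dict = {
        "seed": config.seed,
        "reference_year": ref_year,
        "mask_limit_m": config.mask_limit,
        "optics": config.optics.to_dict(),
        "rf": config.rf.to_dict(),
        "epochs": {},
        "products": {},
    }
    if model is not None:
        sio.write_model_yaml(out / "bathymetry_model.yaml", model)
        manifest["bathymetry_model"] = model.to_dict()
    if depth_validation is not None:
        manifest["depth_validation"] = {
            "r_squared": depth_validation.r_squared,
            "rmse_m": depth_validation.rmse_m,
            "n": depth_validation.n,
        }
    sio.write_raster(out / "sdb.tif", sdb)

    rf = RFConfig.from_dict({**config.rf.to_dict(), "rng_seed": config.rf.rng_seed
                             if config.rf.rng_seed is not None else config.seed})
    maps: dict[int, HabitatMap] = {}
    for y in years:
        e = by_year[y]
        train = sio.read_points_csv(e.train_points, role="train")
        val = sio.read_points_csv(e.val_points, role="validation")
        warn_on_geographic_split(train, val)
        _, habitat, matrix, report = _classify_epoch(
            surfaces[y], sdb, config.optics, train, val, rf, config.mask_limit
        )
        maps[y] = habitat
        sio.write_raster(out / f"habitat_{y}.tif", habitat)
        matrix.to_csv(out / f"error_matrix_{y}.csv")
        report.to_json(out / f"accuracy_{y}.json")
        manifest["epochs"][y] = {"overall_pct": report.overall_pct, "kappa": report.kappa}

    areas = area_series(maps)
    areas.to_csv(out / "areas.csv", index=False)
    if len(years) >= 2:
        y0, y1 = min(years), max(years)
        trends = {}
        for c in config.target_classes:
            sub = areas[areas["class"] == c]
            t = area_trend(sub["year"].to_numpy(), sub["area_ha"].to_numpy())
            trends[int(c)] = {
                "slope_ha_per_yr": t.slope_ha_per_yr,
                "intercept_ha": t.intercept_ha,
                "r_squared": t.r_squared,
            }
            cm = change_map(maps[y0], maps[y1], c, year_start=y0, year_end=y1)
            hm = HabitatMap(
                labels=cm.codes,
                grid=cm.grid,
                class_table={1: "gain", 2: "no_change_present", 3: "loss", 4: "absent_both"},
            )
            sio.write_raster(out / f"change_{c}_{y0}_{y1}.tif", hm)
        sio.dump_yaml(out / "trends.yaml", trends)
        manifest["trends"] = trends
    else:
        warnings.warn("single epoch: change detection skipped", stacklevel=2)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.yaml":
            manifest["products"][p.name] = _sha256(p)
    sio.dump_yaml(out / "manifest.yaml", manifest)
    return manifest
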