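"""Synthetic multispectral scene generation.

Builds everything the analysis pipeline consumes with known ground truth: a
shore-to-deep depth surface, a depth-structured four-class habitat map,
per-pixel bottom spectra, at-surface reflectance rendered through the forward
shallow-water model with additive sensor noise, and disjoint train /
validation / depth point sets sampled from the truth rasters.

Every stage draws from its own seeded stream derived from ``SceneSpec.rng_seed``,
so individual stages and the full scene are bit-reproducible, and changing
e.g. the sensor noise level does not perturb the habitat layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .classification import GroundTruthPoints
from .optics import OpticalConstants, forward_shallow_reflectance
from .rasters import (
    CLASS_TABLE,
    STAGE_BOTTOM,
    DepthRaster,
    Grid,
    HabitatMap,
    ReflectanceScene,
)

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "DEFAULT_CLASS_SPECTRA",
    "generate_depth_surface",
    "generate_habitat_map",
    "render_surface_reflectance",
    "make_scene",
]

#: Default mean bottom reflectance per class at 475/555/658 nm.  Seagrass
#: canopies are dark (P. oceanica darkest, below deep water in the blue),
#: sand is the brightest substrate, C. nodosa sits between algae and sand.
DEFAULT_CLASS_SPECTRA: dict[int, tuple[float, float, float]] = {
    1: (0.06, 0.08, 0.04),  # Cymodocea nodosa
    2: (0.03, 0.05, 0.02),  # Posidonia oceanica
    3: (0.08, 0.10, 0.05),  # Rocky algae
    4: (0.20, 0.18, 0.12),  # Sand
}

#: Depth preference (mean_m, width_m) per class; None = no preference.
#: Rocky algae hug the shallows, C. nodosa and P. oceanica centre at mid
#: depths, sand occurs across the whole range (and dominates the deep end by
#: default since the other classes are penalised away from their optimum).
_DEPTH_PREFERENCE: dict[int, tuple[float, float] | None] = {
    1: (5.8, 2.5),
    2: (8.0, 3.0),
    3: (2.5, 2.0),
    4: None,
}

# Fixed per-stage stream ids so stages are independently reproducible.
_STREAM_DEPTH = 0
_STREAM_HABITAT = 1
_STREAM_REFLECTANCE = 2
_STREAM_POINTS = 3


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    rows: int = 250
    cols: int = 250
    pixel_size: float = 5.0
    depth_min: float = 0.8
    depth_max: float = 18.9
    class_spectra: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECTRA)
    )
    class_sd: float = 0.005
    sensor_noise_sd: float = 0.002
    class_prior: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    n_train_per_class: int = 50
    n_val_per_class: int = 50
    n_depth_points: int = 46
    geographic_split: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")
        if self.depth_min < 0:
            raise ValueError("depths must be non-negative")
        if set(self.class_spectra) != set(CLASS_TABLE):
            raise ValueError(f"class_spectra must cover classes {sorted(CLASS_TABLE)}")
        nb = self.optics.n_bands
        for c, spec in self.class_spectra.items():
            if len(spec) != nb:
                raise ValueError(f"class {c} spectrum must have {nb} bands")
            if any(not (0 <= v <= 1) for v in spec):
                raise ValueError(f"class {c} spectrum outside [0, 1]")
        if not (0 <= self.class_sd <= 1) or not (0 <= self.sensor_noise_sd <= 1):
            raise ValueError("standard deviations must lie in [0, 1]")
        if len(self.class_prior) != len(CLASS_TABLE):
            raise ValueError("class_prior must have one weight per class")
        if any(p < 0 for p in self.class_prior) or sum(self.class_prior) <= 0:
            raise ValueError("class_prior must be non-negative with positive sum")
        spectra = [tuple(self.class_spectra[c]) for c in sorted(self.class_spectra)]
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                if spectra[i] == spectra[j]:
                    raise ValueError("class mean spectra must be pairwise distinct")

    @property
    def grid(self) -> Grid:
        return Grid(rows=self.rows, cols=self.cols, pixel_size=self.pixel_size)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pixel_size": self.pixel_size,
            "depth_min": self.depth_min,
            "depth_max": self.depth_max,
            "class_spectra": {int(c): list(s) for c, s in self.class_spectra.items()},
            "class_sd": self.class_sd,
            "sensor_noise_sd": self.sensor_noise_sd,
            "class_prior": list(self.class_prior),
            "optics": self.optics.to_dict(),
            "n_train_per_class": self.n_train_per_class,
            "n_val_per_class": self.n_val_per_class,
            "n_depth_points": self.n_depth_points,
            "geographic_split": self.geographic_split,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "class_spectra" in d:
            d["class_spectra"] = {int(c): tuple(s) for c, s in d["class_spectra"].items()}
        if "class_prior" in d:
            d["class_prior"] = tuple(d["class_prior"])
        if "optics" in d and isinstance(d["optics"], dict):
            d["optics"] = OpticalConstants.from_dict(d["optics"])
        return cls(**d)


@dataclass
class SyntheticScene:
    """A fully rendered scene plus all ground truth used to test the pipeline."""

    spec: SceneSpec
    truth_habitat: HabitatMap
    truth_depth: DepthRaster
    truth_bottom: ReflectanceScene
    surface: ReflectanceScene
    train_points: GroundTruthPoints
    val_points: GroundTruthPoints
    depth_points: np.ndarray  # (n, 3) columns x, y, depth_m


def _stage_rng(spec: SceneSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Correlated Gaussian field normalised to unit standard deviation."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_depth_surface(
    spec: SceneSpec, rng: np.random.Generator | None = None
) -> DepthRaster:
    """Shore-to-deep depth gradient with low-amplitude correlated noise.

    Depth increases monotonically (in trend) from the first to the last
    column; smoothed noise perturbs the trend and the result is clipped to
    the spec's depth range, so all values stay within it by construction.
    """
    if spec.rows < 5 or spec.cols < 5:
        raise ValueError("grid must be at least 5x5")
    rng = rng or _stage_rng(spec, _STREAM_DEPTH)
    span = spec.depth_max - spec.depth_min
    ramp = np.linspace(spec.depth_min, spec.depth_max, spec.cols)
    base = np.broadcast_to(ramp, (spec.rows, spec.cols)).copy()
    sigma = max(2.0, min(spec.rows, spec.cols) / 20.0)
    noise = _smooth_unit_field(rng, (spec.rows, spec.cols), sigma) * 0.04 * span
    z = np.clip(base + noise, spec.depth_min, spec.depth_max)
    return DepthRaster(values=z, grid=spec.grid)


def generate_habitat_map(
    spec: SceneSpec,
    depth: DepthRaster,
    rng: np.random.Generator | None = None,
) -> HabitatMap:
    """Contiguous habitat patches with depth-dependent class priors.

    Each class scores a smoothed random field plus a Gaussian depth-affinity
    term (rocky algae shallow, the seagrasses at mid depth, sand ubiquitous)
    plus the log of its prior weight; the per-pixel argmax yields the label.
    Classes with zero prior are excluded; every included class must end up
    with at least ``n_train_per_class + n_val_per_class`` pixels.
    """
    if depth.grid != spec.grid:
        raise ValueError("depth raster does not match spec grid")
    rng = rng or _stage_rng(spec, _STREAM_HABITAT)
    classes = sorted(spec.class_spectra)
    prior = np.asarray(spec.class_prior, dtype=float)
    prior = prior / prior.sum()
    sigma = max(3.0, min(spec.rows, spec.cols) / 12.0)
    scores = np.full((len(classes), spec.rows, spec.cols), -np.inf)
    for i, c in enumerate(classes):
        if prior[i] == 0:
            # burn the stream anyway so priors do not shift other classes
            _smooth_unit_field(rng, (spec.rows, spec.cols), sigma)
            continue
        f = _smooth_unit_field(rng, (spec.rows, spec.cols), sigma)
        pref = _DEPTH_PREFERENCE.get(c)
        affinity = 0.0
        if pref is not None:
            mean_m, width_m = pref
            affinity = -0.5 * ((depth.values - mean_m) / width_m) ** 2
        scores[i] = f + affinity + np.log(prior[i] * len(classes))
    labels = np.asarray(classes, dtype=np.uint8)[np.argmax(scores, axis=0)]
    habitat = HabitatMap(labels=labels, grid=spec.grid)
    needed = spec.n_train_per_class + spec.n_val_per_class
    for i, c in enumerate(classes):
        if prior[i] > 0 and habitat.class_counts()[c] < needed:
            raise ValueError(
                f"class {c} occupies {habitat.class_counts()[c]} pixels; "
                f"{needed} required for point sampling"
            )
    return habitat


def _sample_class_points(
    spec: SceneSpec, habitat: HabitatMap, rng: np.random.Generator
) -> tuple[GroundTruthPoints, GroundTruthPoints]:
    """Disjoint train/validation point draws per class (uniform, no
    replacement).  In geographic-split mode training points come from the
    top half of the grid and validation points from the bottom half (the
    split runs across the depth gradient so both halves span all depths)."""
    grid = spec.grid
    mid_row = spec.rows // 2
    tr_rows, tr_cols, tr_lab = [], [], []
    va_rows, va_cols, va_lab = [], [], []
    prior = np.asarray(spec.class_prior, dtype=float)
    for i, c in enumerate(sorted(spec.class_spectra)):
        if prior[i] == 0:
            continue
        rows, cols = np.nonzero(habitat.labels == c)
        if spec.geographic_split:
            top = rows < mid_row
            tr_pool = np.flatnonzero(top)
            va_pool = np.flatnonzero(~top)
            if tr_pool.size < spec.n_train_per_class or va_pool.size < spec.n_val_per_class:
                raise ValueError(
                    f"class {c}: not enough pixels per half for a geographic split"
                )
            tr_idx = rng.choice(tr_pool, size=spec.n_train_per_class, replace=False)
            va_idx = rng.choice(va_pool, size=spec.n_val_per_class, replace=False)
        else:
            n = spec.n_train_per_class + spec.n_val_per_class
            if rows.size < n:
                raise ValueError(f"class {c}: {rows.size} pixels < {n} points requested")
            pick = rng.choice(rows.size, size=n, replace=False)
            tr_idx = pick[: spec.n_train_per_class]
            va_idx = pick[spec.n_train_per_class :]
        tr_rows.append(rows[tr_idx])
        tr_cols.append(cols[tr_idx])
        tr_lab.append(np.full(tr_idx.size, c))
        va_rows.append(rows[va_idx])
        va_cols.append(cols[va_idx])
        va_lab.append(np.full(va_idx.size, c))

    def _to_points(rws, cls_, labs, role):
        r = np.concatenate(rws)
        c = np.concatenate(cls_)
        x = grid.x_origin + (c + 0.5) * grid.pixel_size
        y = grid.y_origin - (r + 0.5) * grid.pixel_size
        return GroundTruthPoints(x=x, y=y, label=np.concatenate(labs), role=role)

    return (
        _to_points(tr_rows, tr_cols, tr_lab, "train"),
        _to_points(va_rows, va_cols, va_lab, "validation"),
    )


def render_surface_reflectance(
    habitat: HabitatMap,
    depth: DepthRaster,
    spec: SceneSpec,
    rng: np.random.Generator | None = None,
    points_rng: np.random.Generator | None = None,
) -> SyntheticScene:
    """Render the scene through the forward model and sample all point sets.

    Per pixel the bottom spectrum is the class mean plus truncated Gaussian
    within-class variation; the surface reflectance is the forward
    shallow-water evaluation plus independent Gaussian sensor noise, clipped
    to [0, 1].
    """
    if habitat.grid != spec.grid or depth.grid != spec.grid:
        raise ValueError("habitat/depth grids do not match spec grid")
    rng = rng or _stage_rng(spec, _STREAM_REFLECTANCE)
    points_rng = points_rng or _stage_rng(spec, _STREAM_POINTS)
    optics = spec.optics
    nb = optics.n_bands
    shape = (spec.rows, spec.cols)

    mean = np.zeros((nb,) + shape)
    for c, spectrum in spec.class_spectra.items():
        sel = habitat.labels == c
        for b in range(nb):
            mean[b][sel] = spectrum[b]
    rb = np.clip(mean + rng.standard_normal((nb,) + shape) * spec.class_sd, 0.0, 1.0)
    bottom = ReflectanceScene(values=rb, bands=optics.bands, grid=spec.grid, stage=STAGE_BOTTOM)

    surface = forward_shallow_reflectance(bottom, depth, optics)
    noisy = np.clip(
        surface.values + rng.standard_normal((nb,) + shape) * spec.sensor_noise_sd, 0.0, 1.0
    )
    surface = surface.with_values(noisy, surface.stage)

    train_pts, val_pts = _sample_class_points(spec, habitat, points_rng)

    n_px = spec.rows * spec.cols
    if spec.n_depth_points > n_px:
        raise ValueError("more depth points requested than pixels")
    flat = points_rng.choice(n_px, size=spec.n_depth_points, replace=False)
    dr, dc = np.unravel_index(flat, shape)
    dx = spec.grid.x_origin + (dc + 0.5) * spec.pixel_size
    dy = spec.grid.y_origin - (dr + 0.5) * spec.pixel_size
    depth_points = np.column_stack([dx, dy, depth.values[dr, dc]])

    return SyntheticScene(
        spec=spec,
        truth_habitat=habitat,
        truth_depth=depth,
        truth_bottom=bottom,
        surface=surface,
        train_points=train_pts,
        val_points=val_pts,
        depth_points=depth_points,
    )


def make_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate a complete synthetic scene from a spec (deterministic per seed)."""
    depth = generate_depth_surface(spec)
    habitat = generate_habitat_map(spec, depth)
    return render_surface_reflectance(habitat, depth, spec)


def noise_free(spec: SceneSpec) -> SceneSpec:
    """Same scene spec with sensor noise switched off (same seed, so the
    habitat, bottom spectra and point draws are identical)."""
    return replace(spec, sensor_noise_sd=0.0)
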