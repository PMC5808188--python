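"""Random-forest pixel classification of bottom-reflectance composites.

Features are the corrected bottom-reflectance bands only (pixel-based, no
texture or depth), trained from per-class ground-truth points and applied to
every unmasked pixel by majority vote over the ensemble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .rasters import (
    CLASS_TABLE,
    NODATA_LABEL,
    STAGE_BOTTOM,
    HabitatMap,
    ReflectanceScene,
    sample_at_points,
)

__all__ = [
    "GroundTruthPoints",
    "RFConfig",
    "extract_features",
    "train_classifier",
    "classify_scene",
    "warn_on_geographic_split",
]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthPoints:
    """Labelled habitat points: coordinates plus class codes and a role tag."""

    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    role: str = "train"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.label = np.asarray(self.label, dtype=int).ravel()
        if not (self.x.size == self.y.size == self.label.size):
            raise ValueError("x, y and label must have equal length")
        if self.role not in ("train", "validation"):
            raise ValueError("role must be 'train' or 'validation'")
        unknown = set(np.unique(self.label).tolist()) - set(CLASS_TABLE)
        if unknown:
            raise ValueError(f"unknown class codes {sorted(unknown)}")

    def __len__(self) -> int:
        return self.x.size

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.label, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "class": self.label})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, role: str = "train") -> "GroundTruthPoints":
        label_col = "class" if "class" in df.columns else "label"
        return cls(
            x=df["x"].to_numpy(), y=df["y"].to_numpy(), label=df[label_col].to_numpy(), role=role
        )


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters: ensemble size, features tried per
    split, split criterion and the seed that makes training deterministic."""

    n_trees: int = 100
    n_random_features: int = 2
    split_criterion: str = "gini"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_random_features < 1:
            raise ValueError("n_random_features must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "n_random_features": self.n_random_features,
            "split_criterion": self.split_criterion,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RFConfig":
        return cls(
            n_trees=int(d.get("n_trees", 100)),
            n_random_features=int(d.get("n_random_features", 2)),
            split_criterion=str(d.get("split_criterion", "gini")),
            rng_seed=d.get("rng_seed"),
        )


def extract_features(
    scene: ReflectanceScene, points: GroundTruthPoints
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point band values from a bottom-reflectance scene.

    Returns ``(X, y)`` with one row of band values per usable point; points
    that fall off-grid or on masked pixels are dropped with a logged count.
    """
    if scene.stage != STAGE_BOTTOM:
        raise ValueError(f"expected a bottom_Rb scene, got {scene.stage!r}")
    cols = []
    usable = None
    for b in range(scene.n_bands):
        vals, u = sample_at_points(scene.values[b], scene.grid, points.x, points.y, mask=scene.mask)
        cols.append(vals)
        usable = u if usable is None else (usable & u)
    n_drop = int(np.count_nonzero(~usable))
    if n_drop:
        logger.info("extract_features: %d points dropped (off grid or masked)", n_drop)
    if not usable.any():
        raise ValueError("no usable points: all fall off-grid or on masked pixels")
    X = np.column_stack(cols)[usable]
    y = points.label[usable]
    return X, y


def train_classifier(X, y, config: RFConfig = RFConfig()) -> RandomForestClassifier:
    """Fit the random forest (bootstrap sampling, majority vote).

    The feature subset size per split is capped at the number of bands.
    Raises on single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.n_random_features, X.shape[1]),
        criterion=config.split_criterion,
        bootstrap=True,
        random_state=config.rng_seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def classify_scene(clf: RandomForestClassifier, scene: ReflectanceScene) -> HabitatMap:
    """Label every unmasked pixel; masked pixels get the nodata code 0.

    Majority vote ties resolve to the lowest class code (class probabilities
    are compared in ascending class order).
    """
    if scene.stage != STAGE_BOTTOM:
        raise ValueError(f"expected a bottom_Rb scene, got {scene.stage!r}")
    if clf.n_features_in_ != scene.n_bands:
        raise ValueError(
            f"classifier expects {clf.n_features_in_} bands, scene has {scene.n_bands}"
        )
    labels = np.full(scene.grid.shape, NODATA_LABEL, dtype=np.uint8)
    sel = ~scene.mask
    if sel.any():
        X = scene.values[:, sel].T
        labels[sel] = clf.predict(X).astype(np.uint8)
    return HabitatMap(labels=labels, grid=scene.grid)


def warn_on_geographic_split(train: GroundTruthPoints, val: GroundTruthPoints) -> bool:
    """Warn when train and validation points occupy disjoint halves of the
    site along either axis (a spatially blocked split can bias the accuracy
    assessment).  Returns True when the warning fired."""

    def _disjoint(a: np.ndarray, b: np.ndarray) -> bool:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if hi == lo:
            return False
        mid = (lo + hi) / 2.0
        return (a.max() <= mid and b.min() >= mid) or (b.max() <= mid and a.min() >= mid)

    disjoint = _disjoint(train.x, val.x) or _disjoint(train.y, val.y)
    if disjoint:
        warnings.warn(
            "training and validation points occupy disjoint halves of the site; "
            "accuracy estimates may be spatially biased",
            stacklevel=2,
        )
    return bool(disjoint)
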