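"""Feature and image normalization with train-only statistics.

Tabular features are z-scored (population-SD convention) for the regression
and random-forest models, or min-max rescaled to [0, 1] for the network's
clinical input.  MRI volumes are mapped to [-1, 1] by ``v / (0.5 * gmax) - 1``
where ``gmax`` is the largest voxel value over a declared reference set; JD
volumes pass through unscaled.  Shape conformance is a centered crop (MRI)
or symmetric zero-pad (JD), odd remainders on the trailing side.

All statistics are fitted on an explicit training set and applied elsewhere;
held-out values are deliberately not clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import ConfigurationError, DegenerateFeatureError, ShapeError


@dataclass
class FeatureScaler:
    """Per-feature affine scaler with statistics learned from training data."""

    kind: Literal["zscore", "minmax"]
    center: np.ndarray | None = None   # mean or min
    scale: np.ndarray | None = None    # SD or (max - min)
    feature_names: list[str] | None = None

    def fit(self, X: np.ndarray, feature_names: list[str] | None = None
            ) -> "FeatureScaler":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ConfigurationError(
                "scaler needs a 2D matrix with >= 2 training rows")
        self.feature_names = feature_names
        if self.kind == "zscore":
            self.center = X.mean(axis=0)
            self.scale = X.std(axis=0)          # population SD (ddof=0)
        elif self.kind == "minmax":
            self.center = X.min(axis=0)
            self.scale = X.max(axis=0) - X.min(axis=0)
        else:
            raise ConfigurationError(f"unknown scaler kind {self.kind!r}")
        bad = np.flatnonzero(self.scale == 0)
        if bad.size:
            name = (self.feature_names[bad[0]] if self.feature_names
                    else f"column {bad[0]}")
            raise DegenerateFeatureError(
                f"feature {name} has zero spread on the training set")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise ConfigurationError("scaler not fitted")
        return (np.asarray(X, float) - self.center) / self.scale

    def fit_transform(self, X: np.ndarray,
                      feature_names: list[str] | None = None) -> np.ndarray:
        return self.fit(X, feature_names).transform(X)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "feature_names": self.feature_names,
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        d = json.loads(text)
        return cls(kind=d["kind"], center=np.array(d["center"]),
                   scale=np.array(d["scale"]),
                   feature_names=d["feature_names"])


def fit_apply_zscore(train_features: np.ndarray,
                     target_features: np.ndarray,
                     feature_names: list[str] | None = None) -> np.ndarray:
    """(x - mean_train) / sd_train, statistics from the training set only."""
    scaler = FeatureScaler("zscore").fit(train_features, feature_names)
    return scaler.transform(target_features)


def fit_apply_minmax(train_features: np.ndarray,
                     target_features: np.ndarray,
                     feature_names: list[str] | None = None) -> np.ndarray:
    """(x - min_train) / (max_train - min_train); held-out values unclipped."""
    scaler = FeatureScaler("minmax").fit(train_features, feature_names)
    return scaler.transform(target_features)


def global_intensity_max(volumes: Iterable[np.ndarray]) -> float:
    """Largest voxel value over a reference set of MRI volumes."""
    gmax = -np.inf
    for v in volumes:
        gmax = max(gmax, float(np.max(v)))
    if not np.isfinite(gmax):
        raise ConfigurationError("empty volume set")
    return gmax


def rescale_mri(volume: np.ndarray, global_max: float) -> np.ndarray:
    """Map nonnegative intensities to [-1, 1]: v / (0.5 * global_max) - 1."""
    if global_max <= 0:
        raise ConfigurationError("global_max must be positive")
    return np.asarray(volume, np.float32) / (0.5 * global_max) - 1.0


def conform_shape(volume: np.ndarray,
                  target_shape: tuple[int, ...],
                  mode: Literal["crop", "zero_pad"]) -> np.ndarray:
    """Centered crop or symmetric zero-pad to ``target_shape``.

    Odd size differences put the extra voxel on the trailing side.  Content
    voxels are preserved exactly, so crop and pad on matched shapes are
    mutual inverses.
    """
    volume = np.asarray(volume)
    if volume.ndim != len(target_shape):
        raise ShapeError(
            f"rank mismatch: volume {volume.ndim}D vs target "
            f"{len(target_shape)}D")
    if mode == "crop":
        slices = []
        for axis, (src, dst) in enumerate(zip(volume.shape, target_shape)):
            if src < dst:
                raise ShapeError(
                    f"cannot crop axis {axis}: source {src} < target {dst}")
            lo = (src - dst) // 2
            slices.append(slice(lo, lo + dst))
        return volume[tuple(slices)]
    if mode == "zero_pad":
        pads = []
        for axis, (src, dst) in enumerate(zip(volume.shape, target_shape)):
            if src > dst:
                raise ShapeError(
                    f"cannot zero-pad axis {axis}: source {src} > target "
                    f"{dst}")
            lo = (dst - src) // 2
            pads.append((lo, dst - src - lo))
        return np.pad(volume, pads, mode="constant", constant_values=0)
    raise ConfigurationError(f"unknown conform mode {mode!r}")
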