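"""ROI-trained moving-window classification of a reflectance scene.

The contract mirrors common practice in coastal benthic mapping: the analyst
draws regions of interest (ROIs) over spectrally homogeneous areas, a
supervised model is trained on the band values within a small moving window
around each labeled pixel, every pixel receives exactly one scene-specific
class, and the scene classes are then collapsed onto four general classes —
land, seagrass, no seagrass, and no data. Pixels masked invalid (clouds,
turbid or deep water) stay no data throughout: no data never precludes, nor
asserts, the presence of seagrass.

The model backend is pluggable. The default is a class-weighted multinomial
logistic regression over the flattened window of band values (window_size=1
reduces it to a purely spectral classifier); any scikit-learn-style estimator
can be substituted via ``model_config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core import (
    GENERAL_CLASSES,
    ClassMap,
    ConfigurationError,
    GridSpec,
    ParameterError,
)
from .radiometry import RrsScene


@dataclass
class ROISet:
    """User-defined training regions: (geometry, scene class label) pairs."""

    regions: list[tuple[shapely.Geometry, str]]
    catalog: tuple[str, ...]

    def __post_init__(self) -> None:
        present = {label for _, label in self.regions}
        missing = [c for c in self.catalog if c not in present]
        if missing:
            raise ConfigurationError(f"classes without any ROI: {missing}")
        for i, (gi, li) in enumerate(self.regions):
            for gj, lj in self.regions[i + 1:]:
                if li != lj and gi.intersects(gj) and not gi.touches(gj):
                    raise ConfigurationError(
                        f"ROIs of different classes overlap: {li!r} / {lj!r}"
                    )

    def labeled_cells(self, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(rows, cols, labels) of every cell whose center falls in an ROI."""
        x, y = grid.cell_centers()
        rows_out, cols_out, labels_out = [], [], []
        seen = np.zeros(grid.shape, dtype=bool)
        for geom, label in self.regions:
            inside = shapely.contains_xy(geom, x, y) & ~seen
            seen |= inside
            r, c = np.nonzero(inside)
            rows_out.append(r)
            cols_out.append(c)
            labels_out.extend([label] * r.size)
        return np.concatenate(rows_out), np.concatenate(cols_out), labels_out


@dataclass
class TrainedClassifier:
    model: Pipeline
    catalog: tuple[str, ...]
    window_size: int
    wavelengths: tuple[float, ...]
    training_report: dict = field(default_factory=dict)

    def predict_codes(self, features: np.ndarray) -> np.ndarray:
        """Argmax over class scores; ties broken by catalog order."""
        scores = self.model.predict_proba(features)
        order = [list(self.model.classes_).index(c) for c in self.catalog]
        return np.argmax(scores[:, order], axis=1)


def _window_features(bands: np.ndarray, window_size: int) -> np.ndarray:
    """(H*W, bands*window²) feature matrix with reflection padding at edges."""
    if window_size % 2 != 1 or window_size < 1:
        raise ParameterError("window_size must be odd and >= 1")
    n_bands, h, w = bands.shape
    if window_size == 1:
        return bands.reshape(n_bands, -1).T.astype(np.float64)
    pad = window_size // 2
    padded = np.pad(bands, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")
    win = sliding_window_view(padded, (window_size, window_size), axis=(1, 2))
    # -> (n_bands, h, w, k, k) -> (h*w, n_bands*k*k)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, -1).astype(np.float64)


def _build_model(model_config: dict | None, seed: int) -> Pipeline:
    cfg = dict(model_config or {})
    kind = cfg.pop("kind", "logreg")
    if kind == "logreg":
        est = LogisticRegression(
            max_iter=int(cfg.pop("max_iter", 1000)),
            C=float(cfg.pop("C", 10.0)),
            class_weight="balanced",
            random_state=seed,
        )
    else:
        raise ConfigurationError(f"unknown model kind: {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def train_classifier(
    scene: RrsScene,
    rois: ROISet,
    window_size: int = 3,
    model_config: dict | None = None,
    seed: int = 0,
    min_samples_per_class: int = 50,
    holdout_fraction: float = 0.2,
) -> TrainedClassifier:
    """Fit the window classifier on ROI pixels; report per-class holdout accuracy.

    A seeded stratified 20% holdout of ROI pixels is scored and recorded in
    ``training_report``; the returned model is refit on all ROI pixels.
    """
    rows, cols, labels = rois.labeled_cells(scene.grid)
    labels = np.asarray(labels)
    for cls in rois.catalog:
        n = int((labels == cls).sum())
        if n < min_samples_per_class:
            raise ParameterError(
                f"class {cls!r} has only {n} labeled pixels "
                f"(minimum {min_samples_per_class})"
            )
    feats_all = _window_features(scene.bands, window_size)
    idx = rows * scene.grid.width + cols
    X, y = feats_all[idx], labels

    rng = np.random.default_rng(seed)
    holdout = np.zeros(len(y), dtype=bool)
    for cls in rois.catalog:
        members = np.nonzero(y == cls)[0]
        k = max(1, int(round(holdout_fraction * members.size)))
        holdout[rng.choice(members, size=k, replace=False)] = True

    probe = _build_model(model_config, seed).fit(X[~holdout], y[~holdout])
    pred = probe.predict(X[holdout])
    per_class = {
        cls: float(np.mean(pred[y[holdout] == cls] == cls)) for cls in rois.catalog
    }
    report = {
        "holdout_accuracy": float(np.mean(pred == y[holdout])),
        "per_class_holdout_accuracy": per_class,
        "n_training_pixels": int(len(y)),
        "seed": seed,
    }
    model = _build_model(model_config, seed).fit(X, y)
    return TrainedClassifier(
        model=model,
        catalog=rois.catalog,
        window_size=window_size,
        wavelengths=tuple(scene.wavelengths),
        training_report=report,
    )


def classify_scene(model: TrainedClassifier, scene: RrsScene) -> ClassMap:
    """Assign exactly one scene class per pixel; invalid pixels become no_data.

    The output catalog is ``("no_data",) + model.catalog`` so that the no-data
    flag survives until (and through) class collapse.
    """
    if tuple(scene.wavelengths) != model.wavelengths:
        raise ParameterError("scene band set differs from the training scene")
    feats = _window_features(scene.bands, model.window_size)
    codes = model.predict_codes(feats).reshape(scene.grid.shape).astype(np.int16)
    labels = codes + 1  # shift: 0 reserved for no_data
    labels[~scene.valid_mask] = 0
    return ClassMap(
        labels=labels,
        grid=scene.grid,
        catalog=("no_data",) + tuple(model.catalog),
        metadata={"window_size": model.window_size, **model.training_report},
    )


def collapse_classes(cmap: ClassMap, collapse_table: dict[str, str] | None = None) -> ClassMap:
    """Label-for-label substitution of scene classes onto the four general classes.

    Pixel counts are conserved; a scene-class ``no_data`` (or masked pixels)
    must map to general no_data — the no-data flag is sticky.
    """
    table = collapse_table or cmap.collapse_table
    if table is None:
        raise ConfigurationError("no collapse_table supplied")
    table = dict(table)
    table.setdefault("no_data", "no_data")
    missing = [c for c in cmap.catalog if c not in table]
    if missing:
        raise ConfigurationError(f"scene classes missing from collapse table: {missing}")
    bad = {c: g for c, g in table.items() if g not in GENERAL_CLASSES}
    if bad:
        raise ConfigurationError(f"collapse targets outside the general classes: {bad}")
    if table["no_data"] != "no_data":
        raise ConfigurationError("no_data must collapse to no_data")
    lut = np.array(
        [GENERAL_CLASSES.index(table[c]) for c in cmap.catalog], dtype=np.int16
    )
    return ClassMap(
        labels=lut[cmap.labels],
        grid=cmap.grid,
        catalog=GENERAL_CLASSES,
        metadata={**cmap.metadata, "collapse_table": table},
    )
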