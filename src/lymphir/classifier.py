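"""Supervised per-pixel tissue classification.

Nine tissue classes are used for lymph-node histopathology: naïve/memory
B cells, T cells, activated B cells of the germinal-center dark and light
zones, red blood cells, connective tissue, the fibrovascular network,
smooth muscle, and an "other/unclassifiable" class covering debris and
confounding material.  The "other" class is a trained class with its own
ROIs, not a rejection rule.

Training data come from pathologist-style regions of interest (ROIs)
drawn on feature images; the classifier is a 40-tree random forest over
the spectral-metric features, predicting by per-tree majority vote with
ties broken deterministically toward the lowest class label.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from PIL import Image
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, IntegrityError, FormatError
from .features import FeatureImage

log = logging.getLogger(__name__)

__all__ = [
    "ClassScheme", "RoiSet", "ForestModel", "ClassMap",
    "assemble_training_set", "train_forest", "classify_image",
    "render_classmap", "spatial_block_split", "read_roi_file",
    "write_roi_file", "DEFAULT_CLASSES",
]

#: The nine-class scheme, label order fixed (labels 1..9; 0 = below mask).
DEFAULT_CLASSES: tuple[str, ...] = (
    "naive/memory B cell",
    "T cell",
    "activated B cell - dark zone",
    "activated B cell - light zone",
    "red blood cells",
    "connective tissue",
    "fibrovascular network",
    "smooth muscle",
    "other",
)

_DEFAULT_COLORS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 255),      # naive/memory B — blue
    (0, 170, 0),      # T cell — green
    (0, 0, 128),      # dark-zone activated B — dark blue
    (0, 255, 255),    # light-zone activated B — cyan
    (255, 0, 0),      # red blood cells — red
    (255, 170, 0),    # connective tissue — orange
    (255, 0, 255),    # fibrovascular network — magenta
    (170, 110, 40),   # smooth muscle — brown
    (128, 128, 128),  # other — grey
)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class names with display colors; label i+1 ↔ classes[i]."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    colors: tuple[tuple[int, int, int], ...] = _DEFAULT_COLORS

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError("class names must be unique")
        if len(self.colors) != len(self.classes):
            raise ConfigurationError("one color per class required")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_of(self, name: str) -> int:
        try:
            return self.classes.index(name) + 1
        except ValueError as exc:
            raise ConfigurationError(f"unknown class name '{name}'") from exc


@dataclass
class RoiSet:
    """Labelled pixel regions: ``entries`` of (image_id, class_name, coords).

    ``coords`` is an (n, 2) integer array of (row, col).  Within one image
    a pixel may belong to at most one ROI.
    """

    entries: list[tuple[str, str, np.ndarray]]

    def __post_init__(self) -> None:
        seen: dict[str, set[tuple[int, int]]] = {}
        norm = []
        for image_id, cls, coords in self.entries:
            coords = np.asarray(coords, dtype=int).reshape(-1, 2)
            pix = seen.setdefault(image_id, set())
            for rc in map(tuple, coords):
                if rc in pix:
                    raise IntegrityError(
                        f"pixel {rc} in image '{image_id}' appears in more "
                        "than one ROI")
                pix.add(rc)
            norm.append((image_id, cls, coords))
        self.entries = norm

    def for_image(self, image_id: str) -> list[tuple[str, np.ndarray]]:
        return [(c, xy) for i, c, xy in self.entries if i == image_id]


def write_roi_file(rois: RoiSet, path: str | Path) -> None:
    """Write ROIs as plain text with run-length-encoded pixel lists.

    Grammar (one token sequence per line)::

        image <image_id>
        class <class name>
        run <row> <col_start> <length>
    """
    lines = ["# lymphir ROI file v1"]
    for image_id, cls, coords in rois.entries:
        lines.append(f"image {image_id}")
        lines.append(f"class {cls}")
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        coords = coords[order]
        for row in np.unique(coords[:, 0]):
            cols = coords[coords[:, 0] == row, 1]
            breaks = np.nonzero(np.diff(cols) != 1)[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [cols.size - 1]))
            for s, e in zip(starts, ends):
                lines.append(f"run {row} {cols[s]} {e - s + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_roi_file(path: str | Path) -> RoiSet:
    """Parse the run-length ROI grammar written by :func:`write_roi_file`."""
    entries: list[tuple[str, str, list]] = []
    image_id = cls = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("image "):
            image_id = line[6:].strip()
        elif line.startswith("class "):
            cls = line[6:].strip()
            entries.append((image_id, cls, []))
        elif line.startswith("run "):
            m = re.fullmatch(r"run (\d+) (\d+) (\d+)", line)
            if m is None or not entries:
                raise FormatError(f"bad ROI run at line {ln}: '{line}'")
            r, c0, n = map(int, m.groups())
            entries[-1][2].extend((r, c0 + j) for j in range(n))
        else:
            raise FormatError(f"unrecognised ROI line {ln}: '{line}'")
    return RoiSet([(i, c, np.array(px, dtype=int)) for i, c, px in entries])


def assemble_training_set(
    features: dict[str, FeatureImage],
    rois: RoiSet,
    scheme: ClassScheme = ClassScheme(),
) -> pd.DataFrame:
    """Gather (feature vector, label) rows from ROI pixels.

    Rows are ordered deterministically (image id, then row-major pixel
    order).  ROI pixels that fall below the tissue mask, or whose metric
    vector carries a NaN sentinel, are excluded with a logged count; a
    class that ends up with zero pixels is a configuration error.
    """
    frames = []
    n_dropped = 0
    for image_id in sorted(features):
        fi = features[image_id]
        for cls, coords in rois.for_image(image_id):
            label = scheme.label_of(cls)
            r, c = coords[:, 0], coords[:, 1]
            if np.any((r < 0) | (r >= fi.values.shape[0]) |
                      (c < 0) | (c >= fi.values.shape[1])):
                raise IntegrityError(
                    f"ROI for '{cls}' in image '{image_id}' leaves the image")
            ok = fi.mask[r, c] & ~fi.flagged[r, c]
            n_dropped += int((~ok).sum())
            order = np.lexsort((c[ok], r[ok]))
            vals = fi.values[r[ok][order], c[ok][order]]
            df = pd.DataFrame(vals, columns=fi.metric_names)
            df.insert(0, "label", label)
            df.insert(0, "col", c[ok][order])
            df.insert(0, "row", r[ok][order])
            df.insert(0, "image", image_id)
            frames.append(df)
    if n_dropped:
        log.warning("excluded %d ROI pixels below mask or flagged", n_dropped)
    if not frames:
        raise ConfigurationError("no ROI pixels available for training")
    table = pd.concat(frames, ignore_index=True)
    counts = table["label"].value_counts()
    for label in counts.index:
        log.info("class %d (%s): %d training pixels", label,
                 scheme.classes[label - 1], counts[label])
    empty = [scheme.classes[lbl - 1]
             for lbl in range(1, scheme.n_classes + 1)
             if lbl not in counts.index
             and any(cls == scheme.classes[lbl - 1] for _, cls, _ in rois.entries)]
    if empty:
        raise ConfigurationError(f"classes with zero usable pixels: {empty}")
    return table


@dataclass
class ForestModel:
    """A fitted random-forest ensemble plus everything needed to reuse it."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    scheme: ClassScheme
    n_trees: int
    seed: int
    oob_accuracy: float | None = None
    impute_values: np.ndarray | None = None
    config_hash: str = ""

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return joblib.load(Path(path))


def train_forest(
    table: pd.DataFrame,
    n_trees: int = 40,
    seed: int = 0,
    scheme: ClassScheme = ClassScheme(),
    feature_names: list[str] | None = None,
) -> ForestModel:
    """Fit the bootstrap-aggregated tree ensemble (default 40 trees).

    Canonical forest defaults are used: unlimited depth, √(n_features)
    candidate features per split, full bootstrap, no class weighting.
    The out-of-bag accuracy is computed and stored; runs are fully
    reproducible for a fixed seed.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("image", "row", "col", "label")]
    y = table["label"].to_numpy(int)
    if np.unique(y).size < 2:
        raise ConfigurationError("training table must contain >= 2 classes")
    x = table[feature_names].to_numpy(float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1)
    import warnings
    with warnings.catch_warnings():
        # few trees can leave some rows never out-of-bag; that's acceptable
        warnings.simplefilter("ignore")
        forest.fit(x, y)
    oob = float(getattr(forest, "oob_score_", np.nan))
    log.info("forest trained: %d trees, %d rows, OOB accuracy %.4f",
             n_trees, len(y), oob)
    cfg = json.dumps({"n_trees": n_trees, "seed": seed,
                      "features": feature_names}, sort_keys=True)
    return ForestModel(
        estimator=forest, feature_names=feature_names, scheme=scheme,
        n_trees=n_trees, seed=seed, oob_accuracy=oob,
        impute_values=np.nanmedian(x, axis=0),
        config_hash=hashlib.sha256(cfg.encode()).hexdigest()[:16])


def _vote(model: ForestModel, x: np.ndarray) -> np.ndarray:
    """Per-tree majority vote; ties go to the lowest class label."""
    classes = model.estimator.classes_
    counts = np.zeros((x.shape[0], classes.size), dtype=np.int32)
    rows = np.arange(x.shape[0])
    for tree in model.estimator.estimators_:
        # sub-trees predict encoded class indices 0..n-1, not labels
        counts[rows, tree.predict(x).astype(int)] += 1
    # argmax returns the first maximum; classes_ is sorted ascending, so
    # ties break toward the lowest label automatically
    return classes[np.argmax(counts, axis=1)].astype(int)


def predict_labels(model: ForestModel, x: np.ndarray) -> np.ndarray:
    """Predict integer labels for a feature matrix by per-tree vote."""
    return _vote(model, np.asarray(x, dtype=float))


@dataclass
class ClassMap:
    """Integer label image: 0 below the tissue mask, 1..n_classes above."""

    labels: np.ndarray
    legend: ClassScheme
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.min() < 0 or self.labels.max() > self.legend.n_classes:
            raise IntegrityError("labels outside 0..n_classes")

    def class_counts(self) -> dict[str, int]:
        out = {}
        for lbl in range(1, self.legend.n_classes + 1):
            out[self.legend.classes[lbl - 1]] = int((self.labels == lbl).sum())
        return out

    def save_grid(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.labels, fmt="%d")

    @classmethod
    def load_grid(cls, path: str | Path,
                  legend: ClassScheme = ClassScheme()) -> "ClassMap":
        return cls(np.loadtxt(Path(path), dtype=int, ndmin=2), legend)


def classify_image(features: FeatureImage, model: ForestModel) -> ClassMap:
    """Classify every in-mask pixel of a feature image.

    Flagged pixels (NaN metrics inside the mask) are imputed with the
    training-set median before prediction, with a logged count.  Pixels
    below the mask receive label 0.
    """
    if features.metric_names != model.feature_names:
        raise ConfigurationError(
            f"feature names {features.metric_names} do not match the "
            f"model's {model.feature_names}")
    labels = np.zeros(features.mask.shape, dtype=np.int32)
    if features.mask.any():
        x = features.values[features.mask]
        nan_rows = np.isnan(x).any(axis=1)
        if nan_rows.any():
            log.warning("imputing %d flagged pixels with training medians",
                        int(nan_rows.sum()))
            x = np.where(np.isnan(x), model.impute_values, x)
        labels[features.mask] = _vote(model, x)
    return ClassMap(labels, model.scheme,
                    provenance={"model_hash": model.config_hash,
                                "n_trees": model.n_trees, "seed": model.seed})


def render_classmap(cmap: ClassMap, path: str | Path) -> None:
    """Write an indexed-color PNG, a text label grid and a legend sidecar."""
    path = Path(path)
    if path.suffix != ".png":
        path = path.with_suffix(".png")
    palette = [0, 0, 0] + [v for rgb in cmap.legend.colors for v in rgb]
    img = Image.fromarray(cmap.labels.astype(np.uint8), mode="P")
    img.putpalette(palette + [0] * (768 - len(palette)))
    try:
        img.save(path)
        cmap.save_grid(path.with_suffix(".labels.txt"))
        sidecar = {
            "legend": {str(i + 1): {"name": n, "color": list(c)}
                       for i, (n, c) in enumerate(zip(cmap.legend.classes,
                                                      cmap.legend.colors))},
            "class_counts": cmap.class_counts(),
            "background_pixels": int((cmap.labels == 0).sum()),
            "provenance": cmap.provenance,
        }
        path.with_suffix(".legend.json").write_text(json.dumps(sidecar, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write class map at {path}: {exc}") from exc


def spatial_block_split(
    rows: int, cols: int, block: int, test_fraction: float, seed: int
) -> np.ndarray:
    """Boolean test-set map from a blocked spatial partition.

    The image is tiled into ``block``×``block`` squares and whole squares
    are assigned to the test set at the requested fraction.  Evaluating on
    held-out blocks (never pixels scattered inside training blocks) avoids
    the optimistic bias spatial autocorrelation would otherwise cause.
    """
    if block < 1 or not 0 < test_fraction < 1:
        raise ConfigurationError("need block >= 1 and 0 < test_fraction < 1")
    nbr = -(-rows // block)
    nbc = -(-cols // block)
    rng = np.random.default_rng(seed)
    test_blocks = rng.random((nbr, nbc)) < test_fraction
    big = np.kron(test_blocks, np.ones((block, block), dtype=bool))
    return big[:rows, :cols]
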