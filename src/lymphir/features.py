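"""Spectral-metric feature extraction and the Amide-I tissue mask.

Rather than feeding every band to the classifier, each pixel's absorbance
spectrum is reduced to a small vector of chemically interpretable scalar
metrics: baseline-corrected peak heights, integrated band areas, ratios of
such features, and band centroids.  The default set holds 11 metrics over
980–3000 cm⁻¹ covering the protein (Amide I/II), nucleic-acid phosphate
and C–H stretch bands standard in tissue IR spectroscopy; it is fully
overridable through a plain-text config since different laboratories use
different metric tables.

Pixels without tissue are excluded up front by thresholding the Amide I
band: a pixel participates only if A(1654 cm⁻¹) > 0.2 AU (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import SpectralCube, WavenumberAxis
from .errors import ConfigurationError
from .preprocess import BaselineSpec, baseline_correct

log = logging.getLogger(__name__)

__all__ = [
    "MetricDefinition", "FeatureImage", "tissue_mask", "compute_metric",
    "extract_features", "default_metrics", "metrics_from_config",
    "AMIDE_I_CM", "TISSUE_THRESHOLD_AU",
]

#: Amide I band centre (protein C=O stretch), cm⁻¹ — the tissue-mask band.
AMIDE_I_CM = 1654.0
#: Absorbance threshold at Amide I above which a pixel counts as tissue.
TISSUE_THRESHOLD_AU = 0.2

_KINDS = ("peak_height", "band_area", "height_ratio", "area_ratio", "centroid")
#: Metrics in the default set must reference wavenumbers inside this window.
DEFAULT_METRIC_RANGE = (980.0, 3000.0)
#: Ratio metrics with |denominator| below this floor yield a NaN sentinel.
RATIO_FLOOR_AU = 1e-6


@dataclass(frozen=True)
class MetricDefinition:
    """Declarative recipe for one scalar spectral feature.

    ``measure`` holds one element for simple kinds (a wavenumber for
    ``peak_height``, a ``(lo, hi)`` interval for ``band_area``/``centroid``)
    and exactly two for the ratio kinds (numerator first).  ``baseline``
    holds one :class:`BaselineSpec` per measured feature.
    """

    name: str
    kind: str
    measure: tuple
    baseline: tuple[BaselineSpec, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown metric kind '{self.kind}'")
        want = 2 if self.kind.endswith("_ratio") else 1
        if len(self.measure) != want or len(self.baseline) != want:
            raise ConfigurationError(
                f"metric '{self.name}' ({self.kind}) needs {want} measure(s) "
                f"and baseline(s)")

    def referenced_wavenumbers(self) -> list[float]:
        out: list[float] = []
        for m in self.measure:
            out.extend(m if isinstance(m, (tuple, list)) else (m,))
        for b in self.baseline:
            out.extend(b.anchors)
        return out

    def validate_for_axis(self, axis: WavenumberAxis) -> None:
        for nu in self.referenced_wavenumbers():
            if not (axis.lo <= nu <= axis.hi):
                raise ConfigurationError(
                    f"metric '{self.name}' references {nu} cm^-1 outside the "
                    f"axis range [{axis.lo}, {axis.hi}]")


def _height(name: str, nu: float, anchors: tuple[float, float]) -> MetricDefinition:
    return MetricDefinition(name, "peak_height", (nu,), (BaselineSpec(anchors),))


def _area(name: str, lo: float, hi: float,
          anchors: tuple[float, float] | None = None) -> MetricDefinition:
    return MetricDefinition(name, "band_area", ((lo, hi),),
                            (BaselineSpec(anchors or (lo, hi)),))


def default_metrics() -> list[MetricDefinition]:
    """The package's default 11-metric set over 980–3000 cm⁻¹.

    Peak heights at the nucleic-acid phosphate (1080, 1236), Amide II
    (1546), Amide I (1654) and CH₂ stretch (2852, 2924) bands with local
    linear baselines; integrated areas over the phosphate/carbohydrate
    (1000–1140) and amide (1500–1700) regions; the 1080/1546 and 1654/1546
    height ratios; and the Amide I centroid over 1600–1700.
    """
    h1080 = _height("h1080", 1080.0, (1000.0, 1140.0))
    h1546 = _height("h1546", 1546.0, (1480.0, 1590.0))
    h1654 = _height("h1654", 1654.0, (1590.0, 1720.0))
    return [
        h1080,
        _height("h1236", 1236.0, (1180.0, 1290.0)),
        h1546,
        h1654,
        _height("h2852", 2852.0, (2800.0, 2880.0)),
        _height("h2924", 2924.0, (2880.0, 2980.0)),
        _area("a1000_1140", 1000.0, 1140.0),
        _area("a1500_1700", 1500.0, 1700.0),
        MetricDefinition("r1080_1546", "height_ratio",
                         h1080.measure + h1546.measure,
                         h1080.baseline + h1546.baseline),
        MetricDefinition("r1654_1546", "height_ratio",
                         h1654.measure + h1546.measure,
                         h1654.baseline + h1546.baseline),
        MetricDefinition("c1600_1700", "centroid", ((1600.0, 1700.0),),
                         (BaselineSpec((1590.0, 1720.0)),)),
    ]


def metrics_from_config(path) -> list[MetricDefinition]:
    """Load metric definitions from a YAML list.

    Each entry: ``{name, kind, measure: [...], baseline: [[lo, hi], ...]}``
    where a measure element is a number (peak) or two-element list (interval).
    """
    raw = yaml.safe_load(open(path))
    if not isinstance(raw, list) or not raw:
        raise ConfigurationError("metric config must be a non-empty list")
    out = []
    for entry in raw:
        try:
            measure = tuple(
                tuple(float(x) for x in m) if isinstance(m, (list, tuple))
                else float(m)
                for m in entry["measure"])
            baseline = tuple(BaselineSpec((float(b[0]), float(b[1])))
                             for b in entry["baseline"])
            out.append(MetricDefinition(entry["name"], entry["kind"],
                                        measure, baseline))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad metric entry {entry!r}: {exc}") from exc
    return out


def tissue_mask(cube: SpectralCube, threshold: float = TISSUE_THRESHOLD_AU,
                band: float = AMIDE_I_CM) -> np.ndarray:
    """Boolean tissue map: True where A(band) > threshold (strict).

    ``band`` is snapped to the nearest sampled band (logged when it does
    not fall exactly on the axis).
    """
    i = cube.axis.index_of(band)
    if abs(cube.axis.values[i] - band) > 1e-9:
        log.info("tissue mask band %.1f snapped to %.1f cm^-1",
                 band, cube.axis.values[i])
    return cube.absorbance[:, :, i] > threshold


def _primitive(flat: np.ndarray, axis: WavenumberAxis, kind: str, measure,
               baseline: BaselineSpec) -> np.ndarray:
    """One primitive feature (height / area / centroid) for a spectrum stack."""
    corrected = baseline_correct(flat, axis, baseline)
    if kind == "peak_height":
        return corrected[..., axis.index_of(measure)]
    lo, hi = measure
    sl = axis.range_slice(lo, hi)
    sub = corrected[..., sl]
    nu = axis.values[sl]
    if kind == "band_area":
        return np.trapezoid(sub, nu, axis=-1)
    # centroid: clamp negatives to 0 so the weighting is a proper density
    w = np.clip(sub, 0.0, None)
    total = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cen = (w * nu).sum(axis=-1) / total
    return np.where(total > 0, cen, np.nan)


def compute_metric(spectrum: np.ndarray, axis: WavenumberAxis,
                   m: MetricDefinition) -> float | np.ndarray:
    """Evaluate one metric on a spectrum (or a stack of spectra).

    Ratio metrics whose denominator magnitude falls below
    :data:`RATIO_FLOOR_AU` yield NaN (the flagged-pixel sentinel).
    """
    m.validate_for_axis(axis)
    spectrum = np.asarray(spectrum, dtype=float)
    scalar_in = spectrum.ndim == 1
    if m.kind in ("peak_height", "band_area", "centroid"):
        base_kind = m.kind
        val = _primitive(spectrum, axis, base_kind, m.measure[0], m.baseline[0])
    else:
        base_kind = "peak_height" if m.kind == "height_ratio" else "band_area"
        num = _primitive(spectrum, axis, base_kind, m.measure[0], m.baseline[0])
        den = _primitive(spectrum, axis, base_kind, m.measure[1], m.baseline[1])
        small = np.abs(den) < RATIO_FLOOR_AU
        if np.any(small):
            log.warning("%d pixels with |denominator| < %.0e in metric '%s'",
                        int(np.sum(small)), RATIO_FLOOR_AU, m.name)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(small, np.nan, num / np.where(small, 1.0, den))
    return float(val) if scalar_in else val


@dataclass
class FeatureImage:
    """Per-pixel metric vectors: ``values[row, col, metric]`` with a mask.

    Masked-out pixels carry NaN sentinels and are excluded from any
    tabular export and from training.
    """

    values: np.ndarray
    metric_names: list[str]
    mask: np.ndarray
    pixel_pitch: float = 1.1
    flagged: np.ndarray = field(default=None)  # in-mask pixels with NaN metrics

    def __post_init__(self) -> None:
        if self.values.shape[2] != len(self.metric_names):
            raise ConfigurationError("metric count mismatch")
        if self.flagged is None:
            self.flagged = self.mask & np.isnan(self.values).any(axis=2)

    @property
    def n_metrics(self) -> int:
        return len(self.metric_names)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per in-mask, unflagged pixel."""
        ok = self.mask & ~self.flagged
        r, c = np.nonzero(ok)
        df = pd.DataFrame(self.values[r, c], columns=self.metric_names)
        df.insert(0, "col", c)
        df.insert(0, "row", r)
        return df

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rows: int, cols: int,
                   pixel_pitch: float = 1.1) -> "FeatureImage":
        names = [c for c in df.columns if c not in ("row", "col")]
        values = np.full((rows, cols, len(names)), np.nan)
        mask = np.zeros((rows, cols), dtype=bool)
        r = df["row"].to_numpy(int)
        c = df["col"].to_numpy(int)
        values[r, c] = df[names].to_numpy(float)
        mask[r, c] = True
        return cls(values, names, mask, pixel_pitch)


def extract_features(cube: SpectralCube,
                     metrics: list[MetricDefinition] | None = None,
                     mask: np.ndarray | None = None) -> FeatureImage:
    """Evaluate every metric at every in-mask pixel.

    All metrics are validated against the axis before any computation so a
    bad configuration fails fast.  Metric order follows the given list.
    """
    if metrics is None:
        metrics = default_metrics()
    if not metrics:
        raise ConfigurationError("metric list must be non-empty")
    names = [m.name for m in metrics]
    if len(set(names)) != len(names):
        raise ConfigurationError("metric names must be unique")
    for m in metrics:
        m.validate_for_axis(cube.axis)
    if mask is None:
        mask = np.ones(cube.shape[:2], dtype=bool)

    values = np.full(cube.shape[:2] + (len(metrics),), np.nan)
    flat = cube.flat_spectra()[mask.ravel()]
    if flat.shape[0]:
        cols = np.stack([compute_metric(flat, cube.axis, m) for m in metrics],
                        axis=-1)
        values[mask] = cols
    return FeatureImage(values, names, mask.copy(), cube.pixel_pitch)
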