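"""Spectral-domain preprocessing.

Covers the standard chain applied to FT-IR absorbance images before
analysis: ratioing single-beam intensities to absorbance, truncating to
the informative 900–3800 cm⁻¹ window, two-point linear baseline
correction, Savitzky–Golay second derivatives (13-point window by
default), vector normalisation over a chosen range, and spatial pixel
binning for resolution-degradation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import SpectralCube, WavenumberAxis
from .errors import RangeError

log = logging.getLogger(__name__)

__all__ = [
    "BaselineSpec", "SgParams", "absorbance_from_single_beam", "truncate",
    "baseline_correct", "second_derivative", "vector_normalize", "bin_pixels",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Two-point linear baseline: the line through the spectrum at the anchors.

    ``anchors`` are ``(ν_left, ν_right)`` in cm⁻¹ with ν_left < ν_right.
    """

    anchors: tuple[float, float]
    kind: str = "linear"

    def __post_init__(self) -> None:
        lo, hi = self.anchors
        if lo >= hi:
            raise RangeError(f"baseline anchors must satisfy left < right, got {self.anchors}")
        if self.kind != "linear":
            raise RangeError(f"unsupported baseline kind '{self.kind}'")


@dataclass(frozen=True)
class SgParams:
    """Savitzky–Golay filter parameters (window in points, not cm⁻¹)."""

    window: int = 13
    polyorder: int = 2
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < self.polyorder + 1:
            raise RangeError("SG window must be odd and >= polyorder + 1")
        if self.deriv > self.polyorder:
            raise RangeError("SG derivative order cannot exceed polyorder")


def absorbance_from_single_beam(
    sample: np.ndarray,
    background: np.ndarray,
    axis: WavenumberAxis,
    pixel_pitch: float = 1.1,
    floor: float = 1e-6,
) -> SpectralCube:
    """Ratio per-pixel single-beam spectra against a background to absorbance.

    A(ν) = −log₁₀(S(ν)/B(ν)).  Non-positive sample intensities are clamped
    to ``floor``·B (logged with a count) rather than raising, since stray
    detector pixels routinely go non-positive.
    """
    sample = np.asarray(sample, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 1 or background.size != len(axis):
        raise RangeError("background must be a single spectrum on the axis")
    if np.any(background <= 0):
        raise RangeError("background intensities must be strictly positive")
    if sample.ndim != 3 or sample.shape[-1] != len(axis):
        raise RangeError("sample must be (rows, cols, bands) matching the axis")
    bad = sample <= 0
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("clamped %d non-positive sample intensities to floor", n_bad)
        sample = np.where(bad, floor * background, sample)
    absorbance = -np.log10(sample / background)
    return SpectralCube(absorbance, axis, pixel_pitch)


def truncate(cube: SpectralCube, lo: float = 900.0, hi: float = 3800.0) -> SpectralCube:
    """Retain bands with lo ≤ ν ≤ hi (closed interval on both ends)."""
    sl = cube.axis.range_slice(lo, hi)
    return cube.with_data(cube.absorbance[:, :, sl],
                          axis=WavenumberAxis(cube.axis.values[sl]))


def _anchor_indices(axis: WavenumberAxis, spec: BaselineSpec) -> tuple[int, int]:
    il, ir = axis.index_of(spec.anchors[0]), axis.index_of(spec.anchors[1])
    if (abs(axis.values[il] - spec.anchors[0]) > axis.step / 2 + 1e-9
            or abs(axis.values[ir] - spec.anchors[1]) > axis.step / 2 + 1e-9):
        log.info("baseline anchors %s snapped to bands (%.1f, %.1f)",
                 spec.anchors, axis.values[il], axis.values[ir])
    if il == ir:
        raise RangeError(f"baseline anchors {spec.anchors} snap to one band")
    return il, ir


def baseline_correct(
    spectrum: np.ndarray, axis: WavenumberAxis, spec: BaselineSpec
) -> np.ndarray:
    """Subtract the straight line through the spectrum at the two anchors.

    Works on a single spectrum or a stack ``(..., bands)``; values at the
    anchor bands become exactly 0.  Anchors off the sampled axis are
    snapped to the nearest band (logged).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    il, ir = _anchor_indices(axis, spec)
    nu_l, nu_r = axis.values[il], axis.values[ir]
    a_l = spectrum[..., il][..., np.newaxis]
    a_r = spectrum[..., ir][..., np.newaxis]
    t = (axis.values - nu_l) / (nu_r - nu_l)
    return spectrum - (a_l + (a_r - a_l) * t)


def second_derivative(cube: SpectralCube, params: SgParams = SgParams()) -> SpectralCube:
    """Savitzky–Golay derivative along the spectral axis, physical units.

    The derivative is scaled by the band spacing (``delta``) so a second
    derivative carries units of AU·cm².  The derivative is undefined within
    half a window of the band edges, so the output is trimmed to the valid
    interior and the axis shrunk accordingly (no padded values are invented).
    """
    if cube.n_bands < params.window:
        raise RangeError(
            f"{cube.n_bands} bands < SG window {params.window}")
    d = savgol_filter(cube.absorbance, params.window, params.polyorder,
                      deriv=params.deriv, delta=cube.axis.step, axis=2)
    half = params.window // 2
    return cube.with_data(d[:, :, half:cube.n_bands - half],
                          axis=WavenumberAxis(cube.axis.values[half:cube.n_bands - half]))


def vector_normalize(
    cube: SpectralCube, lo: float | None = None, hi: float | None = None
) -> tuple[SpectralCube, np.ndarray]:
    """Restrict each pixel's spectrum to [lo, hi] and divide by its 2-norm.

    Returns ``(normalized cube over [lo, hi], ok_mask)`` where ``ok_mask``
    is False for zero-norm pixels (left as zeros, to be excluded downstream).
    """
    if lo is None:
        lo = cube.axis.lo
    if hi is None:
        hi = cube.axis.hi
    sub = truncate(cube, lo, hi)
    norms = np.linalg.norm(sub.absorbance, axis=2)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    data = sub.absorbance / safe[:, :, np.newaxis]
    data[~ok] = 0.0
    if not ok.all():
        log.warning("%d zero-norm pixels flagged during vector normalization",
                    int((~ok).sum()))
    return sub.with_data(data), ok


def bin_pixels(cube: SpectralCube, factor: int) -> SpectralCube:
    """Average non-overlapping factor×factor pixel blocks per band.

    Output dims are ``floor(rows/factor) × floor(cols/factor)``; trailing
    remainder rows/cols are dropped (logged) and pixel pitch is multiplied
    by the factor.  ``factor=1`` is the identity.
    """
    if factor < 1:
        raise RangeError("binning factor must be >= 1")
    if factor == 1:
        return cube
    r, c = cube.rows // factor, cube.cols // factor
    if r == 0 or c == 0:
        raise RangeError(f"binning factor {factor} exceeds image dims "
                         f"{cube.rows}x{cube.cols}")
    if cube.rows % factor or cube.cols % factor:
        log.info("bin_pixels dropping remainder of %d rows, %d cols",
                 cube.rows % factor, cube.cols % factor)
    trimmed = cube.absorbance[:r * factor, :c * factor, :]
    binned = trimmed.reshape(r, factor, c, factor, cube.n_bands).mean(axis=(1, 3))
    return cube.with_data(binned, pixel_pitch=cube.pixel_pitch * factor)
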