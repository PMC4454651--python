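"""Core in-memory containers for hyperspectral absorbance data.

A mid-infrared absorbance image is a 3-D array indexed ``(row, col, band)``
together with a wavenumber axis in cm⁻¹ and a physical pixel pitch in μm.
High-definition (HD) FT-IR imaging works at ~1.1 μm/pixel; conventional
instruments at 6.25 μm/pixel.  All modules in this package exchange data
through :class:`SpectralCube`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import RangeError

__all__ = ["WavenumberAxis", "SpectralCube", "hd_pixel_pitch"]

#: Detector tile edge in pixels for the HD focal plane array.
FPA_TILE_PIXELS = 128
#: Physical extent of one HD tile on the sample, μm.
FPA_TILE_EXTENT_UM = 140.0


def hd_pixel_pitch(
    tile_extent_um: float = FPA_TILE_EXTENT_UM,
    tile_pixels: int = FPA_TILE_PIXELS,
) -> float:
    """Pixel pitch (μm/pixel) implied by a detector tile geometry.

    For the HD focal-plane array a 140 μm × 140 μm field is mapped onto a
    128 × 128 detector, giving 140/128 = 1.09375 ≈ 1.1 μm per pixel.
    """
    if tile_pixels <= 0 or tile_extent_um <= 0:
        raise RangeError("tile extent and pixel count must be positive")
    return tile_extent_um / tile_pixels


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniformly spaced, strictly increasing wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise RangeError("axis needs at least two wavenumbers")
        if np.any(v <= 0):
            raise RangeError("wavenumbers must be positive (cm^-1)")
        d = np.diff(v)
        if np.any(d <= 0):
            raise RangeError("axis must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
            raise RangeError("axis spacing must be uniform (rtol 1e-6)")

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "WavenumberAxis":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=1e-9)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def index_of(self, wavenumber: float) -> int:
        """Index of the band nearest ``wavenumber`` (nearest-band snapping)."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def range_slice(self, lo: float, hi: float) -> slice:
        """Slice selecting bands with ``lo <= ν <= hi`` (closed interval)."""
        if lo >= hi:
            raise RangeError(f"empty wavenumber range [{lo}, {hi}]")
        idx = np.nonzero((self.values >= lo) & (self.values <= hi))[0]
        if idx.size == 0:
            raise RangeError(
                f"range [{lo}, {hi}] cm^-1 selects no bands on axis "
                f"[{self.lo}, {self.hi}]"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class SpectralCube:
    """Absorbance image: ``absorbance[row, col, band]`` in AU.

    Parameters
    ----------
    absorbance
        3-D float array, shape ``(rows, cols, bands)``.
    axis
        Wavenumber axis; its length must equal the band dimension.
    pixel_pitch
        Physical pixel size on the sample, μm/pixel.
    origin
        ``(row, col)`` offset of this cube inside a parent mosaic.
    validity
        Optional boolean map marking pixels that carry real data (mosaics
        with absent tiles mark the fill region ``False``).
    """

    absorbance: np.ndarray
    axis: WavenumberAxis
    pixel_pitch: float = 1.1
    origin: tuple[int, int] = (0, 0)
    validity: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance)
        if a.ndim != 3:
            raise RangeError("absorbance must be (rows, cols, bands)")
        if a.shape[2] != len(self.axis):
            raise RangeError(
                f"band count {a.shape[2]} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(a)):
            raise RangeError("absorbance contains non-finite values")
        if self.pixel_pitch <= 0:
            raise RangeError("pixel_pitch must be positive")
        self.absorbance = a
        if self.validity is not None:
            v = np.asarray(self.validity, dtype=bool)
            if v.shape != a.shape[:2]:
                raise RangeError("validity shape must match spatial dims")
            self.validity = v

    @property
    def rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def cols(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_bands(self) -> int:
        return self.absorbance.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.absorbance.shape

    def flat_spectra(self) -> np.ndarray:
        """View of the cube as ``(rows*cols, bands)`` spectra."""
        return self.absorbance.reshape(-1, self.n_bands)

    def band_image(self, wavenumber: float) -> np.ndarray:
        """2-D image of the band nearest ``wavenumber``."""
        return self.absorbance[:, :, self.axis.index_of(wavenumber)]

    def with_data(self, absorbance: np.ndarray, axis: WavenumberAxis | None = None,
                  pixel_pitch: float | None = None) -> "SpectralCube":
        """Copy of this cube with replaced data (axis/pitch optionally too)."""
        return replace(
            self,
            absorbance=absorbance,
            axis=self.axis if axis is None else axis,
            pixel_pitch=self.pixel_pitch if pixel_pitch is None else pixel_pitch,
        )
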