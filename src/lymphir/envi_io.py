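"""ENVI-format hyperspectral I/O and tile mosaicking.

FT-IR imaging systems emit one cube per focal-plane-array acquisition
(one 128 × 128 pixel tile covering 140 μm × 140 μm of sample); a whole
biopsy is a grid of such tiles that must be mosaicked into one image.
This module reads and writes the plain ENVI header + flat-binary pair
(BSQ, BIL or BIP interleave) and abuts tiles into a mosaic with an
explicit validity mask for absent grid positions.

Coordinate convention: 0-based, row-major, (row, col) = (down, right);
the cube origin is the top-left pixel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import SpectralCube, WavenumberAxis
from .errors import FormatError, IncompatibilityError, IntegrityError, RangeError

log = logging.getLogger(__name__)

__all__ = ["read_envi", "write_envi", "TileGrid", "mosaic"]

# ENVI "data type" codes for the float widths this package emits.
_DTYPE_TO_CODE = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_CODE_TO_DTYPE = {
    1: np.dtype("uint8"), 2: np.dtype("int16"), 3: np.dtype("int32"),
    4: np.dtype("float32"), 5: np.dtype("float64"), 12: np.dtype("uint16"),
    13: np.dtype("uint32"), 14: np.dtype("int64"), 15: np.dtype("uint64"),
}
_REQUIRED_FIELDS = ("samples", "lines", "bands", "data type", "interleave",
                    "wavelength")

_WAVENUMBER_UNITS = {"wavenumber", "wavenumbers", "cm-1", "cm^-1", "1/cm"}
_MICRON_UNITS = {"micrometers", "micrometer", "microns", "micron", "um"}


def _parse_header(text: str) -> dict[str, str]:
    """Parse ENVI header text into a lower-cased key → raw-value dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing 'ENVI' magic line in header")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # Fields are `key = value` or `key = { ... }` possibly spanning lines.
    pattern = re.compile(r"^\s*([\w ^/-]+?)\s*=\s*(\{.*?\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{") and not val.endswith("}"):
            raise FormatError(f"unterminated '{{' list for field '{key}'")
        fields[key] = val
        pos = m.end()
    return fields


def _field(fields: dict[str, str], key: str) -> str:
    if key not in fields:
        raise FormatError(f"ENVI header missing required field '{key}'")
    return fields[key]


def _parse_list(raw: str, key: str) -> list[float]:
    inner = raw.strip()
    if inner.startswith("{") and inner.endswith("}"):
        inner = inner[1:-1]
    try:
        return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]
    except ValueError as exc:
        raise FormatError(f"garbled numeric list in field '{key}'") from exc


def _binary_path(header_path: Path) -> Path:
    """Locate the binary paired with a header (.hdr stripped, or .dat/.img/.bin)."""
    base = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    candidates = [base, base.with_suffix(".dat"), base.with_suffix(".img"),
                  base.with_suffix(".bin")]
    for c in candidates:
        if c.exists() and c != header_path:
            return c
    raise FormatError(f"no binary file found next to header {header_path}")


def read_envi(header_path: str | Path, pixel_pitch: float | None = None) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    The band axis is normalised to ascending wavenumber regardless of the
    on-disk order; a header whose wavelength units are micrometres is
    converted to cm⁻¹ via 10⁴/λ with a logged warning.

    Parameters
    ----------
    header_path
        Path to the ``.hdr`` text header; the binary is located next to it.
    pixel_pitch
        Overrides the ``pixel size`` header field (μm/pixel); defaults to
        that field or 1.1 μm if absent.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    fields = _parse_header(header_path.read_text())
    for key in _REQUIRED_FIELDS:
        _field(fields, key)

    def _int(key: str) -> int:
        try:
            return int(_field(fields, key))
        except ValueError as exc:
            raise FormatError(f"garbled integer field '{key}'") from exc

    samples, lines, bands = _int("samples"), _int("lines"), _int("bands")
    offset = int(fields.get("header offset", "0"))
    code = _int("data type")
    if code not in _CODE_TO_DTYPE:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = _CODE_TO_DTYPE[code]
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    interleave = _field(fields, "interleave").strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"interleave must be bsq/bil/bip, got '{interleave}'")

    wavelengths = np.array(_parse_list(_field(fields, "wavelength"), "wavelength"))
    if wavelengths.size != bands:
        raise IntegrityError(
            f"wavelength list length {wavelengths.size} != bands {bands}")
    units = fields.get("wavelength units", "wavenumber").strip().lower()
    if units in _MICRON_UNITS:
        log.warning("converting header wavelengths from micrometers to cm^-1")
        wavelengths = 1.0e4 / wavelengths
    elif units not in _WAVENUMBER_UNITS:
        raise FormatError(f"unsupported wavelength units '{units}'")

    binary = _binary_path(header_path)
    raw = np.fromfile(binary, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise IntegrityError(
            f"binary holds {raw.size} values but header declares "
            f"{lines}x{samples}x{bands} = {expected}")

    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    order = np.argsort(wavelengths, kind="stable")
    data = np.ascontiguousarray(data[:, :, order], dtype=np.dtype(dtype.kind + str(dtype.itemsize)))
    axis = WavenumberAxis(wavelengths[order])

    if pixel_pitch is None:
        pixel_pitch = float(fields.get("pixel size", "1.1").strip("{} ").split(",")[0])
    return SpectralCube(data.astype(data.dtype, copy=False), axis, pixel_pitch)


def write_envi(cube: SpectralCube, header_path: str | Path,
               interleave: str = "bsq", dtype: str = "float32") -> Path:
    """Write a cube as an ENVI header + binary pair; returns the binary path.

    ``read_envi`` inverts this bit-exactly for the chosen float width.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise RangeError(f"interleave must be bsq/bil/bip, got '{interleave}'")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _DTYPE_TO_CODE:
        raise RangeError("on-disk dtype must be float32 or float64")

    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    binary_path = header_path.with_suffix(".dat")

    data = cube.absorbance
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.values)
    header = (
        "ENVI\n"
        "description = {lymphir absorbance cube}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[np_dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size = {{{cube.pixel_pitch:.6f}, {cube.pixel_pitch:.6f}}}\n"
        "wavelength units = Wavenumber\n"
        f"wavelength = {{{wl}}}\n"
    )
    try:
        header_path.write_text(header)
        np.ascontiguousarray(out, dtype=np_dtype.newbyteorder("<")).tofile(binary_path)
    except OSError as exc:
        raise OSError(f"cannot write ENVI pair at {header_path}: {exc}") from exc
    return binary_path


@dataclass
class TileGrid:
    """A set of equally sized tiles placed on an acquisition grid.

    ``tiles`` is a list of ``(grid_row, grid_col, SpectralCube)``; every
    tile must share one wavenumber axis and pixel pitch, and no two tiles
    may occupy the same grid position.
    """

    tiles: list[tuple[int, int, SpectralCube]]
    tile_rows: int = 128
    tile_cols: int = 128

    def __post_init__(self) -> None:
        if not self.tiles:
            raise RangeError("TileGrid needs at least one tile")
        seen: set[tuple[int, int]] = set()
        _, _, first = self.tiles[0]
        for gr, gc, cube in self.tiles:
            if gr < 0 or gc < 0:
                raise RangeError("grid positions must be non-negative")
            if (gr, gc) in seen:
                raise IncompatibilityError(f"duplicate tile at grid ({gr}, {gc})")
            seen.add((gr, gc))
            if cube.shape[:2] != (self.tile_rows, self.tile_cols):
                raise IncompatibilityError(
                    f"tile at ({gr}, {gc}) is {cube.shape[:2]}, expected "
                    f"({self.tile_rows}, {self.tile_cols})")
            if cube.axis != first.axis:
                raise IncompatibilityError("tiles must share one wavenumber axis")
            if not np.isclose(cube.pixel_pitch, first.pixel_pitch):
                raise IncompatibilityError("tiles must share one pixel pitch")


def mosaic(grid: TileGrid, fill_value: float = 0.0) -> SpectralCube:
    """Abut tiles into one cube; absent positions are fill-valued.

    The output spans ``(max grid_row + 1) · tile_rows`` rows by
    ``(max grid_col + 1) · tile_cols`` columns; each tile's values are
    placed verbatim at offset ``(grid_row·tile_rows, grid_col·tile_cols)``.
    The returned cube's ``validity`` mask is ``False`` over fill regions
    (the overlays in sparse acquisitions leave grid positions empty).
    Tiles are abutted with no seam blending.
    """
    _, _, first = grid.tiles[0]
    n_rows = (max(gr for gr, _, _ in grid.tiles) + 1) * grid.tile_rows
    n_cols = (max(gc for _, gc, _ in grid.tiles) + 1) * grid.tile_cols
    out = np.full((n_rows, n_cols, first.n_bands), fill_value,
                  dtype=first.absorbance.dtype)
    validity = np.zeros((n_rows, n_cols), dtype=bool)
    for gr, gc, cube in grid.tiles:
        r0, c0 = gr * grid.tile_rows, gc * grid.tile_cols
        out[r0:r0 + grid.tile_rows, c0:c0 + grid.tile_cols, :] = cube.absorbance
        validity[r0:r0 + grid.tile_rows, c0:c0 + grid.tile_cols] = True
    return SpectralCube(out, first.axis, first.pixel_pitch, validity=validity)
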