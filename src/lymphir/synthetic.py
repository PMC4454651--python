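"""Seedable lymph-node hyperspectral phantoms with known ground truth.

No public FT-IR dataset of lymph-node biopsies accompanies this problem,
so the pipeline is validated on synthetic phantoms: spatial layouts that
mimic lymph-node anatomy (capsule, mantle of naïve B cells, germinal
center split into light and dark zones, T-cell paracortex, vessels with
red cells and a fibrovascular wall, debris), per-class endmember spectra
built from Gaussian absorption bands at the standard tissue wavenumbers
(Amide A 3300, Amide B 3075, C–H stretches 2852–2958, ester 1740,
Amide I 1654, Amide II 1546, nucleic-acid phosphate 1236/1080, C–O 1032
cm⁻¹, …), per-pixel section-thickness variation, subcellular texture,
optical blur at the pixel scale, and additive spectral noise.

The light-zone and dark-zone activated-B endmembers are deliberately the
most spectrally similar pair (they differ only in nucleic-acid band
amplitudes), so that under heavy noise the classifier's first confusions
appear between those two classes — the subtlest biological distinction.

Everything is driven by a single seed: identical :class:`PhantomSpec`
(including the seed) ⇒ bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifier import ClassScheme, RoiSet, DEFAULT_CLASSES
from .classifier import ClassMap
from .core import SpectralCube, WavenumberAxis
from .errors import RangeError

log = logging.getLogger(__name__)

__all__ = ["Endmember", "PhantomSpec", "make_endmember_library",
           "generate_phantom", "degrade_to_lowres"]

# Band groups used for subcellular texture modulation
_NUCLEIC = {1080.0, 1236.0, 1032.0}
_LIPID = {2852.0, 2872.0, 2924.0, 2958.0, 1740.0}


@dataclass(frozen=True)
class Endmember:
    """A class endmember: a sum of Gaussian absorption bands + baseline.

    ``bands`` is a tuple of (center cm⁻¹, σ cm⁻¹, amplitude AU); the
    baseline is offset + slope·(3800 − ν)/2900, the gentle rise toward low
    wavenumber typical of scattering backgrounds.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline_offset: float = 0.02
    baseline_slope: float = 0.02

    def spectrum(self, axis: WavenumberAxis) -> np.ndarray:
        nu = axis.values
        out = self.baseline_offset + self.baseline_slope * (3800.0 - nu) / 2900.0
        for c, s, a in self.bands:
            out = out + a * np.exp(-0.5 * ((nu - c) / s) ** 2)
        return out

    def partial_spectrum(self, axis: WavenumberAxis, centers: set) -> np.ndarray:
        """Sum of only the bands whose centres are in ``centers`` (no baseline)."""
        nu = axis.values
        out = np.zeros_like(nu)
        for c, s, a in self.bands:
            if c in centers:
                out = out + a * np.exp(-0.5 * ((nu - c) / s) ** 2)
        return out


# (center, sigma) for the shared band set; per-class amplitude tables below.
_BAND_SHAPES: tuple[tuple[float, float], ...] = (
    (3300.0, 70.0),   # Amide A (N-H stretch)
    (3075.0, 30.0),   # Amide B / aromatic-olefinic C-H
    (2958.0, 12.0),   # CH3 asym stretch
    (2924.0, 14.0),   # CH2 asym stretch
    (2872.0, 12.0),   # CH3 sym stretch
    (2852.0, 12.0),   # CH2 sym stretch
    (1740.0, 14.0),   # ester C=O (lipids)
    (1654.0, 22.0),   # Amide I
    (1546.0, 20.0),   # Amide II
    (1456.0, 14.0),   # CH2/CH3 bending
    (1400.0, 14.0),   # COO- sym / CH3
    (1310.0, 18.0),   # Amide III
    (1236.0, 20.0),   # PO2- asym (nucleic acids) / Amide III
    (1155.0, 14.0),   # C-O carbohydrate
    (1080.0, 18.0),   # PO2- sym (nucleic acids)
    (1032.0, 14.0),   # C-O (glycogen / collagen)
    (1204.0, 14.0),   # collagen C-O-C
)

# Per-class amplitudes (AU), one entry per band shape above.
_AMPLITUDES: dict[str, tuple[float, ...]] = {
    # class:              3300  3075  2958  2924  2872  2852  1740  1654  1546  1456  1400  1310  1236  1155  1080  1032  1204
    DEFAULT_CLASSES[0]: (0.42, 0.05, 0.06, 0.11, 0.05, 0.07, 0.02, 0.62, 0.30, 0.10, 0.08, 0.05, 0.12, 0.04, 0.16, 0.06, 0.01),
    DEFAULT_CLASSES[1]: (0.44, 0.05, 0.07, 0.14, 0.06, 0.10, 0.03, 0.64, 0.34, 0.11, 0.07, 0.06, 0.08, 0.05, 0.10, 0.05, 0.01),
    DEFAULT_CLASSES[2]: (0.41, 0.05, 0.06, 0.10, 0.05, 0.06, 0.02, 0.60, 0.29, 0.10, 0.08, 0.05, 0.18, 0.04, 0.24, 0.07, 0.01),
    DEFAULT_CLASSES[3]: (0.41, 0.05, 0.06, 0.10, 0.05, 0.06, 0.02, 0.60, 0.29, 0.10, 0.08, 0.05, 0.16, 0.04, 0.21, 0.07, 0.01),
    DEFAULT_CLASSES[4]: (0.50, 0.08, 0.07, 0.12, 0.06, 0.08, 0.01, 0.74, 0.38, 0.11, 0.09, 0.06, 0.04, 0.03, 0.03, 0.02, 0.00),
    DEFAULT_CLASSES[5]: (0.40, 0.04, 0.06, 0.10, 0.05, 0.07, 0.02, 0.58, 0.33, 0.09, 0.07, 0.09, 0.10, 0.06, 0.10, 0.14, 0.12),
    DEFAULT_CLASSES[6]: (0.42, 0.05, 0.07, 0.14, 0.06, 0.10, 0.06, 0.60, 0.31, 0.10, 0.08, 0.06, 0.09, 0.05, 0.11, 0.09, 0.06),
    DEFAULT_CLASSES[7]: (0.45, 0.05, 0.06, 0.10, 0.05, 0.06, 0.02, 0.66, 0.36, 0.13, 0.12, 0.10, 0.07, 0.07, 0.06, 0.08, 0.01),
    DEFAULT_CLASSES[8]: (0.28, 0.03, 0.09, 0.28, 0.10, 0.20, 0.18, 0.38, 0.15, 0.08, 0.05, 0.03, 0.05, 0.06, 0.05, 0.04, 0.01),
}


def make_endmember_library(seed: int = 0,
                           jitter: float = 0.01) -> dict[str, Endmember]:
    """The nine-class endmember library.

    A small seeded multiplicative jitter (σ = ``jitter``) perturbs band
    amplitudes so distinct seeds give distinct but chemically equivalent
    libraries; the same seed always reproduces the same library.  The
    jitter is an order of magnitude smaller than the designed light-zone /
    dark-zone contrast, so that pair remains the most correlated.
    """
    rng = np.random.default_rng(seed)
    lib: dict[str, Endmember] = {}
    for name in DEFAULT_CLASSES:
        amps = np.array(_AMPLITUDES[name])
        amps = amps * rng.normal(1.0, jitter, amps.size)
        amps = np.clip(amps, 0.0, None)
        bands = tuple((c, s, float(a))
                      for (c, s), a in zip(_BAND_SHAPES, amps))
        lib[name] = Endmember(name, bands)
    return lib


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scene (determinism contract:
    identical spec ⇒ identical phantom).

    Defaults emulate an HD acquisition: 1.1 μm pixels, 900–3800 cm⁻¹ at
    4 cm⁻¹ spacing, optical blur σ of 1.5 μm, additive noise σ of 0.01 AU
    per band, ±10 % lognormal section-thickness variation and a gentle
    subcellular texture on the nucleic-acid and lipid band groups.
    """

    rows: int = 256
    cols: int = 256
    pixel_pitch: float = 1.1
    axis: WavenumberAxis = field(
        default_factory=lambda: WavenumberAxis.from_range(900.0, 3800.0, 4.0))
    layout: str = "follicle"
    n_layout_classes: int = 9
    blur_sigma_um: float = 1.5
    noise_sigma: float = 0.01
    band_dependent_noise: bool = False
    texture_amplitude: float = 0.08
    texture_scale_px: float = 2.0
    thickness_sigma_log: float = 0.1
    roi_erosion: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 8 or self.cols < 8:
            raise RangeError("phantom must be at least 8x8")
        if min(self.blur_sigma_um, self.noise_sigma,
               self.texture_amplitude, self.thickness_sigma_log) < 0:
            raise RangeError("sigmas and amplitudes must be >= 0")
        if self.layout not in ("follicle", "sinus", "sheet", "grid"):
            raise RangeError(f"unknown layout '{self.layout}'")


def _disk(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float],
          radius: float) -> np.ndarray:
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def paint_layout(spec: PhantomSpec) -> np.ndarray:
    """Integer label image (1..9) for the requested layout."""
    r, c = spec.rows, spec.cols
    rr, cc = np.mgrid[0:r, 0:c].astype(float)
    m = min(r, c)
    if spec.layout == "sheet":
        return np.ones((r, c), dtype=np.int32)
    if spec.layout == "grid":
        n = spec.n_layout_classes
        patch = max(m // (2 * n), 8)
        br = (rr.astype(int) // patch)
        bc = (cc.astype(int) // patch)
        return ((br + bc * ((r + patch - 1) // patch)) % n + 1).astype(np.int32)
    if spec.layout == "sinus":
        n = min(spec.n_layout_classes, 3)
        band = max(r // (3 * n), 4)
        return ((rr.astype(int) // band) % n + 1).astype(np.int32)

    # follicle: anatomy-like scene using all nine classes
    labels = np.full((r, c), 2, dtype=np.int32)          # paracortex: T cells
    cap_h = max(int(0.07 * r), 4)
    mus_h = max(int(0.05 * r), 3)
    labels[:cap_h, :] = 6                                 # capsule: connective
    labels[cap_h:cap_h + mus_h, :] = 8                    # smooth muscle band
    center = (0.56 * r, 0.50 * c)
    big_r = 0.30 * m
    gc_r = 0.62 * big_r
    follicle = _disk(rr, cc, center, big_r)
    labels[follicle] = 1                                  # mantle: naive B
    gc = _disk(rr, cc, center, gc_r)
    labels[gc & (rr < center[0])] = 4                     # light zone (upper)
    labels[gc & (rr >= center[0])] = 3                    # dark zone (lower)
    vess_r = max(0.045 * m, 3.0)
    ring = max(0.035 * m, 2.0)
    for vc in ((0.22 * r, 0.16 * c), (0.80 * r, 0.84 * c)):
        wall = _disk(rr, cc, vc, vess_r + ring)
        labels[wall] = 7                                  # fibrovascular wall
        labels[_disk(rr, cc, vc, vess_r)] = 5             # red cells in lumen
    other_r = max(0.06 * m, 3.0)
    labels[_disk(rr, cc, (0.86 * r, 0.14 * c), other_r)] = 9   # debris
    return labels


def _texture_field(rng: np.random.Generator, shape: tuple[int, int],
                   scale_px: float) -> np.ndarray:
    g = rng.standard_normal(shape)
    if scale_px > 0:
        g = ndimage.gaussian_filter(g, scale_px)
        sd = g.std()
        if sd > 0:
            g = g / sd
    return np.clip(g, -2.5, 2.5)


def generate_phantom(
    spec: PhantomSpec,
    library: dict[str, Endmember] | None = None,
) -> tuple[SpectralCube, ClassMap, RoiSet]:
    """Render a phantom scene into (cube, ground-truth map, training ROIs).

    The ground truth records the pre-blur layout labels.  ROIs sample each
    class's eroded interior (default 3-pixel erosion) so training pixels
    never touch blur-mixed boundaries, mirroring how a pathologist avoids
    ambiguous regions; a class too small to survive erosion falls back to
    its full region with a warning.
    """
    scheme = ClassScheme()
    if library is None:
        library = make_endmember_library(spec.seed)
    labels = paint_layout(spec)
    rng = np.random.default_rng(spec.seed)
    axis = spec.axis
    nb = len(axis)

    names = [scheme.classes[i] for i in range(scheme.n_classes)]
    e_full = np.stack([library[n].spectrum(axis) for n in names])
    e_nuc = np.stack([library[n].partial_spectrum(axis, _NUCLEIC) for n in names])
    e_lip = np.stack([library[n].partial_spectrum(axis, _LIPID) for n in names])
    e_rest = e_full - e_nuc - e_lip

    idx = labels - 1
    thickness = rng.lognormal(0.0, spec.thickness_sigma_log,
                              (spec.rows, spec.cols)).astype(np.float32)
    tau = spec.texture_amplitude
    g1 = _texture_field(rng, (spec.rows, spec.cols), spec.texture_scale_px)
    g2 = _texture_field(rng, (spec.rows, spec.cols), spec.texture_scale_px)

    cube = (e_rest[idx]
            + (1.0 + tau * g1)[:, :, None] * e_nuc[idx]
            + (1.0 + tau * g2)[:, :, None] * e_lip[idx]).astype(np.float32)
    cube *= thickness[:, :, None]

    if spec.blur_sigma_um > 0:
        s_px = spec.blur_sigma_um / spec.pixel_pitch
        cube = ndimage.gaussian_filter(cube, sigma=(s_px, s_px, 0.0))

    if spec.noise_sigma > 0:
        sigma = np.full(nb, spec.noise_sigma, dtype=np.float32)
        if spec.band_dependent_noise:
            # detector response falls off toward the range edges
            t = (axis.values - axis.lo) / (axis.hi - axis.lo)
            sigma = sigma * (1.0 + 0.5 * (2.0 * np.abs(t - 0.5)) ** 2).astype(np.float32)
        cube = cube + (rng.standard_normal(cube.shape).astype(np.float32)
                       * sigma[None, None, :])

    truth = ClassMap(labels, scheme, provenance={"phantom_seed": spec.seed,
                                                 "layout": spec.layout})
    rois = _rois_from_labels(labels, scheme, spec.roi_erosion)
    return (SpectralCube(cube, axis, spec.pixel_pitch), truth, rois)


def _rois_from_labels(labels: np.ndarray, scheme: ClassScheme,
                      erosion: int, image_id: str = "phantom") -> RoiSet:
    entries = []
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        region = labels == lbl
        core = (ndimage.binary_erosion(region, iterations=erosion)
                if erosion > 0 else region)
        if not core.any():
            log.warning("class %d too small for %d-pixel erosion; using full "
                        "region for its ROI", lbl, erosion)
            core = region
        coords = np.argwhere(core)
        entries.append((image_id, scheme.classes[lbl - 1], coords))
    return RoiSet(entries)


def degrade_to_lowres(cube: SpectralCube, target_pitch: float = 6.25) -> SpectralCube:
    """Simulate a conventional (coarse-pixel) acquisition of the same scene.

    Blurs each band at the coarser optical scale (Gaussian with FWHM equal
    to the target pitch) then area-average-resamples onto the target grid;
    output dims are ``floor(dim · pitch / target)``.  A no-op when the
    target equals the source pitch.
    """
    if target_pitch < cube.pixel_pitch:
        raise RangeError(
            f"target pitch {target_pitch} < source pitch {cube.pixel_pitch}")
    if np.isclose(target_pitch, cube.pixel_pitch):
        return cube
    ratio = cube.pixel_pitch / target_pitch
    out_r = int(np.floor(cube.rows * ratio))
    out_c = int(np.floor(cube.cols * ratio))
    if out_r < 1 or out_c < 1:
        raise RangeError("image too small for the requested target pitch")

    s_px = (target_pitch / cube.pixel_pitch) / 2.355   # FWHM = target pitch
    blurred = ndimage.gaussian_filter(
        cube.absorbance.astype(np.float64), sigma=(s_px, s_px, 0.0))

    map_r = np.floor(np.arange(cube.rows) * ratio).astype(int)
    map_c = np.floor(np.arange(cube.cols) * ratio).astype(int)
    keep_r = map_r < out_r
    keep_c = map_c < out_c
    sub = blurred[keep_r][:, keep_c]
    fr = map_r[keep_r]
    fc = map_c[keep_c]
    flat_idx = (fr[:, None] * out_c + fc[None, :]).ravel()
    acc = np.zeros((out_r * out_c, cube.n_bands))
    np.add.at(acc, flat_idx, sub.reshape(-1, cube.n_bands))
    counts = np.bincount(flat_idx, minlength=out_r * out_c).astype(float)
    acc /= counts[:, None]
    return cube.with_data(acc.reshape(out_r, out_c, cube.n_bands),
                          pixel_pitch=target_pitch)


def three_group_phantom(rows: int = 48, cols: int = 48, seed: int = 0,
                        noise_sigma: float = 0.0) -> tuple[SpectralCube, ClassMap, RoiSet]:
    """Convenience: a zero-blur phantom with three spatially separated
    groups of identical spectra (grid layout, 3 classes) — the canonical
    clustering sanity case."""
    spec = PhantomSpec(rows=rows, cols=cols, layout="grid",
                       n_layout_classes=3, blur_sigma_um=0.0,
                       noise_sigma=noise_sigma, texture_amplitude=0.0,
                       thickness_sigma_log=0.0, seed=seed)
    return generate_phantom(spec)
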