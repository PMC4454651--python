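"""Minimum Noise Fraction (MNF) transform for spectral noise rejection.

HD FT-IR imaging spreads the source signal over many small detector
pixels, so per-pixel spectra are noisy; MNF recovers SNR by projecting
spectra onto a noise-whitened principal-component basis and keeping only
the high-SNR leading components.

The transform solves the generalized symmetric eigenproblem

    Σ_data · w = λ · Σ_noise · w

whose eigenvalues λ order components by (signal+noise)/noise variance.
Σ_noise is estimated from shift differences between spatially adjacent
pixels — neighbouring pixels of a tissue image share signal, so their
difference is dominated by noise.  Reconstruction from the leading ``k``
components gives the denoised cube.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .core import SpectralCube
from .errors import EstimationError, RangeError

log = logging.getLogger(__name__)

__all__ = ["MnfTransform", "estimate_noise_covariance", "fit_mnf", "denoise",
           "choose_k"]


def estimate_noise_covariance(
    cube: SpectralCube,
    mask: np.ndarray | None = None,
    direction: str = "h",
) -> np.ndarray:
    """Shift-difference noise covariance estimate.

    Forms d = (x[r, c] − x[r, c+1]) / √2 over all horizontally adjacent
    pixel pairs (``direction='v'`` uses vertical pairs, ``'both'`` averages
    the two estimates) and returns the band covariance of d.  When a
    boolean ``mask`` is given, only pairs with both pixels in-mask count.
    """
    if direction not in ("h", "v", "both"):
        raise RangeError("direction must be 'h', 'v' or 'both'")
    if direction == "both":
        ch = estimate_noise_covariance(cube, mask, "h")
        cv = estimate_noise_covariance(cube, mask, "v")
        return 0.5 * (ch + cv)

    a = cube.absorbance
    if direction == "h":
        if cube.cols < 2:
            raise EstimationError("need >= 2 columns for horizontal differences")
        diffs = (a[:, :-1, :] - a[:, 1:, :]) / np.sqrt(2.0)
        pair_ok = None if mask is None else (mask[:, :-1] & mask[:, 1:])
    else:
        if cube.rows < 2:
            raise EstimationError("need >= 2 rows for vertical differences")
        diffs = (a[:-1, :, :] - a[1:, :, :]) / np.sqrt(2.0)
        pair_ok = None if mask is None else (mask[:-1, :] & mask[1:, :])

    d = diffs.reshape(-1, cube.n_bands)
    if pair_ok is not None:
        d = d[pair_ok.ravel()]
    if d.shape[0] < 2:
        raise EstimationError("no (or too few) valid adjacent pixel pairs in mask")
    cov = np.cov(d, rowvar=False)
    return 0.5 * (cov + cov.T)


@dataclass
class MnfTransform:
    """Fitted MNF eigenbasis with SNR-ordered components.

    ``forward`` maps mean-centred spectra to component scores
    (``c = forward @ (x − mean)``); ``inverse`` maps scores back
    (``x = mean + inverse @ c``).  ``eigenvalues`` are sorted descending.
    """

    noise_cov: np.ndarray
    data_cov: np.ndarray
    eigenvalues: np.ndarray
    forward: np.ndarray
    inverse: np.ndarray
    mean: np.ndarray
    k_retained: int | None = None

    @property
    def n_bands(self) -> int:
        return self.mean.size

    def save(self, path: str | Path) -> None:
        """Serialize to a portable JSON file (matrices as nested lists)."""
        payload = {
            "noise_cov": self.noise_cov.tolist(),
            "data_cov": self.data_cov.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "forward": self.forward.tolist(),
            "inverse": self.inverse.tolist(),
            "mean": self.mean.tolist(),
            "k_retained": self.k_retained,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MnfTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            noise_cov=np.array(d["noise_cov"]),
            data_cov=np.array(d["data_cov"]),
            eigenvalues=np.array(d["eigenvalues"]),
            forward=np.array(d["forward"]),
            inverse=np.array(d["inverse"]),
            mean=np.array(d["mean"]),
            k_retained=d["k_retained"],
        )


def fit_mnf(
    cube: SpectralCube,
    noise_cov: np.ndarray,
    mask: np.ndarray | None = None,
    ridge_eps: float = 1e-8,
) -> MnfTransform:
    """Fit the MNF eigenbasis from a cube and a noise covariance estimate.

    A singular (or near-singular) noise covariance is regularized by adding
    a ridge of ``ridge_eps · trace / bands`` to its diagonal (logged).  The
    eigenvector sign is fixed so the largest-magnitude loading of each
    component is positive, making repeated fits reproducible.
    """
    noise_cov = np.asarray(noise_cov, dtype=float)
    b = cube.n_bands
    if noise_cov.shape != (b, b):
        raise RangeError("noise_cov must be bands x bands")

    x = cube.flat_spectra()
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool).ravel()]
    if x.shape[0] < 2:
        raise EstimationError("need >= 2 in-mask pixels for the data covariance")
    mean = x.mean(axis=0)
    data_cov = np.cov(x, rowvar=False)
    data_cov = 0.5 * (data_cov + data_cov.T)

    ridge = ridge_eps * (np.trace(noise_cov) / b if np.trace(noise_cov) > 0 else 1.0)
    min_eig = float(np.linalg.eigvalsh(noise_cov)[0])
    if min_eig <= ridge:
        log.warning("noise covariance near-singular (min eig %.3e); "
                    "adding ridge %.3e", min_eig, ridge)
        noise_cov = noise_cov + ridge * np.eye(b)

    evals, evecs = eigh(data_cov, noise_cov)     # ascending, w' Σn w = I
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-|loading| entry positive, per component
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(b)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    forward = evecs.T
    inverse = np.linalg.inv(forward)
    return MnfTransform(noise_cov=noise_cov, data_cov=data_cov,
                        eigenvalues=evals, forward=forward, inverse=inverse,
                        mean=mean)


def choose_k(transform: MnfTransform, threshold_factor: float = 1.5) -> int:
    """Automatic component count: largest k whose eigenvalue exceeds
    ``threshold_factor`` × the median eigenvalue (at least 1).

    The retained-k choice materially affects downstream results, so callers
    should log or report it prominently.
    """
    med = float(np.median(transform.eigenvalues))
    k = int(np.sum(transform.eigenvalues > threshold_factor * med))
    return max(k, 1)


def denoise(cube: SpectralCube, transform: MnfTransform, k: int) -> SpectralCube:
    """Reconstruct the cube from the leading ``k`` MNF components.

    Forward-transform every pixel (masked pixels included — exclusion from
    fitting does not preclude reconstruction), zero all components beyond
    ``k``, inverse-transform, and re-add the mean spectrum.
    """
    b = cube.n_bands
    if not 1 <= k <= b:
        raise RangeError(f"k must be in [1, {b}], got {k}")
    x = cube.flat_spectra()
    scores = (x - transform.mean) @ transform.forward[:k].T
    recon = scores @ transform.inverse[:, :k].T + transform.mean
    denoised = recon.reshape(cube.shape)
    transform.k_retained = k
    return cube.with_data(denoised)
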