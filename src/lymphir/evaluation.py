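"""Phantom-based evaluation protocols.

These helpers run the full analysis chain on phantoms with known ground
truth and score it.  Held-out classification accuracy uses a spatially
blocked split: the image is tiled into blocks and whole blocks are held
out, so test pixels are never spatial neighbours of training pixels
(per-pixel random splits would be optimistically biased by spatial
autocorrelation).  Accuracy is evaluated on ROI pixels — eroded class
interiors — of the held-out blocks: boundary pixels are physically mixed
by optical blur and have no single true class, so including them would
measure blur geometry rather than classifier quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import (assemble_training_set, predict_labels,
                         spatial_block_split, train_forest)
from .features import extract_features, tissue_mask
from .mnf import choose_k, denoise, estimate_noise_covariance, fit_mnf
from .synthetic import PhantomSpec, generate_phantom

log = logging.getLogger(__name__)

__all__ = ["HoldoutResult", "phantom_holdout_evaluation",
           "mnf_denoising_replicates"]


#: A blocked split only yields a usable evaluation when every class has at
#: least this many ROI pixels on each side; degenerate draws are redrawn.
MIN_CLASS_PIXELS = 30


def _stratified_block_split(rr, cc, labels, rows, cols, block,
                            test_fraction, split_seed, max_attempts=50):
    """Blocked split redrawn (deterministically) until every class appears
    with at least :data:`MIN_CLASS_PIXELS` ROI pixels in both train and
    test blocks — a draw that holds out none of a class cannot measure
    that class's confusion at all."""
    classes = np.unique(labels)
    full = MIN_CLASS_PIXELS * classes.size
    best, best_score = None, -1
    for attempt in range(max_attempts):
        test_map = spatial_block_split(rows, cols, block, test_fraction,
                                       split_seed + attempt)
        in_test = test_map[rr, cc]
        # per-class two-sided coverage, each capped at the target
        score = sum(
            min(MIN_CLASS_PIXELS,
                int(np.sum(in_test & (labels == lbl))),
                int(np.sum(~in_test & (labels == lbl))))
            for lbl in classes)
        if score >= full:
            if attempt:
                log.info("blocked split redrawn %d time(s) to cover every "
                         "class", attempt)
            return in_test
        if score > best_score:
            best, best_score = in_test, score
    # tiny classes can occupy a single block and are then unsplittable;
    # fall back to the draw with the best overall class coverage
    log.warning("no blocked split reached %d pixels per class per side in "
                "%d draws; using best draw (coverage %d/%d)",
                MIN_CLASS_PIXELS, max_attempts, best_score, full)
    return best


@dataclass
class HoldoutResult:
    """Outcome of one blocked-split phantom classification run."""

    accuracy: float
    confusion: np.ndarray          # 9x9, rows = truth, cols = predicted
    most_confused_pair: tuple[int, int]   # 1-based labels, unordered (i < j)
    n_test: int
    mnf_k: int
    oob_accuracy: float


def phantom_holdout_evaluation(
    rows: int = 256,
    cols: int = 256,
    seed: int = 7,
    noise_sigma: float = 0.01,
    n_trees: int = 40,
    block: int = 32,
    test_fraction: float = 0.25,
    split_seed: int = 123,
    train_seed: int = 42,
    use_mnf: bool = True,
) -> HoldoutResult:
    """Generate a follicle phantom, run the chain, score the held-out blocks.

    Chain: phantom → tissue mask → MNF denoise (automatic rank) → 11-metric
    features → 40-tree forest trained on ROI pixels of the training blocks →
    accuracy and confusion matrix on ROI pixels of the held-out blocks.
    """
    spec = PhantomSpec(rows=rows, cols=cols, seed=seed,
                       noise_sigma=noise_sigma)
    cube, _truth, rois = generate_phantom(spec)
    mask = tissue_mask(cube)
    k = 0
    if use_mnf:
        ncov = estimate_noise_covariance(cube, mask)
        transform = fit_mnf(cube, ncov, mask)
        k = choose_k(transform)
        cube = denoise(cube, transform, k)
    feats = extract_features(cube, None, mask)

    table = assemble_training_set({"phantom": feats}, rois)
    rr = table["row"].to_numpy(int)
    cc = table["col"].to_numpy(int)
    labels = table["label"].to_numpy(int)
    in_test = _stratified_block_split(rr, cc, labels, rows, cols, block,
                                      test_fraction, split_seed)
    model = train_forest(table[~in_test], n_trees, train_seed,
                         feature_names=feats.metric_names)

    x_test = table.loc[in_test, feats.metric_names].to_numpy(float)
    y_test = table.loc[in_test, "label"].to_numpy(int)
    y_hat = predict_labels(model, x_test)
    accuracy = float((y_hat == y_test).mean())

    n = model.scheme.n_classes
    confusion = np.zeros((n, n), dtype=int)
    np.add.at(confusion, (y_test - 1, y_hat - 1), 1)
    off = confusion - np.diag(np.diag(confusion))
    pair_errors = np.triu(off + off.T, 1)
    i, j = np.unravel_index(int(np.argmax(pair_errors)), pair_errors.shape)
    log.info("holdout accuracy %.4f (n=%d, MNF k=%d); most-confused pair "
             "(%d, %d) with %d errors", accuracy, y_test.size, k,
             i + 1, j + 1, int(pair_errors[i, j]))
    return HoldoutResult(accuracy=accuracy, confusion=confusion,
                         most_confused_pair=(i + 1, j + 1),
                         n_test=int(y_test.size), mnf_k=k,
                         oob_accuracy=model.oob_accuracy)


def mnf_denoising_replicates(
    n_replicates: int = 100,
    seed: int = 0,
    shape: tuple[int, int, int] = (24, 24, 60),
    rank: int = 5,
    noise_sigma: float = 0.05,
    signal_amplitude: float = 0.25,
    smooth_sigma: float = 3.0,
) -> int:
    """Count replicates where rank-k MNF reconstruction beats the noisy cube.

    Each replicate builds a rank-``rank`` clean cube — spatially smooth
    score maps times random spectral loadings, as in real tissue where
    neighbouring pixels share composition — plus i.i.d. Gaussian noise,
    fits MNF from the noisy cube's own shift-difference noise estimate,
    reconstructs at k = ``rank``, and checks
    MSE(clean, denoised) < MSE(clean, noisy).  Returns the success count.
    """
    from scipy import ndimage

    from .core import SpectralCube, WavenumberAxis

    r, c, b = shape
    axis = WavenumberAxis.from_range(1000.0, 1000.0 + 4.0 * (b - 1), 4.0)
    root = np.random.SeedSequence(seed)
    wins = 0
    for child in root.spawn(n_replicates):
        rng = np.random.default_rng(child)
        scores = ndimage.gaussian_filter(
            rng.normal(size=(r, c, rank)), (smooth_sigma, smooth_sigma, 0.0))
        scores /= scores.std(axis=(0, 1), keepdims=True)
        basis = rng.normal(size=(rank, b))
        clean = signal_amplitude * (scores.reshape(r * c, rank) @ basis)
        clean = clean.reshape(r, c, b)
        noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
        cube = SpectralCube(noisy, axis, 1.1)
        transform = fit_mnf(cube, estimate_noise_covariance(cube))
        recon = denoise(cube, transform, rank).absorbance
        if np.mean((recon - clean) ** 2) < np.mean((noisy - clean) ** 2):
            wins += 1
    return wins
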