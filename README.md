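# lymphir

Per-pixel tissue classification for high-definition (HD) FT-IR
spectroscopic images of lymph nodes.

## The problem

Mid-infrared spectroscopic imaging records an absorption spectrum
A(ν) — a chemical "fingerprint" — at every pixel of an unstained tissue
section. Conventional instruments image at 5.5–6.25 μm/pixel, about the
diameter of a lymphocyte, so spectra average over whole cells and the
dense, heterogeneous architecture of a lymph node (follicles, germinal
centers, paracortex, vessels) blurs away. HD optics bring the pixel
pitch down to ~1.1 μm (a 140 μm × 140 μm field mapped onto a 128 × 128
focal-plane array: 140/128 = 1.09375 μm/pixel), resolving individual
lymphocytes — at the price of lower per-pixel signal-to-noise and of
spectra that now sample *subcellular* domains.

`lymphir` implements the full analysis chain this regime needs, for
spectroscopists and computational pathologists:

1. **ENVI I/O and mosaicking** (`lymphir.envi_io`) — header+binary
   cubes in BSQ/BIL/BIP, per-tile acquisitions abutted into a mosaic
   with an explicit validity mask.
2. **Preprocessing** (`lymphir.preprocess`) — absorbance ratioing
   A = −log₁₀(S/B), truncation to 900–3800 cm⁻¹, two-point linear
   baselines, Savitzky–Golay second derivatives (13-point window),
   vector normalisation, pixel binning.
3. **MNF denoising** (`lymphir.mnf`) — the Minimum Noise Fraction
   transform: solve Σ_data·w = λ·Σ_noise·w with Σ_noise estimated from
   adjacent-pixel shift differences, order components by SNR, and
   reconstruct from the leading k.
4. **Spectral-metric features and tissue mask** (`lymphir.features`) —
   pixels with A(1654 cm⁻¹) > 0.2 AU count as tissue; each tissue pixel
   is reduced to 11 baseline-corrected peak heights, band areas, ratios
   and a centroid over 980–3000 cm⁻¹ (fully configurable).
5. **Nine-class random forest** (`lymphir.classifier`) — naïve/memory
   B, T cell, dark- and light-zone activated B, red blood cells,
   connective tissue, fibrovascular network, smooth muscle, "other";
   40 trees, per-tree majority vote, deterministic tie-breaks, trained
   from ROI files with a documented run-length grammar.
6. **HCA comparison arm** (`lymphir.hca`) — agglomerative clustering
   over 940–1265 cm⁻¹ with Euclidean or correlation-based "D-values"
   distance, plus a pixel-binning study.
7. **Phantoms** (`lymphir.synthetic`) — seedable lymph-node scenes
   with known ground truth: per-class endmember spectra built from
   Gaussian bands at standard tissue wavenumbers, follicle-like
   layouts, thickness variation, subcellular texture, optical blur and
   noise. All validation runs on these phantoms.
8. **Pipeline** (`lymphir.pipeline`, `lymphir` CLI) — one YAML config
   drives simulate → mask → MNF → features → train/classify → HCA with
   a provenance manifest and byte-reproducible outputs.

## Worked example

```python
from lymphir import phantom_holdout_evaluation

res = phantom_holdout_evaluation(rows=128, cols=128, seed=7,
                                 noise_sigma=0.01, block=16)
print(res.mnf_k, res.oob_accuracy, res.accuracy, res.most_confused_pair)
```

prints (via `python examples/01_phantom_and_classify.py`):

```
MNF components retained:   10
Out-of-bag accuracy:       0.9922
Held-out accuracy:         0.9971  (3476 test pixels)
Most-confused class pair:  1 vs 4
```

i.e. the MNF scree kept 10 of 726 components, and the 40-tree forest
recovered the phantom's tissue classes on spatially held-out blocks
with 99.7 % per-pixel accuracy. At 5× the default noise the dominant
confusions appear between the light-zone and dark-zone activated-B
classes — the subtlest spectral distinction, since those endmembers
differ only in nucleic-acid band amplitudes. The `examples/` directory
holds one short script per capability (I/O and mosaicking, MNF, HCA
binning study, full pipeline).

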