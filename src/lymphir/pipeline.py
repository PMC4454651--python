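"""End-to-end pipeline orchestration with provenance.

One plain-text (YAML) config drives the whole chain:

    simulate/ingest → truncate → tissue mask → MNF denoise → metric
    features → train forest → classify → (optional) HCA → report

Every intermediate artifact lands in a run directory together with a
machine-readable manifest (seeds, config hash, chosen MNF rank, timings)
so any reported number can be recomputed from stored intermediates.  A
single global seed fans out into independent per-stage seeds through a
splittable scheme, so re-running one stage reproduces its result exactly.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envi_io, mnf as mnf_mod
from .classifier import (ClassMap, ClassScheme, assemble_training_set,
                         classify_image, predict_labels, render_classmap,
                         spatial_block_split, train_forest, write_roi_file)
from .errors import ConfigurationError
from .features import (default_metrics, extract_features, metrics_from_config,
                       tissue_mask)
from .hca import HcaConfig, run_hca
from .preprocess import truncate
from .synthetic import PhantomSpec, generate_phantom

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

_KNOWN_SECTIONS = {"seed", "out_dir", "stages", "input", "preprocess", "mnf",
                   "mask", "features", "classify", "hca"}
_SECTION_KEYS = {
    "input": {"kind", "header", "rows", "cols", "layout", "noise_sigma",
              "blur_sigma_um", "texture_amplitude", "thickness_sigma_log",
              "n_layout_classes", "pixel_pitch", "roi_erosion"},
    "preprocess": {"truncate"},
    "mnf": {"enabled", "k", "noise_shift", "threshold_factor"},
    "mask": {"threshold", "band"},
    "features": {"metrics"},
    "classify": {"n_trees", "test_fraction", "block"},
    "hca": {"enabled", "range", "distance", "n_clusters", "binning",
            "linkage"},
}
_DEFAULTS = {
    "seed": 0,
    "out_dir": "lymphir_run",
    "input": {"kind": "phantom", "rows": 256, "cols": 256,
              "layout": "follicle"},
    "preprocess": {"truncate": [900.0, 3800.0]},
    "mnf": {"enabled": True, "k": "auto", "noise_shift": "h",
            "threshold_factor": 1.5},
    "mask": {"threshold": 0.2, "band": 1654.0},
    "features": {"metrics": "default"},
    "classify": {"n_trees": 40, "test_fraction": 0.25, "block": 32},
    "hca": {"enabled": False, "range": [940.0, 1265.0],
            "distance": "euclidean", "n_clusters": 10, "binning": 2,
            "linkage": None},
}


class PipelineConfig:
    """Validated pipeline configuration; defaults mirror the stated
    acquisition/analysis settings (truncate 900–3800 cm⁻¹; mask 0.2 AU at
    1654 cm⁻¹; 11 default metrics over 980–3000; 40 trees; HCA over
    940–1265 with 10 clusters)."""

    def __init__(self, raw: dict | None = None) -> None:
        raw = dict(raw or {})
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        self.data: dict = {}
        for key, default in _DEFAULTS.items():
            if isinstance(default, dict):
                section = dict(default)
                given = raw.get(key, {})
                if not isinstance(given, dict):
                    raise ConfigurationError(f"section '{key}' must be a map")
                bad = set(given) - _SECTION_KEYS[key]
                if bad:
                    raise ConfigurationError(
                        f"unknown keys in '{key}': {sorted(bad)}")
                section.update(given)
                self.data[key] = section
            else:
                self.data[key] = raw.get(key, default)
        self._validate()

    def _validate(self) -> None:
        lo, hi = self.data["preprocess"]["truncate"]
        band = self.data["mask"]["band"]
        if not lo <= band <= hi:
            raise ConfigurationError(
                f"mask band {band} cm^-1 outside the truncation range "
                f"[{lo}, {hi}]")
        if self.data["input"]["kind"] not in ("phantom", "envi"):
            raise ConfigurationError("input.kind must be phantom or envi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        """Splittable per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([int(self.data["seed"]),
                                     zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    @property
    def config_hash(self) -> str:
        import hashlib
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()).hexdigest()[:16]


def _load_input(config: PipelineConfig, out: Path):
    sec = config.data["input"]
    if sec["kind"] == "envi":
        cube = envi_io.read_envi(sec["header"])
        return cube, None, None
    spec_kwargs = {k: v for k, v in sec.items() if k != "kind"}
    spec = PhantomSpec(seed=config.stage_seed("simulate"), **spec_kwargs)
    cube, truth, rois = generate_phantom(spec)
    truth.save_grid(out / "truth.labels.txt")
    write_roi_file(rois, out / "rois.txt")
    return cube, truth, rois


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Re-running with an identical config (including the seed) reproduces
    identical outputs.  A stage failure aborts with the stage name; partial
    outputs are retained and flagged in the manifest.
    """
    out = Path(out_dir if out_dir is not None else config.data["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.data, "config_hash": config.config_hash,
                      "stages_completed": [], "numbers": {}}
    stage = "input"
    try:
        cube, truth, rois = _load_input(config, out)
        manifest["stages_completed"].append(stage)

        stage = "preprocess"
        lo, hi = config.data["preprocess"]["truncate"]
        cube = truncate(cube, lo, hi)
        manifest["stages_completed"].append(stage)

        stage = "mask"
        msec = config.data["mask"]
        mask = tissue_mask(cube, msec["threshold"], msec["band"])
        np.savetxt(out / "mask.txt", mask.astype(int), fmt="%d")
        manifest["numbers"]["in_mask_pixels"] = int(mask.sum())
        manifest["stages_completed"].append(stage)

        stage = "mnf"
        nsec = config.data["mnf"]
        if nsec["enabled"]:
            ncov = mnf_mod.estimate_noise_covariance(cube, mask,
                                                     nsec["noise_shift"])
            transform = mnf_mod.fit_mnf(cube, ncov, mask)
            k = (mnf_mod.choose_k(transform, nsec["threshold_factor"])
                 if nsec["k"] == "auto" else int(nsec["k"]))
            log.info("MNF retaining k=%d of %d components", k, cube.n_bands)
            cube = mnf_mod.denoise(cube, transform, k)
            pd.DataFrame({"component": np.arange(1, len(transform.eigenvalues) + 1),
                          "eigenvalue": transform.eigenvalues}).to_csv(
                out / "mnf_scree.csv", index=False)
            manifest["numbers"]["mnf_k"] = k
        manifest["stages_completed"].append(stage)

        stage = "features"
        fsec = config.data["features"]
        metrics = (default_metrics() if fsec["metrics"] == "default"
                   else metrics_from_config(fsec["metrics"]))
        feats = extract_features(cube, metrics, mask)
        feats.save_csv(out / "features.csv")
        manifest["stages_completed"].append(stage)

        stage = "classify"
        if rois is not None:
            csec = config.data["classify"]
            scheme = ClassScheme()
            test_map = spatial_block_split(
                cube.rows, cube.cols, csec["block"], csec["test_fraction"],
                config.stage_seed("split"))
            table = assemble_training_set({"phantom": feats}, rois, scheme)
            rr = table["row"].to_numpy(int)
            cc = table["col"].to_numpy(int)
            in_test = test_map[rr, cc]
            model = train_forest(table[~in_test], csec["n_trees"],
                                 config.stage_seed("train"), scheme,
                                 feats.metric_names)
            cmap = classify_image(feats, model)
            render_classmap(cmap, out / "classmap.png")
            model.save(out / "model.joblib")

            x_test = table.loc[in_test, feats.metric_names].to_numpy(float)
            y_test = table.loc[in_test, "label"].to_numpy(int)
            if y_test.size:
                y_hat = predict_labels(model, x_test)
                acc = float((y_hat == y_test).mean())
                n = scheme.n_classes
                conf = np.zeros((n, n), dtype=int)
                np.add.at(conf, (y_test - 1, y_hat - 1), 1)
                pd.DataFrame(conf, index=list(scheme.classes),
                             columns=list(scheme.classes)).to_csv(
                    out / "confusion.csv")
                manifest["numbers"]["holdout_accuracy"] = acc
                manifest["numbers"]["holdout_pixels"] = int(y_test.size)
                manifest["numbers"]["oob_accuracy"] = model.oob_accuracy
        manifest["stages_completed"].append(stage)

        stage = "hca"
        hsec = config.data["hca"]
        if hsec["enabled"]:
            hcfg = HcaConfig(range=tuple(hsec["range"]),
                             distance=hsec["distance"],
                             n_clusters=hsec["n_clusters"],
                             binning=hsec["binning"],
                             linkage=hsec["linkage"])
            hmap = run_hca(cube, hcfg, mask)
            hmap.save_grid(out / "hca.labels.txt")
            if truth is not None and hcfg.binning == 1:
                from sklearn.metrics import adjusted_rand_score
                use = hmap.labels > 0
                manifest["numbers"]["hca_ari"] = float(adjusted_rand_score(
                    truth.labels[use], hmap.labels[use]))
        manifest["stages_completed"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("pipeline aborted in stage '%s'; partial outputs retained "
                  "in %s", stage, out)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir: str | Path) -> dict:
    """Summarise a completed run from its stored intermediates.

    Returns a dict with per-class pixel counts, held-out accuracy and
    confusion matrix (phantom runs), the MNF eigenvalue scree and any HCA
    agreement score; missing intermediates yield explicit ``None`` gaps.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    summary: dict = {"config_hash": manifest["config_hash"],
                     "numbers": manifest.get("numbers", {}),
                     "stages_completed": manifest["stages_completed"]}

    labels_file = run_dir / "classmap.labels.txt"
    if labels_file.exists():
        cmap = ClassMap.load_grid(labels_file)
        summary["class_counts"] = cmap.class_counts()
        summary["background_pixels"] = int((cmap.labels == 0).sum())
    else:
        summary["class_counts"] = None

    conf_file = run_dir / "confusion.csv"
    summary["confusion"] = (pd.read_csv(conf_file, index_col=0).to_dict()
                            if conf_file.exists() else None)
    scree_file = run_dir / "mnf_scree.csv"
    summary["mnf_eigenvalues"] = (
        pd.read_csv(scree_file)["eigenvalue"].tolist()
        if scree_file.exists() else None)
    return summary
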