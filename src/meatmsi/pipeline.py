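"""End-to-end orchestration: simulate -> segment -> featurize -> regress.

A run directory receives per-stage artifacts (``cubes/ masks/ features/
models/ reports/``) plus a manifest recording the seeds, a hash of the
configuration and the package version, so identical configurations
reproduce every numeric output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .chemometrics import grid_search, split_data, summarize_targets
from .cube_io import mean_spectrum, write_cube, write_spectrum_csv
from .morphometry import (FEATURE_NAMES, assemble_feature_cube,
                          features_for_sample)
from .segmentation import SegmentationParams, segment_imct
from .synthetic import (GROUND_TRUTH_COLUMNS, SceneParams, generate_dataset,
                        write_target_table)

log = logging.getLogger("meatmsi")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str
    n_samples: int = 20
    seed: int = 0
    scene: dict = field(default_factory=dict)
    param_ranges: dict | None = None
    segmentation: dict = field(default_factory=dict)
    features: tuple[str, ...] = ("orientation",)
    bin_counts: tuple[int, ...] = (300,)
    targets: tuple[str, ...] = GROUND_TRUTH_COLUMNS
    n_lv: int = 10
    grid: tuple[int, int] = (2, 8)
    max_epochs: int = 1000
    strict: bool = False
    save_cubes: bool = False
    save_masks: bool = False
    save_feature_table: bool = True

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.bin_counts = tuple(int(b) for b in self.bin_counts)
        self.targets = tuple(self.targets)
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
        unknown = set(self.targets) - set(GROUND_TRUTH_COLUMNS)
        if unknown:
            raise ValueError(f"unknown target name(s): {sorted(unknown)}")
        if any(b < 1 for b in self.bin_counts):
            raise ValueError("bin counts must be >= 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 for a three-way split")
        # fail fast on invalid nested blocks, before any compute
        self.scene_params()
        self.segmentation_params()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def scene_params(self) -> SceneParams:
        return SceneParams(**self.scene)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.output_dir)
    for sub in ("cubes", "masks", "features", "models", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # -- stage 1: simulation -------------------------------------------
    log.info("simulate: %d scenes", config.n_samples)
    scenes, targets = generate_dataset(
        config.n_samples, config.param_ranges, seed=config.seed,
        base_params=config.scene_params())
    write_target_table(targets, out / "features" / "targets.csv")

    # -- stage 2+3: segmentation and object features -------------------
    seg_params = config.segmentation_params()
    tables = []
    spectra_sum = None
    wavelengths = None
    for i in range(len(scenes)):
        try:
            cube, truth, masks = scenes.scene(i)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage simulate failed on sample {i}: {exc}"
                               ) from exc
        if config.save_cubes:
            write_cube(cube, out / "cubes" / f"sample_{i:04d}.tif")
        if config.save_masks:
            for name, m in masks.items():
                tifffile.imwrite(
                    out / "masks" / f"sample_{i:04d}_{name}.tif",
                    m.astype(np.uint8))
        try:
            labeled = segment_imct(cube, seg_params)
        except Exception as exc:
            raise RuntimeError(f"stage segment failed on sample {i}: {exc}"
                               ) from exc
        table = features_for_sample(labeled, sample_id=i,
                                    features=tuple(config.features))
        if table.empty:
            warnings_log.append(f"sample {i}: no objects segmented")
        tables.append(table)
        spec = mean_spectrum(cube)
        spectra_sum = spec if spectra_sum is None else spectra_sum + spec
        wavelengths = cube.wavelengths
        log.info("segment+features: sample %d/%d done", i + 1, len(scenes))
    objects = pd.concat(tables, ignore_index=True)
    if config.save_feature_table:
        objects.to_csv(out / "features" / "objects.csv", index=False)
    write_spectrum_csv(wavelengths,
                       spectra_sum / spectra_sum.sum(),
                       out / "reports" / "mean_spectrum.csv")

    # -- stage 4: histogram cubes --------------------------------------
    n_bands = config.scene_params().n_bands
    sample_ids = list(range(config.n_samples))
    cubes = [
        assemble_feature_cube(objects, feature, b, n_bands=n_bands,
                              sample_ids=sample_ids)
        for feature in config.features for b in config.bin_counts
    ]

    # -- stage 5: regression -------------------------------------------
    split = split_data(config.n_samples, seed=config.seed)
    lo, hi = config.grid
    grid = tuple((a, b) for a in range(lo, hi + 1)
                 for b in range(lo, hi + 1))
    reports = []
    for target in config.targets:
        y = targets[target].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings_log.append(f"target {target}: zero variance, skipped")
            continue
        log.info("train: target %s", target)
        rep = grid_search(cubes, y, split, grid=grid, n_lv=config.n_lv,
                          seed=config.seed, max_epochs=config.max_epochs,
                          strict=config.strict, target=target)
        reports.append(rep.as_dict())

    summary = summarize_targets(targets[list(config.targets)])
    (out / "reports" / "regression_report.json").write_text(
        json.dumps(reports, indent=1, sort_keys=True))
    (out / "reports" / "dataset_summary.json").write_text(
        json.dumps(summary.as_dict(), indent=1, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(
            config.to_canonical_json().encode()).hexdigest(),
        "master_seed": config.seed,
        "split_seed": config.seed,
        "n_samples": config.n_samples,
        "warnings": warnings_log,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out
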