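"""The packaged parameter-recovery study.

Runs the whole pipeline on a 240-scene synthetic dataset — scene
simulation, per-band IMCT segmentation, orientation histograms at 900 size
classes, PLS compression to 10 latent variables and the grid-searched
two-hidden-layer network — and reports the held-out test R² per target.

Scenes are simulated at 320 x 392 px (the acquisition aspect ratio at
roughly a third of the full pixel count, with the fiber count scaled with
image area); this keeps the full 240-sample study a few minutes on one
CPU while leaving every other condition (19 bands, noise SD 0.01,
default parameter ranges, 70/15/15 split, hidden-layer grid 2..8) at its
default.
"""

from __future__ import annotations

import logging

import pandas as pd

from .chemometrics import DEFAULT_GRID, RegressionReport, grid_search, \
    split_data
from .morphometry import assemble_feature_cube, features_for_sample
from .segmentation import SegmentationParams, segment_imct
from .synthetic import DEFAULT_PARAM_RANGES, SceneParams, generate_dataset

log = logging.getLogger("meatmsi")

#: Reduced-scale scene of the packaged study (full frame is 575 x 700).
STUDY_HEIGHT = 320
STUDY_WIDTH = 392
_AREA_RATIO = (STUDY_HEIGHT * STUDY_WIDTH) / (575 * 700)


def study_scene_params() -> SceneParams:
    return SceneParams(image_height=STUDY_HEIGHT, image_width=STUDY_WIDTH,
                       n_fibers=max(10, int(350 * _AREA_RATIO)))


def study_param_ranges() -> dict[str, tuple[float, float]]:
    ranges = dict(DEFAULT_PARAM_RANGES)
    lo, hi = ranges["n_fibers"]
    ranges["n_fibers"] = (lo * _AREA_RATIO, hi * _AREA_RATIO)
    return ranges


def run_recovery_study(seed: int = 42, n_samples: int = 240,
                       n_bins: int = 900,
                       feature: str = "orientation",
                       targets: tuple[str, ...] = ("imf",
                                                   "perimysium_area"),
                       grid: tuple[tuple[int, int], ...] = DEFAULT_GRID,
                       strict: bool = False
                       ) -> dict[str, RegressionReport]:
    """Full-pipeline parameter recovery on synthetic scenes.

    Returns one :class:`RegressionReport` per requested target.  All
    randomness (scene draws, data split, network initializations) derives
    from ``seed``.
    """
    base = study_scene_params()
    scenes, table = generate_dataset(n_samples, study_param_ranges(),
                                     seed=seed, base_params=base)
    seg_params = SegmentationParams()
    tables = []
    for i in range(n_samples):
        cube = scenes[i]
        labeled = segment_imct(cube, seg_params)
        tables.append(features_for_sample(labeled, sample_id=i,
                                          features=(feature,)))
        if (i + 1) % 20 == 0:
            log.info("segmented %d/%d scenes", i + 1, n_samples)
    objects = pd.concat(tables, ignore_index=True)
    cube900 = assemble_feature_cube(objects, feature, n_bins,
                                    n_bands=base.n_bands,
                                    sample_ids=list(range(n_samples)))
    split = split_data(n_samples, seed=seed)
    reports: dict[str, RegressionReport] = {}
    for target in targets:
        y = table[target].to_numpy(dtype=float)
        reports[target] = grid_search([cube900], y, split, grid=grid,
                                      seed=seed, strict=strict,
                                      target=target)
        log.info("%s: R2P=%.4f RMSEP=%.4f", target,
                 reports[target].r2p, reports[target].rmsep)
    return reports
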