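"""Synthetic multispectral meat scenes with exact ground truth.

A scene emulates a cross-cut beef-muscle surface imaged at 19 LED
wavelengths (405--1050 nm): lean muscle, an intramuscular connective-tissue
(IMCT) network made of thick perimysium strands and a fine endomysium
tessellation around individual fiber cells, and marbling fat deposited along
the perimysium.  Each pixel is a pure-tissue reflectance spectrum plus
additive Gaussian noise, so every geometric target (areas, lengths, widths,
fiber density) is known exactly from the generating masks and every
biochemical target (intramuscular fat, total/insoluble collagen) is an
affine function of the generating parameters.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage.morphology import disk, skeletonize

from .cube_io import MultispectralCube

#: VideometerLab-style LED wavelengths (nm), ascending, spanning 405-1050.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (
    405, 435, 450, 470, 505, 525, 570, 590, 630, 645,
    660, 700, 850, 870, 890, 910, 940, 970, 1050,
)

# Biochemical target ranges (dataset Min-Max the affine maps reproduce).
IMF_RANGE = (3.61, 22.82)            # g / 100 g dry matter
TOTAL_COLLAGEN_RANGE = (2.94, 10.45)  # mg OH-prolin / g dry matter
INSOLUBLE_COLLAGEN_RANGE = (2.01, 6.87)

# Generating-parameter ranges the affine maps are calibrated against:
# fat_fraction 0 -> imf minimum, FAT_FRACTION_CAL_MAX -> imf maximum, and
# likewise perimysium_density for the two collagen contents.
FAT_FRACTION_CAL_MAX = 0.25
DENSITY_CAL_MAX = 1.6

GROUND_TRUTH_COLUMNS = (
    "perimysium_area", "perimysium_length", "perimysium_width",
    "endomysium_area", "endomysium_length", "endomysium_width",
    "fiber_density", "imf", "total_collagen", "insoluble_collagen",
)

GROUND_TRUTH_UNITS = {
    "perimysium_area": "% of the total image area",
    "perimysium_length": "mm x mm^-2 of the image",
    "perimysium_width": "um",
    "endomysium_area": "% of the total image area",
    "endomysium_length": "mm x mm^-2 of the image",
    "endomysium_width": "um",
    "fiber_density": "number mm^-2",
    "imf": "g x 100 g^-1 DM",
    "total_collagen": "mg OH-Prol x g^-1 DM",
    "insoluble_collagen": "mg OH-Prol x g^-1 DM",
}


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    ``pixel_size`` defaults to 86 um/px (a 6 x 5 cm sample imaged onto
    700 x 575 px).  ``perimysium_density`` scales the number of random
    branching strands; ``n_fibers`` seeds the endomysium tessellation;
    ``fat_fraction`` is the target marbling area fraction.
    """

    image_height: int = 575
    image_width: int = 700
    n_bands: int = 19
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    pixel_size: float = 86.0
    perimysium_density: float = 1.0
    perimysium_width_px: int = 5
    n_fibers: int = 350
    fat_fraction: float = 0.08
    noise_sd: float = 0.01
    illumination_gradient: float = 0.0
    endomysium_opacity: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_bands <= 0:
            raise ValueError("n_bands must be positive")
        if len(self.wavelengths) != self.n_bands:
            raise ValueError(
                f"wavelengths has {len(self.wavelengths)} entries, "
                f"expected n_bands={self.n_bands}"
            )
        wl = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not 0.0 <= self.fat_fraction < 1.0:
            raise ValueError("fat_fraction must be in [0, 1)")
        if self.perimysium_density < 0:
            raise ValueError("perimysium_density must be >= 0")
        if self.perimysium_width_px < 1:
            raise ValueError("perimysium_width_px must be >= 1")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.endomysium_opacity <= 1.0:
            raise ValueError("endomysium_opacity must be in [0, 1]")
        mean_cell_area = self.image_height * self.image_width / self.n_fibers
        if mean_cell_area < 4:
            raise ValueError(
                f"n_fibers={self.n_fibers} gives mean cell area "
                f"{mean_cell_area:.2f} px < 4 px (degenerate tessellation)"
            )


@dataclass(frozen=True)
class SceneGroundTruth:
    """The ten per-sample target parameters, known exactly for a scene."""

    perimysium_area: float       # % of image area
    perimysium_length: float     # mm per mm^2 of image
    perimysium_width: float      # um
    endomysium_area: float       # % of image area
    endomysium_length: float     # mm per mm^2 of image
    endomysium_width: float      # um
    fiber_density: float         # fibers per mm^2
    imf: float                   # g / 100 g DM
    total_collagen: float        # mg OH-Prol / g DM
    insoluble_collagen: float    # mg OH-Prol / g DM

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TissueSpectra:
    """Per-band reflectance of the three pure tissues."""

    lean: np.ndarray
    connective: np.ndarray
    fat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lean", "connective", "fat"):
            s = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, s)
            if s.ndim != 1:
                raise ValueError(f"{name} spectrum must be 1-D")
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError(f"{name} reflectance must lie in [0, 1]")
        if not (len(self.lean) == len(self.connective) == len(self.fat)):
            raise ValueError("tissue spectra must share one band count")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_tissue_spectra(wavelengths: Sequence[float]) -> TissueSpectra:
    """Smooth reflectance models of lean muscle, collagenous IMCT and fat.

    Lean muscle is dark in the visible (myoglobin absorption) with a small
    reflectance maximum near 500 nm, bright in the NIR with a maximum near
    850 nm and a water dip near 970 nm.  Connective tissue is whitish and
    brighter across the visible.  Marbling fat is near-white in the visible
    (strong contrast against lean) but close to lean in the NIR apart from
    the CH-related dip near 930 nm, so fat/lean contrast varies strongly
    with wavelength.
    """
    wl = np.asarray(wavelengths, dtype=float)
    lean = (
        0.12
        + 0.10 * _gauss(wl, 500.0, 40.0)
        + 0.55 * _gauss(wl, 850.0, 150.0)
        - 0.08 * _gauss(wl, 970.0, 40.0)
    )
    connective = (
        0.34
        + 0.08 * _gauss(wl, 500.0, 45.0)
        + 0.46 * _gauss(wl, 880.0, 160.0)
        - 0.05 * _gauss(wl, 970.0, 40.0)
    )
    fat = (
        0.66
        - 0.06 * _gauss(wl, 930.0, 80.0)
        + 0.04 * _gauss(wl, 560.0, 120.0)
    )
    return TissueSpectra(lean=np.clip(lean, 0, 1),
                         connective=np.clip(connective, 0, 1),
                         fat=np.clip(fat, 0, 1))


def _perimysium_skeleton(h: int, w: int, density: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Rasterize a random branching polyline network (1 px wide).

    Strand count scales with ``density``; strands are drawn sequentially
    from one stream, so raising density with the same seed only appends
    strands (the earlier network is unchanged).
    """
    skel = np.zeros((h, w), dtype=bool)
    n_strands = int(round(density * 6))
    scale = max(h, w)
    for _ in range(n_strands):
        stack = [(rng.uniform(0, h), rng.uniform(0, w),
                  rng.uniform(0, 2 * np.pi), 7)]
        while stack:
            r, c, theta, budget = stack.pop()
            for _ in range(budget):
                seg = rng.uniform(0.05, 0.12) * scale
                theta += rng.normal(0.0, 0.35)
                r2 = r + seg * np.sin(theta)
                c2 = c + seg * np.cos(theta)
                rr, cc = skdraw.line(int(round(r)), int(round(c)),
                                     int(round(r2)), int(round(c2)))
                inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                skel[rr[inside], cc[inside]] = True
                if rng.uniform() < 0.3 and budget > 2:
                    stack.append((r2, c2,
                                  theta + rng.choice([-1.0, 1.0])
                                  * rng.uniform(0.6, 1.2),
                                  budget - 2))
                r, c = r2, c2
                if not (-0.1 * h < r < 1.1 * h and -0.1 * w < c < 1.1 * w):
                    break
    return skel


def _endomysium_tessellation(h: int, w: int, n_fibers: int,
                             rng: np.random.Generator
                             ) -> tuple[np.ndarray, int]:
    """Nearest-seed (Voronoi) fiber cells; boundary pixels are endomysium."""
    seeds = np.column_stack([rng.uniform(0, h, n_fibers),
                             rng.uniform(0, w, n_fibers)])
    grid = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"),
                    axis=-1).reshape(-1, 2).astype(float)
    _, labels = cKDTree(seeds).query(grid)
    labels = labels.reshape(h, w)
    boundary = np.zeros((h, w), dtype=bool)
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    n_cells = len(np.unique(labels))
    return boundary, n_cells


def _fat_blobs(h: int, w: int, fat_fraction: float, skeleton: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Round marbling deposits, seeded on the perimysium when it exists."""
    mask = np.zeros((h, w), dtype=bool)
    target = int(round(fat_fraction * h * w))
    if target == 0:
        return mask
    anchors = np.argwhere(skeleton)
    scale = max(h, w)
    covered = 0
    for _ in range(100_000):
        if covered >= target:
            break
        if len(anchors) > 0:
            r0, c0 = anchors[rng.integers(len(anchors))]
            r0 = r0 + rng.normal(0, 0.03 * scale)
            c0 = c0 + rng.normal(0, 0.03 * scale)
        else:
            r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(0.004, 0.012) * scale
        rr, cc = skdraw.disk((r0, c0), max(radius, 1.5), shape=(h, w))
        covered += int(np.count_nonzero(~mask[rr, cc]))
        mask[rr, cc] = True
    return mask


def _network_length_width(mask: np.ndarray, pixel_size_um: float
                          ) -> tuple[float, float]:
    """Skeleton length (mm per mm^2 of image) and width (um) of a network.

    Length is the skeleton pixel count times the pixel size; width is twice
    the mean Euclidean distance-to-background sampled along the skeleton.
    """
    h, w = mask.shape
    px_mm = pixel_size_um / 1000.0
    image_area_mm2 = h * w * px_mm * px_mm
    if not mask.any():
        return 0.0, 0.0
    skel = skeletonize(mask)
    n_skel = int(skel.sum())
    if n_skel == 0:
        return 0.0, 0.0
    length_mm = n_skel * px_mm
    edt = ndi.distance_transform_edt(mask)
    width_um = 2.0 * float(edt[skel].mean()) * pixel_size_um
    return length_mm / image_area_mm2, width_um


def _affine(value: float, cal_max: float, out_range: tuple[float, float]
            ) -> float:
    lo, hi = out_range
    return lo + (hi - lo) * (value / cal_max)


def generate_scene(params: SceneParams,
                   spectra: TissueSpectra | None = None
                   ) -> tuple[MultispectralCube, SceneGroundTruth,
                              dict[str, np.ndarray]]:
    """Generate one scene: reflectance cube, exact targets, tissue masks.

    The returned masks (``lean``, ``connective``, ``fat``; plus the
    ``perimysium`` / ``endomysium`` split of connective) partition the
    image.  Where tissues overlap, fat wins over perimysium, which wins
    over endomysium.  The same seed always yields bit-identical output.
    """
    if spectra is None:
        spectra = default_tissue_spectra(params.wavelengths)
    if len(spectra.lean) != params.n_bands:
        raise ValueError("spectra band count does not match params.n_bands")
    h, w = params.image_height, params.image_width
    net_ss, tess_ss, fat_ss, noise_ss = np.random.SeedSequence(
        params.seed).spawn(4)

    skel = _perimysium_skeleton(h, w, params.perimysium_density,
                                np.random.default_rng(net_ss))
    radius = params.perimysium_width_px // 2
    peri = ndi.binary_dilation(skel, disk(radius)) if radius else skel.copy()
    endo, n_cells = _endomysium_tessellation(
        h, w, params.n_fibers, np.random.default_rng(tess_ss))
    fat = _fat_blobs(h, w, params.fat_fraction, skel,
                     np.random.default_rng(fat_ss))

    peri &= ~fat
    endo &= ~(fat | peri)
    connective = peri | endo
    lean = ~(connective | fat)

    # Rendering: a ~1 um endomysium sheath is far thinner than one 86 um
    # pixel, so endomysium pixels are a partial-volume blend of connective
    # and lean reflectance (still a linear mixture of the tissue spectra).
    alpha = params.endomysium_opacity
    endo_spec = alpha * spectra.connective + (1 - alpha) * spectra.lean
    label = np.zeros((h, w), dtype=np.uint8)
    label[endo] = 1
    label[peri] = 2
    label[fat] = 3
    spec = np.stack([spectra.lean, endo_spec, spectra.connective,
                     spectra.fat]).astype(np.float32)
    pixels = spec[label]
    if params.illumination_gradient:
        cols = np.linspace(-0.5, 0.5, w, dtype=np.float32)
        pixels = pixels * (1.0 + params.illumination_gradient
                           * cols)[None, :, None]
    if params.noise_sd > 0:
        noise = np.random.default_rng(noise_ss).standard_normal(
            pixels.shape, dtype=np.float32)
        pixels = pixels + np.float32(params.noise_sd) * noise

    cube = MultispectralCube(pixels=np.asarray(pixels, dtype=np.float32),
                             wavelengths=np.asarray(params.wavelengths,
                                                    dtype=float),
                             pixel_size=params.pixel_size)

    px_mm = params.pixel_size / 1000.0
    image_area_mm2 = h * w * px_mm * px_mm
    peri_len, peri_width = _network_length_width(peri, params.pixel_size)
    endo_len, endo_width = _network_length_width(endo, params.pixel_size)
    truth = SceneGroundTruth(
        perimysium_area=100.0 * peri.sum() / (h * w),
        perimysium_length=peri_len,
        perimysium_width=peri_width,
        endomysium_area=100.0 * endo.sum() / (h * w),
        endomysium_length=endo_len,
        endomysium_width=endo_width,
        fiber_density=n_cells / image_area_mm2,
        imf=_affine(params.fat_fraction, FAT_FRACTION_CAL_MAX, IMF_RANGE),
        total_collagen=_affine(params.perimysium_density, DENSITY_CAL_MAX,
                               TOTAL_COLLAGEN_RANGE),
        insoluble_collagen=_affine(params.perimysium_density,
                                   DENSITY_CAL_MAX,
                                   INSOLUBLE_COLLAGEN_RANGE),
    )
    masks = {"lean": lean, "connective": connective, "fat": fat,
             "perimysium": peri, "endomysium": endo}
    return cube, truth, masks


#: Default per-sample parameter ranges for generate_dataset.  Uniform draws
#: over these reproduce the dataset Min-Max of the biochemical targets via
#: the affine maps above.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "fat_fraction": (0.0, FAT_FRACTION_CAL_MAX),
    "perimysium_density": (0.25, DENSITY_CAL_MAX),
    "n_fibers": (150, 600),
}

_INT_FIELDS = {"n_fibers", "perimysium_width_px"}


def sample_seed(master_seed: int, index: int) -> int:
    """Per-sample seed: first word of SeedSequence([master, index]), < 2^31."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2 ** 31))


def _draw_params(base: SceneParams, ranges: dict[str, tuple[float, float]],
                 seed: int, rng: np.random.Generator) -> SceneParams:
    updates: dict[str, object] = {"seed": seed}
    for name in sorted(ranges):
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"invalid range for {name}: min {lo} > max {hi}")
        value = rng.uniform(lo, hi)
        if name in _INT_FIELDS:
            value = int(round(value))
        updates[name] = value
    return dataclasses.replace(base, **updates)


class SceneSequence(Sequence):
    """Lazy, index-stable sequence of scene cubes.

    Cubes are regenerated on demand from their stored parameters, so a
    240-scene dataset never has to reside in memory at once.  ``scene(i)``
    returns the full (cube, ground truth, masks) triple.
    """

    def __init__(self, params_list: list[SceneParams],
                 spectra: TissueSpectra | None = None):
        self.params_list = list(params_list)
        self.spectra = spectra

    def __len__(self) -> int:
        return len(self.params_list)

    def __getitem__(self, i: int) -> MultispectralCube:
        return self.scene(i)[0]

    def scene(self, i: int) -> tuple[MultispectralCube, SceneGroundTruth,
                                     dict[str, np.ndarray]]:
        return generate_scene(self.params_list[i], self.spectra)


def generate_dataset(n_samples: int,
                     param_ranges: dict[str, tuple[float, float]]
                     | None = None,
                     seed: int = 0,
                     base_params: SceneParams | None = None,
                     spectra: TissueSpectra | None = None
                     ) -> tuple[SceneSequence, pd.DataFrame]:
    """Draw ``n_samples`` scenes and return (lazy cubes, target table).

    Per-sample scene parameters are drawn uniformly from ``param_ranges``
    (default :data:`DEFAULT_PARAM_RANGES`) with a per-sample seed derived
    from the master seed via :func:`sample_seed`.  The target table has one
    row per sample and the ten ground-truth columns.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    ranges = DEFAULT_PARAM_RANGES if param_ranges is None else param_ranges
    base = base_params if base_params is not None else SceneParams()
    params_list = []
    for i in range(n_samples):
        s = sample_seed(seed, i)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, 1]))
        params_list.append(_draw_params(base, ranges, s, rng))
    scenes = SceneSequence(params_list, spectra)
    rows = [scenes.scene(i)[1].as_dict() for i in range(n_samples)]
    table = pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))
    return scenes, table


def write_target_table(table: pd.DataFrame, path) -> None:
    """Write the target table as CSV with the units in a header comment."""
    with open(path, "w") as fh:
        units = "; ".join(f"{c} [{GROUND_TRUTH_UNITS[c]}]"
                          for c in table.columns)
        fh.write(f"# units: {units}\n")
        table.to_csv(fh, index=False)
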