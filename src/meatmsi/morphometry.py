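"""Object shape features and size-class frequency-histogram cubes.

For every segmented object, eight shape descriptors are measured (area,
major/minor axis length, eccentricity, orientation, solidity, extent,
perimeter).  Per sample and band, each descriptor's values are binned into
B equal-width size classes (B in 100..1000 for the study design), and the
per-sample histograms are stacked into a samples x bins x bands cube — the
regression input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .segmentation import LabeledImage

FEATURE_NAMES = (
    "area", "major_axis_length", "minor_axis_length", "eccentricity",
    "orientation", "solidity", "extent", "perimeter",
)

#: The study's canonical histogram class counts.
BIN_COUNTS = tuple(range(100, 1001, 100))

_SKIMAGE_PROPS = {
    "area": "area",
    "major_axis_length": "axis_major_length",
    "minor_axis_length": "axis_minor_length",
    "eccentricity": "eccentricity",
    "orientation": "orientation",
    "solidity": "solidity",
    "extent": "extent",
    "perimeter": "perimeter",
}


def object_features(labeled: LabeledImage,
                    sample_id: int | str = 0,
                    features: tuple[str, ...] = FEATURE_NAMES
                    ) -> pd.DataFrame:
    """Shape descriptors of every labeled object, one row per object.

    Orientation is reported in degrees in (-90, 90], measured from the
    horizontal image axis, positive counter-clockwise when the image is
    viewed with row 0 on top (a stroke running from bottom-left to
    top-right has positive orientation).  All other descriptors follow the
    moment/convex-hull definitions of ``skimage.measure.regionprops``.
    A labeling with zero objects yields an empty table.
    """
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    cols = ["sample_id", "band_index", *features]
    if labeled.n_objects == 0:
        return pd.DataFrame({c: [] for c in cols})
    props = measure.regionprops_table(
        labeled.labels, properties=[_SKIMAGE_PROPS[f] for f in features])
    out = pd.DataFrame({f: props[_SKIMAGE_PROPS[f]] for f in features})
    if "orientation" in out:
        # regionprops: radians from the row (vertical) axis in (-pi/2, pi/2].
        # Shift to degrees from the horizontal axis, positive when the major
        # axis climbs to the right in the displayed image (row 0 on top).
        deg = np.degrees(out["orientation"].to_numpy()) - 90.0
        deg[deg <= -90.0] += 180.0
        out["orientation"] = deg
    out.insert(0, "band_index", labeled.band_index)
    out.insert(0, "sample_id", sample_id)
    return out


def features_for_sample(labeled_images: list[LabeledImage],
                        sample_id: int | str = 0,
                        features: tuple[str, ...] = FEATURE_NAMES
                        ) -> pd.DataFrame:
    """Concatenate per-band object tables for one sample."""
    tables = [object_features(li, sample_id, features)
              for li in labeled_images]
    return pd.concat(tables, ignore_index=True)


def feature_histogram(values: np.ndarray, n_bins: int,
                      value_range: tuple[float, float]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [lo, hi]; out-of-range values are clipped.

    Bins are half-open [edge_i, edge_{i+1}) except the last, which is
    closed, so a value exactly at ``hi`` lands in the last bin.  ``hi ==
    lo`` degenerates to a single bin holding every value.
    """
    lo, hi = float(value_range[0]), float(value_range[1])
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if hi < lo:
        raise ValueError(f"invalid range: hi {hi} < lo {lo}")
    v = np.asarray(values, dtype=float)
    if hi == lo:
        return (np.array([v.size]),
                np.array([lo, hi]))
    counts, edges = np.histogram(np.clip(v, lo, hi), bins=n_bins,
                                 range=(lo, hi))
    return counts, edges


@dataclass
class FeatureCube:
    """samples x bins x bands histogram tensor for one shape feature."""

    values: np.ndarray
    feature_name: str
    n_bins: int
    bin_edges: np.ndarray          # (n_bands, n_bins + 1)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be samples x bins x bands")
        if self.values.shape[1] != self.n_bins:
            raise ValueError("second dimension must equal n_bins")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


def assemble_feature_cube(tables: pd.DataFrame,
                          feature_name: str,
                          n_bins: int,
                          n_bands: int | None = None,
                          range_policy: str = "global",
                          sample_ids: list | None = None,
                          range_rows: np.ndarray | None = None
                          ) -> FeatureCube:
    """Bin per-object feature values into a samples x bins x bands cube.

    ``tables`` is the tidy concatenation of object tables (columns
    ``sample_id``, ``band_index`` and the feature).  With the default
    ``range_policy="global"`` the bin range for each band is the (min, max)
    of the feature over all samples for that band, so bins are comparable
    across samples; ``"per_image"`` uses each sample's own range.
    ``range_rows`` optionally restricts the samples used to set the global
    ranges (e.g. the training set, to avoid test-set leakage).
    """
    if feature_name not in FEATURE_NAMES:
        raise ValueError(
            f"feature_name must be one of {FEATURE_NAMES}, "
            f"got {feature_name!r}")
    if range_policy not in ("global", "per_image"):
        raise ValueError("range_policy must be 'global' or 'per_image'")
    if sample_ids is None:
        sample_ids = sorted(pd.unique(tables["sample_id"]))
    if n_bands is None:
        n_bands = int(tables["band_index"].max()) + 1 if len(tables) else 1

    values = np.zeros((len(sample_ids), n_bins, n_bands))
    edges = np.zeros((n_bands, n_bins + 1))
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    by_band = dict(tuple(tables.groupby("band_index"))) if len(tables) else {}
    for b in range(n_bands):
        sub = by_band.get(b)
        if sub is None or sub.empty:
            edges[b] = np.linspace(0.0, 1.0, n_bins + 1)
            continue
        if range_policy == "global":
            if range_rows is not None:
                ranged = sub[sub["sample_id"].isin(range_rows)]
                ranged = ranged if len(ranged) else sub
            else:
                ranged = sub
            lo = float(ranged[feature_name].min())
            hi = float(ranged[feature_name].max())
            if hi == lo:
                hi = lo + 1.0  # degenerate band: single occupied bin
            band_edges = np.linspace(lo, hi, n_bins + 1)
            edges[b] = band_edges
            for sid, grp in sub.groupby("sample_id"):
                counts, _ = feature_histogram(
                    grp[feature_name].to_numpy(), n_bins, (lo, hi))
                values[sample_pos[sid], :, b] = counts
        else:
            edges[b] = np.nan
            for sid, grp in sub.groupby("sample_id"):
                v = grp[feature_name].to_numpy()
                lo, hi = float(v.min()), float(v.max())
                if hi == lo:
                    hi = lo + 1.0
                counts, _ = feature_histogram(v, n_bins, (lo, hi))
                values[sample_pos[sid], :, b] = counts
    return FeatureCube(values=values, feature_name=feature_name,
                       n_bins=n_bins, bin_edges=edges,
                       sample_ids=list(sample_ids))
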