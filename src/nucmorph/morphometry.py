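"""Per-nucleus interpretable features from instance label maps.

Given an instance-segmented RGB patch (labels registered to the image) and
the scanner's physical pixel size (MPP, microns per pixel), this module
computes 15 features per nucleus:

* 7 shape descriptors in micron units — area, perimeter, major/minor axis
  length, eccentricity, circularity, solidity;
* 8 color statistics — mean and sample SD of grayscale intensity (Rec.601
  luma, 0–255), HSV saturation (0–1), and the CIELAB a* and b* channels
  (sRGB, D65, 2° observer).

Conventions (fixed, documented constants):

* area = pixel count × MPP²;
* perimeter = 4-direction Crofton line-integral boundary estimator × MPP,
  low-bias for smooth convex shapes over the nucleus size range;
* axis lengths = 4·sqrt(eigenvalues of the 2×2 covariance of pixel-center
  coordinates) × MPP (ellipse-of-inertia convention);
* eccentricity = sqrt(1 − (minor/major)²);
* circularity = form factor 4π·area/perimeter² (unit-free);
* solidity = pixel count / pixel count of the filled convex hull, where the
  filled hull is the set of pixels whose center lies in the convex hull of
  the instance's pixel centers;
* SDs use the sample (n−1) convention; 0 when the instance has one pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import color as skcolor
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .schema import FEATURE_NAMES

__all__ = [
    "DegenerateGeometryError",
    "NucleusFeatureRecord",
    "LabeledPatch",
    "shape_features",
    "color_features",
    "featurize_patch",
    "records_to_frame",
]

#: Rec.601 luma weights applied to 8-bit sRGB.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateGeometryError(ValueError):
    """Instance geometry too degenerate for the shape descriptors
    (empty, single pixel, or collinear pixel set)."""


@dataclass(frozen=True)
class NucleusFeatureRecord:
    """The 15 per-nucleus features plus identity columns."""

    nucleus_id: int
    cell_class: str
    area: float
    perimeter: float
    major_axis_length: float
    minor_axis_length: float
    eccentricity: float
    circularity: float
    solidity: float
    gray_mean: float
    gray_sd: float
    sat_mean: float
    sat_sd: float
    lab_a_mean: float
    lab_a_sd: float
    lab_b_mean: float
    lab_b_sd: float

    def feature_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class LabeledPatch:
    """An RGB patch with a registered instance label map.

    ``labels`` is a 2-D non-negative integer map (0 = background) of the
    same height/width as ``rgb``; ``class_map`` assigns a cell class to
    every nonzero instance label.  ``mpp`` is microns per pixel.
    """

    rgb: np.ndarray
    labels: np.ndarray
    mpp: float
    class_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.labels = np.asarray(self.labels)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.labels.shape != self.rgb.shape[:2]:
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"rgb shape {self.rgb.shape[:2]}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _hull_pixel_count(coords: np.ndarray) -> int:
    """Pixels whose center lies in the convex hull of the pixel centers.

    Falls back to the instance's own pixel count for collinear sets, whose
    hull has zero area (solidity 1 by convention).
    """
    pts = coords.astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return len(coords)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    cand = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    # hull.equations: A x + b <= 0 inside
    inside = np.all(
        cand @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9, axis=1
    )
    return int(inside.sum())


def shape_features(
    pixel_set: np.ndarray, mpp: float, *, permissive: bool = False
) -> tuple[float, float, float, float, float, float, float]:
    """Shape descriptors of one instance.

    Parameters
    ----------
    pixel_set
        (N, 2) integer array of (row, col) pixel coordinates.
    mpp
        Microns per pixel; area scales with mpp², lengths with mpp.
    permissive
        If true, degenerate instances (single pixel or collinear) get the
        minor axis floored at 1 px instead of raising.

    Returns
    -------
    (area, perimeter, major, minor, eccentricity, circularity, solidity)
    in micron units where dimensional.
    """
    coords = np.asarray(pixel_set)
    if coords.size == 0:
        raise DegenerateGeometryError("empty pixel set")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("pixel_set must be an (N, 2) coordinate array")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    coords = coords.astype(np.int64)

    n = len(coords)
    rmin, cmin = coords.min(axis=0)
    mask = np.zeros(
        (coords[:, 0].max() - rmin + 1, coords[:, 1].max() - cmin + 1), dtype=np.uint8
    )
    mask[coords[:, 0] - rmin, coords[:, 1] - cmin] = 1
    if int(mask.sum()) != n:
        raise ValueError("pixel_set contains duplicate coordinates")
    if cc_label(mask, connectivity=2).max() > 1:
        # one label, several islands: moments/hull taken over the union to
        # preserve upstream label semantics
        warnings.warn("multi-component instance treated as one pixel set",
                      stacklevel=2)

    (rp,) = regionprops(mask)
    major_px = float(rp.axis_major_length)
    minor_px = float(rp.axis_minor_length)
    perim_px = float(rp.perimeter_crofton)

    if minor_px <= 0.0 or perim_px <= 0.0:
        if not permissive:
            raise DegenerateGeometryError(
                f"degenerate instance geometry ({n} px, minor axis "
                f"{minor_px:.3g} px); pass permissive=True to floor it"
            )
        minor_px = max(minor_px, 1.0)
        major_px = max(major_px, minor_px)
        perim_px = max(perim_px, 4.0 * np.sqrt(n))

    area = n * mpp**2
    perimeter = perim_px * mpp
    major = major_px * mpp
    minor = minor_px * mpp
    eccentricity = float(np.sqrt(max(0.0, 1.0 - (minor_px / major_px) ** 2)))
    circularity = float(4.0 * np.pi * n / perim_px**2)
    solidity = n / _hull_pixel_count(coords)
    return area, perimeter, major, minor, eccentricity, circularity, solidity


def _color_planes(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Grayscale (0–255), saturation (0–1), LAB a*, LAB b* planes."""
    rgb = np.asarray(rgb)
    gray = rgb.astype(float) @ _LUMA
    hsv_s = skcolor.rgb2hsv(rgb)[..., 1]
    lab = skcolor.rgb2lab(rgb)
    return gray, hsv_s, lab[..., 1], lab[..., 2]


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    # sample (n-1) SD; 0 for a single pixel
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return m, s


def color_features(
    pixel_set: np.ndarray, rgb: np.ndarray
) -> tuple[float, float, float, float, float, float, float, float]:
    """Color statistics of one instance over its own pixels.

    Returns (gray_mean, gray_sd, sat_mean, sat_sd, lab_a_mean, lab_a_sd,
    lab_b_mean, lab_b_sd).
    """
    coords = np.asarray(pixel_set)
    if coords.size == 0:
        raise ValueError("empty pixel set")
    rgb = np.asarray(rgb)
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= rgb.shape[0]
        or coords[:, 1].max() >= rgb.shape[1]
    ):
        raise ValueError("pixel coordinates out of image bounds")
    pixels = rgb[coords[:, 0], coords[:, 1]].reshape(-1, 1, 3)
    gray, sat, lab_a, lab_b = _color_planes(pixels)
    return (*_mean_sd(gray.ravel()), *_mean_sd(sat.ravel()),
            *_mean_sd(lab_a.ravel()), *_mean_sd(lab_b.ravel()))


def featurize_patch(
    patch: LabeledPatch, *, permissive: bool = False, min_pixels: int = 0
) -> tuple[list[NucleusFeatureRecord], list[tuple[int, str]]]:
    """All 15 features for every instance in a patch.

    Returns ``(records, failures)``: one record per nonzero label in
    ascending label order, plus a list of (label, reason) for instances that
    failed the degenerate-geometry checks — reported, never silently
    dropped.  Instances below ``min_pixels`` are likewise reported (no
    minimum by default).  Multi-component instances (one label, several
    islands) are treated as a single pixel set, with a warning.
    """
    gray, sat, lab_a, lab_b = _color_planes(patch.rgb)
    records: list[NucleusFeatureRecord] = []
    failures: list[tuple[int, str]] = []
    unclassified = [
        int(i) for i in patch.instance_ids() if int(i) not in patch.class_map
    ]
    if unclassified:
        warnings.warn(
            f"{len(unclassified)} instance(s) without a cell class; "
            "recorded as 'UNCLASSIFIED'",
            stacklevel=2,
        )
    for rp in regionprops(patch.labels):
        label = int(rp.label)
        coords = rp.coords
        if min_pixels and len(coords) < min_pixels:
            failures.append((label, f"below minimum size ({len(coords)} px)"))
            continue
        try:
            shp = shape_features(coords, patch.mpp, permissive=permissive)
        except DegenerateGeometryError as exc:
            failures.append((label, str(exc)))
            continue
        sel = (coords[:, 0], coords[:, 1])
        col = (*_mean_sd(gray[sel]), *_mean_sd(sat[sel]),
               *_mean_sd(lab_a[sel]), *_mean_sd(lab_b[sel]))
        records.append(
            NucleusFeatureRecord(
                label, patch.class_map.get(label, "UNCLASSIFIED"), *shp, *col
            )
        )
    return records, failures


def records_to_frame(records, patch_id: str | None = None):
    """Per-nucleus records as a DataFrame (one row per nucleus)."""
    import pandas as pd

    cols = [f.name for f in fields(NucleusFeatureRecord)]
    df = pd.DataFrame(
        [[getattr(r, c) for c in cols] for r in records], columns=cols
    )
    if patch_id is not None:
        df.insert(0, "patch_id", patch_id)
    return df
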