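"""Micron-calibrated mathematical morphology on binary tissue masks.

All operations take radii in μm and convert to pixel units via the mask
spacing. Disk structuring elements are defined as the set of integer pixel
offsets whose Euclidean length is at most ``radius_um / spacing_um``.
Dilation, erosion and closing are computed through exact Euclidean distance
transforms, which is equivalent to sliding that disk but runs in linear
time:

* dilation  = {p : dist(p, foreground) <= r}
* erosion   = {p : dist(p, background)  > r}   (outside the canvas counts
  as background)
* closing   = erosion(dilation(X)) computed on a padded canvas so the
  intermediate dilation is never clipped at the border, then cropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import BiomarkerConfig
from .io import BACKGROUND, TUMOR, LYMPHOCYTES, LabelMask, MitosisSet, points_to_pixels

#: 8-connectivity structure for connected components of tissue and tumor.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryRegionMask:
    """A boolean region aligned to a source :class:`LabelMask`."""

    pixels: np.ndarray
    spacing_um: float
    role: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("region mask must be 2D")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")

    @property
    def area_mm2(self) -> float:
        return area_mm2(self.pixels, self.spacing_um)


def area_mm2(mask: np.ndarray, spacing_um: float) -> float:
    """Physical area of the true pixels: count x spacing^2, in mm^2."""
    return float(np.count_nonzero(mask)) * spacing_um**2 * 1e-6


def radius_px(radius_um: float, spacing_um: float) -> float:
    return radius_um / spacing_um


def disk_footprint(radius_um: float, spacing_um: float) -> np.ndarray:
    """Disk structuring element: pixel offsets with Euclidean norm <= r.

    Distances are computed as sqrt of integer squared offsets, the same
    arithmetic the distance-transform route uses, so both routes make
    identical inclusion decisions at the disk boundary.
    """
    r = radius_px(radius_um, spacing_um)
    n = int(math.floor(r))
    ax = np.arange(-n, n + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return np.sqrt(d2.astype(float)) <= r


def binary_dilation_um(mask: np.ndarray, radius_um: float, spacing_um: float) -> np.ndarray:
    """Dilation by a disk of physical radius, clipped to the canvas."""
    mask = np.asarray(mask, dtype=bool)
    r = radius_px(radius_um, spacing_um)
    if r < 1 or not mask.any():
        return mask.copy()
    dt = ndimage.distance_transform_edt(~mask)
    return dt <= r


def binary_erosion_um(mask: np.ndarray, radius_um: float, spacing_um: float) -> np.ndarray:
    """Erosion by a disk of physical radius; outside the canvas is background."""
    mask = np.asarray(mask, dtype=bool)
    r = radius_px(radius_um, spacing_um)
    if r < 1 or not mask.any():
        return mask.copy()
    pad = int(math.floor(r)) + 1
    padded = np.pad(mask, pad, constant_values=False)
    dt = ndimage.distance_transform_edt(padded)
    return (dt > r)[pad:-pad, pad:-pad]


def binary_closing_um(mask: np.ndarray, radius_um: float, spacing_um: float) -> np.ndarray:
    """Closing by a disk of physical radius on a padded canvas.

    Padding by the kernel radius keeps the intermediate dilation off the
    border, so the result is always a superset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    r = radius_px(radius_um, spacing_um)
    if r < 1 or not mask.any():
        return mask.copy()
    pad = int(math.floor(r)) + 2
    padded = np.pad(mask, pad, constant_values=False)
    dil = ndimage.distance_transform_edt(~padded) <= r
    dt_bg = ndimage.distance_transform_edt(dil)
    closed = dt_bg > r
    return closed[pad:-pad, pad:-pad]


def filter_small_regions(
    mask: np.ndarray, spacing_um: float, min_area_mm2: float
) -> np.ndarray:
    """Drop 8-connected components strictly smaller than ``min_area_mm2``."""
    mask = np.asarray(mask, dtype=bool)
    if min_area_mm2 <= 0 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=STRUCTURE_8)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())[1:]  # skip background bin
    # compare in um^2 with a sub-pixel tolerance: "smaller than" is strict,
    # so a component exactly at the threshold is retained even when the
    # mm^2 conversion is not exactly representable
    areas_um2 = counts * (spacing_um * spacing_um)
    keep = np.concatenate([[False], areas_um2 >= min_area_mm2 * 1e6 - 1e-6])
    return keep[labels]


def filter_small_tumor_regions(
    mask: LabelMask, min_area_mm2: float | None = None, config: BiomarkerConfig | None = None
) -> BinaryRegionMask:
    """Binary tumor mask with sub-threshold connected components removed."""
    if min_area_mm2 is None:
        min_area_mm2 = (config or BiomarkerConfig()).min_tumor_region_mm2
    tumor = filter_small_regions(mask.class_mask(TUMOR), mask.spacing_um, min_area_mm2)
    return BinaryRegionMask(tumor, mask.spacing_um, role="filtered_tumor")


def build_tumor_bulk(
    filtered_tumor: BinaryRegionMask, config: BiomarkerConfig
) -> BinaryRegionMask:
    """Tumor bulk: closing with the clustering-distance disk, then dilation
    by the margin. Joins tumor regions within the clustering distance and
    draws an outlining envelope around them."""
    sp = filtered_tumor.spacing_um
    closed = binary_closing_um(filtered_tumor.pixels, config.clustering_distance_um, sp)
    bulk = binary_dilation_um(closed, config.margin_um, sp)
    return BinaryRegionMask(bulk, sp, role="tumor_bulk")


def inflamed_tumor_mask(
    mask: LabelMask, tumor: BinaryRegionMask, config: BiomarkerConfig
) -> BinaryRegionMask:
    """Tumor pixels within the interaction distance of any lymphocyte pixel."""
    lymph = mask.class_mask(LYMPHOCYTES)
    near = binary_dilation_um(lymph, config.interaction_distance_um, mask.spacing_um)
    return BinaryRegionMask(tumor.pixels & near, mask.spacing_um, role="inflamed_tumor")


def filter_mitoses(
    mitoses: MitosisSet,
    tumor: BinaryRegionMask | LabelMask,
    config: BiomarkerConfig,
) -> MitosisSet:
    """Keep mitoses surrounded by tumor at least ``mitosis_surround_um`` wide.

    Implemented as membership in the tumor mask eroded by a disk of that
    radius, which is equivalent to requiring every pixel within the disk
    around the point to be tumor.
    """
    if isinstance(tumor, LabelMask):
        tumor = BinaryRegionMask(tumor.class_mask(TUMOR), tumor.spacing_um, role="filtered_tumor")
    sp = tumor.spacing_um
    eroded = binary_erosion_um(tumor.pixels, config.mitosis_surround_um, sp)
    rc = points_to_pixels(mitoses.points, sp)
    h, w = tumor.pixels.shape
    oob = (rc[:, 0] < 0) | (rc[:, 0] >= h) | (rc[:, 1] < 0) | (rc[:, 1] >= w)
    if oob.any():
        raise ValueError(
            f"{int(oob.sum())} mitosis point(s) outside the mask extent "
            f"(slide {mitoses.slide_id or '<unnamed>'})"
        )
    kept = eroded[rc[:, 0], rc[:, 1]] if len(rc) else np.zeros(0, dtype=bool)
    return MitosisSet(points=mitoses.points, kept=kept, slide_id=mitoses.slide_id)


@dataclass
class Core:
    """A connected tissue component (one biopsy core on the slide)."""

    pixels: np.ndarray
    spacing_um: float
    tumor_bearing: bool
    label: int

    @property
    def area_mm2(self) -> float:
        return area_mm2(self.pixels, self.spacing_um)


def identify_cores(
    mask: LabelMask, filtered_tumor: BinaryRegionMask | None = None,
    config: BiomarkerConfig | None = None,
) -> list[Core]:
    """Connected components of non-background tissue, flagged tumor-bearing.

    A core is tumor-bearing iff it contains at least one pixel of the
    (small-region-filtered) tumor mask. Only tumor-bearing cores enter the
    biomarker computation.
    """
    if filtered_tumor is None:
        filtered_tumor = filter_small_tumor_regions(mask, config=config)
    tissue = mask.pixels != BACKGROUND
    labels, n = ndimage.label(tissue, structure=STRUCTURE_8)
    cores: list[Core] = []
    for i in range(1, n + 1):
        comp = labels == i
        cores.append(
            Core(
                pixels=comp,
                spacing_um=mask.spacing_um,
                tumor_bearing=bool(np.any(comp & filtered_tumor.pixels)),
                label=i,
            )
        )
    return cores
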