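"""Reading and writing of label masks, mitosis point sets and cohort tables.

Masks are single-channel integer images (TIFF or PNG) with an isotropic
physical pixel spacing in μm. The label scheme follows the six-compartment
tissue taxonomy used throughout: background, tumor, stroma, lymphocytes,
necrosis, fat, rest. Spacing is metadata: it is taken from an explicit
argument, a sidecar ``<name>.meta.yaml``, or (for TIFF) consistent
resolution tags, in that order of precedence.

Coordinate convention: points live in slide micron space with x along
columns and y along rows; a point (x, y) μm falls into pixel
``(row, col) = (floor(y / spacing), floor(x / spacing))`` (half-open raster
cells, 0-based).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from imageio.v3 import imread, imwrite

#: Canonical label scheme.
DEFAULT_LABEL_MAP: dict[int, str] = {
    0: "background",
    1: "tumor",
    2: "stroma",
    3: "lymphocytes",
    4: "necrosis",
    5: "fat",
    6: "rest",
}

BACKGROUND, TUMOR, STROMA, LYMPHOCYTES, NECROSIS, FAT, REST = range(7)


class DataError(ValueError):
    """Raised for invalid input data (bad labels, units, schemas)."""


@dataclass
class LabelMask:
    """A 2D multi-class tissue segmentation with physical calibration."""

    pixels: np.ndarray
    spacing_um: float
    label_map: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DataError(
                f"label mask must be single-channel 2D, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise DataError(f"label mask must be integer, got {self.pixels.dtype}")
        if not (math.isfinite(self.spacing_um) and self.spacing_um > 0):
            raise DataError(f"spacing_um must be positive and finite, got {self.spacing_um}")
        present = np.unique(self.pixels)
        unknown = sorted(int(v) for v in present if int(v) not in self.label_map)
        if unknown:
            raise DataError(
                f"pixel values {unknown} not in label map "
                f"{sorted(self.label_map)} (slide {self.slide_id or '<unnamed>'})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def class_mask(self, label: int) -> np.ndarray:
        """Boolean mask of one tissue class."""
        return self.pixels == label

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the slide in μm."""
        h, w = self.pixels.shape
        return w * self.spacing_um, h * self.spacing_um


@dataclass
class MitosisSet:
    """Mitosis detections as points in slide micron space.

    ``kept`` is unset until the tumor-surround filter has run; afterwards it
    holds one boolean per point.
    """

    points: np.ndarray  # (n, 2) array of (x_um, y_um)
    kept: np.ndarray | None = None
    slide_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError(f"points must be (n, 2), got shape {pts.shape}")
        if np.any(pts < 0) or not np.all(np.isfinite(pts)):
            raise DataError("mitosis coordinates must be finite and non-negative")
        self.points = pts
        if self.kept is not None:
            self.kept = np.asarray(self.kept, dtype=bool)
            if self.kept.shape != (len(pts),):
                raise DataError("kept must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def kept_points(self) -> np.ndarray:
        if self.kept is None:
            raise ValueError("mitoses have not been filtered yet")
        return self.points[self.kept]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml").with_name(
        path.stem + ".meta.yaml"
    )


def _tiff_spacing(path: Path) -> float | None:
    """Pixel spacing in μm from TIFF resolution tags, if present and isotropic."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if "XResolution" not in tags or "YResolution" not in tags:
            return None
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
        unit = getattr(unit, "value", unit)

        def to_um(res: tuple[int, int] | float) -> float | None:
            num, den = res if isinstance(res, tuple) else (res, 1)
            if not num:
                return None
            per_unit = num / den  # pixels per unit
            if unit == 3:  # centimeter
                return 1e4 / per_unit
            if unit == 2:  # inch
                return 25.4e3 / per_unit
            return None

        sx, sy = to_um(xres), to_um(yres)
    if sx is None or sy is None:
        return None
    if not math.isclose(sx, sy, rel_tol=1e-3):
        raise DataError(f"anisotropic TIFF resolution tags ({sx:.4g} x {sy:.4g} um)")
    return sx


def read_label_mask(
    path: str | Path,
    spacing_um: float | None = None,
    label_map: Mapping[int, str] | None = None,
    slide_id: str | None = None,
) -> LabelMask:
    """Read a single-channel integer mask with its physical calibration.

    Spacing precedence: explicit ``spacing_um`` argument, sidecar
    ``<name>.meta.yaml``, consistent TIFF resolution tags. The sidecar may
    also carry a label map, which an explicit ``label_map`` overrides.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}

    if spacing_um is None:
        spacing_um = meta.get("spacing_um")
    if spacing_um is None and path.suffix.lower() in {".tif", ".tiff"}:
        spacing_um = _tiff_spacing(path)
    if spacing_um is None:
        raise DataError(
            f"no pixel spacing for {path.name}: pass spacing_um, provide a "
            f"sidecar meta.yaml, or embed TIFF resolution tags"
        )

    if label_map is None:
        raw = meta.get("label_map")
        label_map = {int(k): str(v) for k, v in raw.items()} if raw else None

    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        pixels = imread(path)
    if pixels.ndim != 2:
        raise DataError(f"{path.name}: expected single-channel image, got shape {pixels.shape}")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise DataError(f"{path.name}: expected integer pixels, got {pixels.dtype}")

    return LabelMask(
        pixels=pixels,
        spacing_um=float(spacing_um),
        label_map=dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP),
        slide_id=slide_id if slide_id is not None else path.stem,
    )


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as uint8 TIFF/PNG plus a sidecar meta.yaml."""
    path = Path(path)
    pixels = mask.pixels.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        ppcm = 1e4 / mask.spacing_um  # pixels per centimeter
        tifffile.imwrite(
            path, pixels, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER"
        )
    else:
        imwrite(path, pixels)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        yaml.safe_dump(
            {
                "slide_id": mask.slide_id,
                "spacing_um": float(mask.spacing_um),
                "label_map": {int(k): str(v) for k, v in mask.label_map.items()},
            },
            sort_keys=True,
        )
    )
    return path


def read_mitoses(
    path: str | Path,
    unit: str = "um",
    spacing_um: float | None = None,
    slide_id: str | None = None,
) -> MitosisSet:
    """Read mitosis points from CSV (columns x,y) or a JSON array of {x,y}.

    ``unit`` is ``"um"`` or ``"pixel"``; pixel coordinates are converted to
    μm via ``spacing_um`` (mapping a pixel index to its cell center would
    shift all points by half a pixel, so the raw index times spacing is
    used, matching the inverse of the floor pixel-lookup convention).
    """
    path = Path(path)
    if unit not in {"um", "pixel"}:
        raise DataError(f"unknown unit {unit!r}; expected 'um' or 'pixel'")
    if unit == "pixel":
        if spacing_um is None or not spacing_um > 0:
            raise DataError("pixel-unit mitoses need a positive spacing_um")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        pts = np.array([[r["x"], r["y"]] for r in records], dtype=float).reshape(-1, 2)
    else:
        df = pd.read_csv(path)
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        pts = df[["x", "y"]].to_numpy(dtype=float)
    if unit == "pixel":
        pts = pts * float(spacing_um)
    return MitosisSet(points=pts, slide_id=slide_id if slide_id is not None else path.stem)


def write_mitoses(mitoses: MitosisSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(mitoses.points, columns=["x", "y"])
    if mitoses.kept is not None:
        df["kept"] = mitoses.kept.astype(int)
    df.to_csv(path, index=False)
    return path


COHORT_COLUMNS = [
    "case_id",
    "slide_ids",
    "pcr",
    "subtype",
    "age_years",
    "grade",
    "t_stage",
    "n_stage",
    "vtils",
]

_SUBTYPES = {"TNBC", "LuminalB", "HER2pos"}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Required: case_id (unique), pcr in {0,1}. Clinical covariates
    (subtype, age_years, grade, t_stage, n_stage, vtils) are optional and
    may contain missing values; vtils must lie in [0, 100] where present.
    """
    df = pd.read_csv(Path(path))
    if "case_id" not in df.columns or "pcr" not in df.columns:
        raise DataError("cohort table needs case_id and pcr columns")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise DataError(f"duplicate case ids: {dupes}")
    pcr = df["pcr"].dropna()
    if not pcr.isin([0, 1]).all():
        raise DataError("pcr must be binary 0/1")
    if "subtype" in df.columns:
        bad = set(df["subtype"].dropna()) - _SUBTYPES
        if bad:
            raise DataError(f"unknown subtypes {sorted(bad)}; expected {sorted(_SUBTYPES)}")
    if "vtils" in df.columns:
        v = df["vtils"].dropna()
        if ((v < 0) | (v > 100)).any():
            raise DataError("vtils must lie in [0, 100]")
    return df


def points_to_pixels(
    points_um: np.ndarray | Sequence[Sequence[float]], spacing_um: float
) -> np.ndarray:
    """Map (x, y) μm points to (row, col) raster indices (floor convention)."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    cols = np.floor(pts[:, 0] / spacing_um).astype(int)
    rows = np.floor(pts[:, 1] / spacing_um).astype(int)
    return np.stack([rows, cols], axis=1)
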