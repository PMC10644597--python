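"""The four tumor-microenvironment biomarkers and their case-level pooling.

Per slide, everything is computed over tumor-bearing biopsy cores only:

* cTILs = lymphocytes / (lymphocytes + stroma), both measured inside the
  tumor bulk — a computational analogue of visual stromal TIL scoring.
* LTR   = lymphocytes / (lymphocytes + tumor) over the tumor-bearing cores.
* ITR   = tumor within the interaction distance of lymphocytes / tumor.
* MTR   = kept mitoses per mm^2 of tumor.

A ratio whose denominator is zero is *undefined* and represented as None;
undefined values propagate as missing data rather than numeric sentinels.
Case-level scores pool the per-slide area sums and mitosis counts first and
apply the ratios to the pooled sums, as if all cores lay on a single slide
— never by averaging per-slide ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import BiomarkerConfig
from .geometry import (
    BinaryRegionMask,
    area_mm2,
    build_tumor_bulk,
    filter_mitoses,
    filter_small_tumor_regions,
    identify_cores,
    inflamed_tumor_mask,
)
from .io import LYMPHOCYTES, STROMA, TUMOR, LabelMask, MitosisSet

BIOMARKER_NAMES = ("ctils", "ltr", "itr", "mtr")

NO_TUMOR = "no_tumor"


@dataclass
class AreaSummary:
    """Per-slide tissue areas (mm^2) and kept-mitosis count.

    This is the sufficient statistic for all four biomarkers and for case
    pooling. Bulk quantities are measured inside the tumor-bulk envelope;
    the others over all tumor-bearing cores.
    """

    lymphocytes_bulk_mm2: float = 0.0
    stroma_bulk_mm2: float = 0.0
    lymphocytes_mm2: float = 0.0
    tumor_mm2: float = 0.0
    inflamed_tumor_mm2: float = 0.0
    mitoses_kept: int = 0
    mitoses_available: bool = True
    slide_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "lymphocytes_bulk_mm2",
            "stroma_bulk_mm2",
            "lymphocytes_mm2",
            "tumor_mm2",
            "inflamed_tumor_mm2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inflamed_tumor_mm2 > self.tumor_mm2 + 1e-12:
            raise ValueError("inflamed tumor cannot exceed total tumor")
        if self.mitoses_kept < 0:
            raise ValueError("mitoses_kept must be >= 0")


@dataclass
class BiomarkerPanel:
    """The four scores at slide or case level; None marks undefined."""

    ctils: float | None
    ltr: float | None
    itr: float | None
    mtr: float | None
    level: str = "slide"  # or "case"
    id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("ctils", "ltr", "itr"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mtr is not None and self.mtr < 0:
            raise ValueError("mtr must be >= 0")


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def ctils(summary: AreaSummary) -> float | None:
    """Computational TILs: lymphocyte share of (lymphocytes + stroma) in the bulk."""
    return _ratio(
        summary.lymphocytes_bulk_mm2,
        summary.lymphocytes_bulk_mm2 + summary.stroma_bulk_mm2,
    )


def ltr(summary: AreaSummary) -> float | None:
    """Lymphocytes-to-tumor ratio over tumor-bearing cores."""
    return _ratio(summary.lymphocytes_mm2, summary.lymphocytes_mm2 + summary.tumor_mm2)


def itr(summary: AreaSummary) -> float | None:
    """Inflamed tumor ratio: tumor near lymphocytes over all tumor."""
    return _ratio(summary.inflamed_tumor_mm2, summary.tumor_mm2)


def mtr(summary: AreaSummary) -> float | None:
    """Mitotic rate: kept mitoses per mm^2 of tumor; None when no tumor or
    no mitosis input was provided."""
    if not summary.mitoses_available:
        return None
    return _ratio(float(summary.mitoses_kept), summary.tumor_mm2)


def panel_from_summary(
    summary: AreaSummary, level: str = "slide", id: str | None = None
) -> BiomarkerPanel:
    return BiomarkerPanel(
        ctils=ctils(summary),
        ltr=ltr(summary),
        itr=itr(summary),
        mtr=mtr(summary),
        level=level,
        id=id if id is not None else summary.slide_id,
        flags=list(summary.flags),
    )


def summarize_slide(
    mask: LabelMask,
    mitoses: MitosisSet | None = None,
    config: BiomarkerConfig | None = None,
) -> AreaSummary:
    """Measure all biomarker inputs on one slide.

    Steps: filter small tumor components; find tissue cores and keep the
    tumor-bearing ones; restrict every tissue class to those cores; build
    the tumor bulk, the inflamed-tumor mask and the kept-mitosis set;
    tabulate areas. A slide without any tumor-bearing core yields an
    all-zero summary flagged ``no_tumor``.
    """
    config = config or BiomarkerConfig()
    sp = mask.spacing_um

    filtered = filter_small_tumor_regions(mask, config=config)
    if not config.apply_small_region_filter_globally:
        # bulk still uses the filtered mask; denominators use raw tumor
        denom_tumor = mask.class_mask(TUMOR)
    else:
        denom_tumor = filtered.pixels

    cores = identify_cores(mask, filtered, config)
    bearing = [c for c in cores if c.tumor_bearing]
    if not bearing:
        return AreaSummary(
            slide_id=mask.slide_id,
            mitoses_available=mitoses is not None,
            flags=[NO_TUMOR],
        )
    region = np.zeros(mask.shape, dtype=bool)
    for c in bearing:
        region |= c.pixels

    tumor = BinaryRegionMask(denom_tumor & region, sp, role="filtered_tumor")
    tumor_for_bulk = BinaryRegionMask(filtered.pixels & region, sp, role="filtered_tumor")
    lymph = mask.class_mask(LYMPHOCYTES) & region
    stroma = mask.class_mask(STROMA) & region

    bulk = build_tumor_bulk(tumor_for_bulk, config)
    restricted = LabelMask(
        pixels=np.where(region, mask.pixels, 0),
        spacing_um=sp,
        label_map=mask.label_map,
        slide_id=mask.slide_id,
    )
    inflamed = inflamed_tumor_mask(restricted, tumor, config)

    kept = 0
    if mitoses is not None and len(mitoses):
        kept = int(filter_mitoses(mitoses, tumor, config).kept.sum())

    return AreaSummary(
        lymphocytes_bulk_mm2=area_mm2(lymph & bulk.pixels, sp),
        stroma_bulk_mm2=area_mm2(stroma & bulk.pixels, sp),
        lymphocytes_mm2=area_mm2(lymph, sp),
        tumor_mm2=tumor.area_mm2,
        inflamed_tumor_mm2=inflamed.area_mm2,
        mitoses_kept=kept,
        mitoses_available=mitoses is not None,
        slide_id=mask.slide_id,
    )


def pool_summaries(summaries: Sequence[AreaSummary], case_id: str = "") -> AreaSummary:
    """Sum per-slide areas and mitosis counts into one case-level summary.

    The ``no_tumor`` flag survives pooling only if every slide carries it;
    all other flags are unioned.
    """
    if not summaries:
        raise ValueError("pooling needs at least one slide summary")
    flags = sorted({f for s in summaries for f in s.flags if f != NO_TUMOR})
    if all(NO_TUMOR in s.flags for s in summaries):
        flags.append(NO_TUMOR)
    return AreaSummary(
        lymphocytes_bulk_mm2=sum(s.lymphocytes_bulk_mm2 for s in summaries),
        stroma_bulk_mm2=sum(s.stroma_bulk_mm2 for s in summaries),
        lymphocytes_mm2=sum(s.lymphocytes_mm2 for s in summaries),
        tumor_mm2=sum(s.tumor_mm2 for s in summaries),
        inflamed_tumor_mm2=sum(s.inflamed_tumor_mm2 for s in summaries),
        mitoses_kept=sum(s.mitoses_kept for s in summaries),
        mitoses_available=all(s.mitoses_available for s in summaries),
        slide_id=case_id,
        flags=sorted(flags),
    )


def pool_case(summaries: Sequence[AreaSummary], case_id: str = "") -> BiomarkerPanel:
    """Case-level panel: ratios applied to the pooled sums, never to
    averages of per-slide ratios."""
    pooled = pool_summaries(summaries, case_id)
    return panel_from_summary(pooled, level="case", id=case_id)


_CSV_COLUMNS = [
    "id",
    "level",
    "ctils",
    "ltr",
    "itr",
    "mtr",
    "tumor_mm2",
    "lymphocytes_mm2",
    "stroma_bulk_mm2",
    "lymphocytes_bulk_mm2",
    "inflamed_tumor_mm2",
    "mitoses_kept",
    "flags",
]


def panels_to_frame(
    panels: Iterable[BiomarkerPanel],
    summaries: Iterable[AreaSummary | None] | None = None,
) -> pd.DataFrame:
    """Tabulate panels (and optionally their area summaries) for CSV output."""
    panels = list(panels)
    summaries = list(summaries) if summaries is not None else [None] * len(panels)
    rows = []
    for p, s in zip(panels, summaries):
        row: dict = {
            "id": p.id,
            "level": p.level,
            "ctils": p.ctils,
            "ltr": p.ltr,
            "itr": p.itr,
            "mtr": p.mtr,
            "flags": ";".join(p.flags),
        }
        if s is not None:
            row.update(
                tumor_mm2=s.tumor_mm2,
                lymphocytes_mm2=s.lymphocytes_mm2,
                stroma_bulk_mm2=s.stroma_bulk_mm2,
                lymphocytes_bulk_mm2=s.lymphocytes_bulk_mm2,
                inflamed_tumor_mm2=s.inflamed_tumor_mm2,
                mitoses_kept=s.mitoses_kept,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[_CSV_COLUMNS]
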