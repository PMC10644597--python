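"""Geometric hyperparameters of the biomarker pipeline.

All distances are physical (μm) and independent of the raster resolution of
the input masks; areas are in mm². The defaults are the biopsy-scale values
the biomarkers were designed with: a 100 μm clustering distance and 50 μm
margin for the tumor bulk, a 0.1 mm² minimum tumor-region size, an 80 μm
lymphocyte-tumor interaction distance and a 20 μm tumor-surround requirement
for mitosis detections.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class BiomarkerConfig:
    """Tunable geometry of the four biomarkers.

    Parameters
    ----------
    clustering_distance_um:
        Radius of the circular closing kernel that joins nearby tumor
        regions into the tumor bulk.
    margin_um:
        Radius of the dilation applied after closing; the outlining
        envelope of the bulk.
    min_tumor_region_mm2:
        Connected tumor components strictly smaller than this area are
        discarded before any biomarker computation (guards against small
        spurious tumor predictions). Components exactly at the threshold
        are retained.
    interaction_distance_um:
        Tumor within this Euclidean distance of lymphocytes counts as
        "inflamed" (ITR numerator).
    mitosis_surround_um:
        A mitosis is kept only if it is surrounded by tumor at least this
        wide, i.e. it lies in the tumor mask eroded by a disk of this
        radius.
    apply_small_region_filter_globally:
        When True (default) the small-region-filtered tumor mask feeds
        every biomarker denominator, not only the bulk construction, so a
        single tumor definition is used throughout.
    """

    clustering_distance_um: float = 100.0
    margin_um: float = 50.0
    min_tumor_region_mm2: float = 0.1
    interaction_distance_um: float = 80.0
    mitosis_surround_um: float = 20.0
    apply_small_region_filter_globally: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "apply_small_region_filter_globally":
                continue
            if not (v >= 0):  # also catches NaN
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")


DEFAULT_CONFIG = BiomarkerConfig()
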