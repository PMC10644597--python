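"""Seedable synthetic biopsy phantoms with analytically known biomarkers.

A phantom emulates a core-needle biopsy slide: several elongated tissue
cores of stroma, tumor nests of controllable size and spacing, compact
lymphocyte clusters inside the tumor bulk, and mitosis points planted at a
controlled distance from the tumor boundary. All shapes are axis-aligned
rectangles, so every ground-truth area has a constructive value.

Ground truth is computed in *continuous* micron space with polygon
geometry (shapely buffers implement the closing/dilation of the bulk
construction), never by running the raster pipeline; the pipeline is then
validated against it. For a single convex nest the bulk area reduces to
the closed form ``L*W + 2*(L+W)*r + pi*r**2`` of a rectangle dilated by a
disk of radius r.

Mitoses are placed on the perimeter of each nest's inset rectangle
(inset = ``mitosis_edge_distance_um``), so every point sits at exactly
that distance from the tumor boundary and the kept count under the
tumor-surround rule is known exactly: all points survive iff the edge
distance exceeds the surround radius.

The cohort simulator draws a latent biomarker per case from a standard
normal, links it to pathological complete response through a logistic
model, and adds Gaussian observation noise; the AUC of the generative
model is available in closed form via numerical integration for
calibration checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from shapely.geometry import box
from shapely.ops import unary_union

from .biomarkers import AreaSummary, BiomarkerPanel, panel_from_summary
from .config import BiomarkerConfig
from .io import LYMPHOCYTES, STROMA, REST, TUMOR, LabelMask, MitosisSet

_QS = 64  # quadrant segments for shapely buffers; disk-area error < 1e-4
LYMPH_CLUSTER_SIDE_UM = 40.0  # compact cluster of ~25 lymphocytes
_CLUSTER_PITCH_UM = 48.0  # multiple of the 4 um grid quantum below
# cluster corners snap to this quantum so cluster edges land on pixel
# boundaries at the common 2 and 4 um spacings, keeping rasterized areas
# and distance fronts faithful to the continuous geometry
_CLUSTER_SNAP_UM = 4.0
_BORDER_UM = 200.0
_CORE_GAP_UM = 500.0
_NEST_TOP_FRACTION = 0.08  # first nest starts this far down the core

Rect = tuple[float, float, float, float]  # (x0, y0, x1, y1) in um


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of one synthetic biopsy slide.

    Defaults describe a plausible breast core-needle biopsy: three cores of
    6 x 1 mm, four 0.36 mm^2 tumor nests whose 150 um gaps are bridged by
    the 100 um clustering distance, a moderately inflamed stroma
    (15% lymphocytes in the bulk) and ~3 mitoses per mm^2 of tumor planted
    40 um inside the nests (beyond the 20 um surround rule).
    """

    n_cores: int = 3
    core_length_um: float = 6000.0
    core_width_um: float = 1000.0
    tumor_nest_count: int = 4
    tumor_nest_diameter_um: float = 600.0
    tumor_nest_gap_um: float = 150.0
    lymphocyte_fraction_in_bulk: float = 0.15
    stroma_fill: float = 1.0
    mitosis_density_per_mm2: float = 3.0
    mitosis_edge_distance_um: float = 40.0
    spacing_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cores < 1 or self.tumor_nest_count < 0:
            raise ValueError("need at least one core and a non-negative nest count")
        for name in ("core_length_um", "core_width_um", "spacing_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lymphocyte_fraction_in_bulk", "stroma_fill"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mitosis_density_per_mm2 < 0:
            raise ValueError("mitosis_density_per_mm2 must be >= 0")


@dataclass
class PhantomTruth:
    """Constructive ground truth of a phantom (continuous geometry)."""

    summary: AreaSummary
    panel: BiomarkerPanel
    bulk_mm2: float
    core_rects: list[Rect]
    nest_rects: list[Rect]
    lymph_rects: list[Rect]


def _core_rects(spec: PhantomSpec) -> list[Rect]:
    rects = []
    for i in range(spec.n_cores):
        x0 = _BORDER_UM + i * (spec.core_width_um + _CORE_GAP_UM)
        rects.append((x0, _BORDER_UM, x0 + spec.core_width_um, _BORDER_UM + spec.core_length_um))
    return rects


def _nest_rects(spec: PhantomSpec, cores: list[Rect]) -> list[Rect]:
    """Distribute nests round-robin over cores 0..n_cores-2 (the last core
    stays tumor-free whenever there is more than one core)."""
    if spec.tumor_nest_count == 0:
        return []
    d = spec.tumor_nest_diameter_um
    if d > spec.core_width_um:
        raise ValueError("tumor nest wider than the core")
    n_host = max(1, spec.n_cores - 1)
    per_core: dict[int, int] = {}
    nests: list[Rect] = []
    for k in range(spec.tumor_nest_count):
        ci = k % n_host
        slot = per_core.get(ci, 0)
        per_core[ci] = slot + 1
        cx0, cy0, cx1, cy1 = cores[ci]
        x0 = cx0 + (spec.core_width_um - d) / 2
        y0 = cy0 + _NEST_TOP_FRACTION * spec.core_length_um + slot * (d + spec.tumor_nest_gap_um)
        if y0 + d > cy1:
            raise ValueError(
                f"tumor nests do not fit in the core (nest {k} ends at "
                f"{y0 + d - cy0:.0f} um of {spec.core_length_um:.0f} um)"
            )
        nests.append((x0, y0, x0 + d, y0 + d))
    return nests


def _bulk_polygon(tumor_poly, config: BiomarkerConfig):
    """Continuous-space tumor bulk: morphological closing with the
    clustering-distance disk, then dilation by the margin."""
    r = config.clustering_distance_um
    closed = tumor_poly.buffer(r, quad_segs=_QS).buffer(-r, quad_segs=_QS)
    closed = closed.union(tumor_poly)
    return closed.buffer(config.margin_um, quad_segs=_QS)


def _place_lymph_clusters(
    rng: np.random.Generator, avail_region, target_area_um2: float
) -> list[Rect]:
    """Disjoint square clusters inside ``avail_region`` totalling exactly
    the target area (the last cluster is trimmed)."""
    if target_area_um2 <= 0:
        return []
    s = LYMPH_CLUSTER_SIDE_UM
    minx, miny, maxx, maxy = avail_region.bounds
    x0 = _CLUSTER_SNAP_UM * math.ceil(minx / _CLUSTER_SNAP_UM)
    y0 = _CLUSTER_SNAP_UM * math.ceil(miny / _CLUSTER_SNAP_UM)
    xs = np.arange(x0, maxx - s, _CLUSTER_PITCH_UM)
    ys = np.arange(y0, maxy - s, _CLUSTER_PITCH_UM)
    candidates = [
        (x, y, x + s, y + s)
        for y in ys
        for x in xs
        if box(x, y, x + s, y + s).within(avail_region)
    ]
    if len(candidates) * s * s < target_area_um2:
        raise ValueError(
            f"cannot fit lymphocyte fraction: {target_area_um2:.0f} um2 requested, "
            f"only {len(candidates) * s * s:.0f} um2 of cluster sites available"
        )
    order = rng.permutation(len(candidates))
    placed: list[Rect] = []
    remaining = target_area_um2
    for idx in order:
        if remaining <= 1e-9:
            break
        x0, y0, x1, y1 = candidates[idx]
        if remaining >= s * s:
            placed.append((x0, y0, x1, y1))
            remaining -= s * s
        else:
            w = remaining / s
            if w > 1e-6:
                placed.append((x0, y0, x0 + w, y1))
            remaining = 0.0
    return placed


def _plant_mitoses(
    rng: np.random.Generator, spec: PhantomSpec, nests: list[Rect], tumor_mm2: float
) -> np.ndarray:
    n = int(round(spec.mitosis_density_per_mm2 * tumor_mm2))
    if n == 0 or not nests:
        return np.zeros((0, 2))
    e = spec.mitosis_edge_distance_um
    if spec.tumor_nest_diameter_um <= 2 * e:
        raise ValueError("mitosis_edge_distance_um too large for the nest size")
    pts = []
    for k in range(n):
        x0, y0, x1, y1 = nests[k % len(nests)]
        ix0, iy0, ix1, iy1 = x0 + e, y0 + e, x1 - e, y1 - e
        w, h = ix1 - ix0, iy1 - iy0
        t = rng.uniform(0, 2 * (w + h))
        if t < w:
            p = (ix0 + t, iy0)
        elif t < w + h:
            p = (ix1, iy0 + (t - w))
        elif t < 2 * w + h:
            p = (ix1 - (t - w - h), iy1)
        else:
            p = (ix0, iy1 - (t - 2 * w - h))
        pts.append(p)
    return np.asarray(pts)


def _paint_rect(pixels: np.ndarray, rect: Rect, value: int, sp: float) -> None:
    """Set pixels whose centers fall inside the half-open rectangle."""
    x0, y0, x1, y1 = rect
    c0 = max(int(math.ceil(x0 / sp - 0.5)), 0)
    c1 = max(int(math.ceil(x1 / sp - 0.5)), 0)
    r0 = max(int(math.ceil(y0 / sp - 0.5)), 0)
    r1 = max(int(math.ceil(y1 / sp - 0.5)), 0)
    pixels[r0:r1, c0:c1] = value


def generate_phantom(
    spec: PhantomSpec, config: BiomarkerConfig | None = None
) -> tuple[LabelMask, MitosisSet, PhantomTruth]:
    """Build a phantom slide, its mitoses, and its constructive ground truth.

    Deterministic for a fixed ``spec.seed``. The ground truth is evaluated
    under ``config`` (default geometry: 100/50/0.1/80/20) and assumes every
    nest exceeds the small-region threshold.
    """
    config = config or BiomarkerConfig()
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing_um

    cores = _core_rects(spec)
    nests = _nest_rects(spec, cores)

    stroma_rects = [
        (x0, y0, x1, y0 + spec.stroma_fill * (y1 - y0)) for x0, y0, x1, y1 in cores
    ]
    rest_rects = [
        (x0, y0 + spec.stroma_fill * (y1 - y0), x1, y1) for x0, y0, x1, y1 in cores
    ]

    # --- continuous ground truth ------------------------------------------
    tumor_poly = unary_union([box(*r) for r in nests]) if nests else box(0, 0, 0, 0)
    tumor_um2 = sum((r[2] - r[0]) * (r[3] - r[1]) for r in nests)
    host_cores = {k % max(1, spec.n_cores - 1) for k in range(spec.tumor_nest_count)}
    bearing_poly = unary_union([box(*cores[i]) for i in sorted(host_cores)]) if nests else None
    stroma_poly = unary_union([box(*r) for r in stroma_rects])

    lymph_rects: list[Rect] = []
    bulk_um2 = 0.0
    avail_um2 = 0.0
    if nests:
        bulk_poly = _bulk_polygon(tumor_poly, config)
        bulk_um2 = bulk_poly.area
        avail = bulk_poly.intersection(stroma_poly).intersection(bearing_poly).difference(
            tumor_poly
        )
        avail_um2 = avail.area
        # shrink slightly so clusters stay clear of region borders after
        # rasterization
        avail_inner = avail.buffer(-1.0, quad_segs=_QS)
        lymph_rects = _place_lymph_clusters(
            rng, avail_inner, spec.lymphocyte_fraction_in_bulk * avail_um2
        )

    lymph_um2 = sum((r[2] - r[0]) * (r[3] - r[1]) for r in lymph_rects)
    if lymph_rects:
        lymph_poly = unary_union([box(*r) for r in lymph_rects])
        near = lymph_poly.buffer(config.interaction_distance_um, quad_segs=_QS)
        inflamed_um2 = tumor_poly.intersection(near).area
    else:
        inflamed_um2 = 0.0

    mito_pts = _plant_mitoses(rng, spec, nests, tumor_um2 * 1e-6)
    kept = (
        len(mito_pts)
        if spec.mitosis_edge_distance_um > config.mitosis_surround_um
        else 0
    )

    truth_summary = AreaSummary(
        lymphocytes_bulk_mm2=lymph_um2 * 1e-6,
        stroma_bulk_mm2=(avail_um2 - lymph_um2) * 1e-6,
        lymphocytes_mm2=lymph_um2 * 1e-6,
        tumor_mm2=tumor_um2 * 1e-6,
        inflamed_tumor_mm2=min(inflamed_um2, tumor_um2) * 1e-6,
        mitoses_kept=kept,
        slide_id=f"phantom_seed{spec.seed}",
        flags=[] if nests else ["no_tumor"],
    )
    truth = PhantomTruth(
        summary=truth_summary,
        panel=panel_from_summary(truth_summary, level="slide"),
        bulk_mm2=bulk_um2 * 1e-6,
        core_rects=cores,
        nest_rects=nests,
        lymph_rects=lymph_rects,
    )

    # --- rasterization -----------------------------------------------------
    width_um = 2 * _BORDER_UM + spec.n_cores * spec.core_width_um + (
        spec.n_cores - 1
    ) * _CORE_GAP_UM
    height_um = 2 * _BORDER_UM + spec.core_length_um
    shape = (int(round(height_um / sp)), int(round(width_um / sp)))
    pixels = np.zeros(shape, dtype=np.uint8)
    for r in stroma_rects:
        _paint_rect(pixels, r, STROMA, sp)
    for r in rest_rects:
        _paint_rect(pixels, r, REST, sp)
    for r in nests:
        _paint_rect(pixels, r, TUMOR, sp)
    for r in lymph_rects:
        _paint_rect(pixels, r, LYMPHOCYTES, sp)

    mask = LabelMask(pixels=pixels, spacing_um=sp, slide_id=truth_summary.slide_id)
    mitoses = MitosisSet(points=mito_pts, slide_id=truth_summary.slide_id)
    return mask, mitoses, truth


def dilated_rectangle_area_um2(length_um: float, width_um: float, radius_um: float) -> float:
    """Closed-form area of a rectangle dilated by a disk:
    L*W + 2*(L+W)*r + pi*r^2."""
    return (
        length_um * width_um
        + 2 * (length_um + width_um) * radius_um
        + math.pi * radius_um**2
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative model of a biomarker-outcome cohort.

    A latent biomarker b ~ N(0,1) drives pathological complete response via
    logit P(pCR | b) = intercept + effect_size * b, with the intercept
    solved so the marginal responder fraction matches; the observed
    biomarker is b plus N(0, noise_sd^2) measurement noise. Clinical
    covariates are drawn independently of the biomarker with prevalences
    typical of neoadjuvant breast-cancer cohorts.
    """

    n_cases: int = 200
    responder_fraction: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _solve_intercept(effect_size: float, responder_fraction: float) -> float:
    b = np.linspace(-9, 9, 4001)
    w = stats.norm.pdf(b)
    w /= np.trapezoid(w, b)

    def marginal(a: float) -> float:
        return float(np.trapezoid(w / (1 + np.exp(-(a + effect_size * b))), b))

    return float(
        optimize.brentq(lambda a: marginal(a) - responder_fraction, -40, 40)
    )


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate a cohort table with true and observed biomarker values."""
    rng = np.random.default_rng(spec.seed)
    a = _solve_intercept(spec.effect_size, spec.responder_fraction)
    b = rng.normal(size=spec.n_cases)
    p = 1 / (1 + np.exp(-(a + spec.effect_size * b)))
    pcr = rng.uniform(size=spec.n_cases) < p
    if pcr.all() or not pcr.any():
        raise ValueError("degenerate cohort: all cases share one pCR label")
    obs = b + rng.normal(scale=spec.noise_sd, size=spec.n_cases)

    n = spec.n_cases
    df = pd.DataFrame(
        {
            "case_id": [f"C{i:05d}" for i in range(n)],
            "slide_ids": [f"C{i:05d}_s1" for i in range(n)],
            "pcr": pcr.astype(int),
            "subtype": rng.choice(["TNBC", "LuminalB"], size=n, p=[0.4, 0.6]),
            "age_years": np.round(rng.normal(51, 11, size=n), 1),
            "grade": rng.choice([2, 3], size=n, p=[0.55, 0.45]),
            "t_stage": rng.choice(["T1/2", "T3/4"], size=n, p=[0.75, 0.25]),
            "n_stage": rng.choice(["N0", "N1"], size=n, p=[0.5, 0.5]),
            "biomarker_true": b,
            "biomarker_observed": obs,
        }
    )
    df["vtils"] = np.clip(50 + 18 * obs + rng.normal(scale=5, size=n), 0, 100)
    return df


def analytic_auc(
    effect_size: float, noise_sd: float = 0.0, responder_fraction: float = 0.3
) -> float:
    """AUC of the observed biomarker against pCR under the generative model,
    by numerical integration of the class-conditional score densities."""
    a = _solve_intercept(effect_size, responder_fraction)
    s = np.linspace(-12, 12, 8001)
    phi = stats.norm.pdf(s)
    sig = 1 / (1 + np.exp(-(a + effect_size * s)))
    f1 = phi * sig
    f0 = phi * (1 - sig)
    if noise_sd > 0:
        ds = s[1] - s[0]
        half = int(np.ceil(5 * noise_sd / ds))
        kernel = stats.norm.pdf(np.arange(-half, half + 1) * ds, scale=noise_sd) * ds
        f1 = np.convolve(f1, kernel, mode="same")
        f0 = np.convolve(f0, kernel, mode="same")
    f1 /= np.trapezoid(f1, s)
    f0 /= np.trapezoid(f0, s)
    F0 = integrate.cumulative_trapezoid(f0, s, initial=0.0)
    return float(np.trapezoid(f1 * F0, s))
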