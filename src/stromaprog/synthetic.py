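"""Synthetic H&E scenes with exact ternary masks, and survival cohorts.

The scene generator paints three tissue classes with known, pixel-exact
geometry: gland-like tumor structures (rings of hematoxylin-rich epithelium
around a pale lumen), clusters of small dark basophilic discs standing in for
lymphocytes, and a pink fibrous-textured stromal background.  Appearance is
composed in optical-density space from two reference stain vectors
(hematoxylin and eosin) via the Beer–Lambert law, so the images carry a true
two-stain structure that stain-separation methods can recover.

The cohort generator draws per-patient stroma and lymphocyte fractions (SIP,
LIP), assigns each patient a ground-truth prognostic group from two SIP cuts
and one LIP cut, and samples exponential survival with a group-specific
hazard: intermediate SIP and high LIP are protective, mirroring the U-shaped
stroma effect and the favourable lymphocyte effect the analysis is built to
detect.  Censoring is independent exponential plus an administrative cutoff.

Everything is a pure function of its parameters, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tiling import IGNORE, rasterize_polygon

# class encoding shared across the package
STROMA, TUMOR, LYMPHOCYTE = 0, 1, 2
CLASS_NAMES = {STROMA: "stroma", TUMOR: "tumor", LYMPHOCYTE: "lymphocyte"}

# reference H&E stain vectors (unit optical-density absorption per channel)
HE_STAIN_MATRIX = np.array(
    [[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]]
)
HE_STAIN_MATRIX /= np.linalg.norm(HE_STAIN_MATRIX, axis=0, keepdims=True)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic H&E tile scene."""

    image_size_px: tuple[int, int] = (396, 396)
    tumor_gland_count: int = 3
    lymphocyte_cluster_count: int = 3
    stroma_fiber_density: float = 0.5
    stain_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 32 or w < 32:
            raise ValueError("image_size_px must be at least 32 per side")
        if self.tumor_gland_count < 0 or self.lymphocyte_cluster_count < 0:
            raise ValueError("object counts must be non-negative")
        if not 0.0 <= self.stroma_fiber_density <= 1.0:
            raise ValueError("stroma_fiber_density must lie in [0, 1]")
        if self.stain_jitter < 0:
            raise ValueError("stain_jitter must be non-negative")


def gland_polygon(
    rng: np.random.Generator, size: tuple[int, int], n_vertices: int = 24
) -> np.ndarray:
    """Perturbed-circle polygon used as a tumor gland outline."""
    h, w = size
    r_base = rng.uniform(0.08, 0.18) * min(h, w)
    cx = rng.uniform(r_base, w - r_base)
    cy = rng.uniform(r_base, h - r_base)
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    radii = r_base * (1.0 + 0.25 * rng.standard_normal(n_vertices))
    radii = np.clip(radii, 0.4 * r_base, 1.6 * r_base)
    return np.column_stack([cx + radii * np.cos(ang), cy + radii * np.sin(ang)])


def _paint_glands(
    rng: np.random.Generator, size: tuple[int, int], count: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize gland polygons; returns (tumor mask, lumen mask)."""
    tumor = np.zeros(size, dtype=bool)
    lumen = np.zeros(size, dtype=bool)
    for _ in range(count):
        poly = gland_polygon(rng, size)
        m = rasterize_polygon(poly, size)
        centre = poly.mean(axis=0)
        inner = centre + 0.4 * (poly - centre)
        tumor |= m
        lumen |= rasterize_polygon(inner, size) & m
    return tumor, lumen


def _paint_lymphocytes(
    rng: np.random.Generator, size: tuple[int, int], count: int
) -> np.ndarray:
    """Clusters of small round discs; exact disc geometry at pixel centres."""
    h, w = size
    mask = np.zeros(size, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    ycent, xcent = yy + 0.5, xx + 0.5
    for _ in range(count):
        cx = rng.uniform(10, w - 10)
        cy = rng.uniform(10, h - 10)
        n_cells = rng.integers(8, 22)
        spread = rng.uniform(8, 18)
        for _ in range(n_cells):
            dx, dy = rng.normal(0.0, spread, size=2)
            r = rng.uniform(2.2, 4.0)
            mask |= (xcent - (cx + dx)) ** 2 + (ycent - (cy + dy)) ** 2 <= r**2
    return mask


def _smooth_noise(rng: np.random.Generator, size, sigma) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    z = gaussian_filter(rng.standard_normal(size), sigma)
    s = z.std()
    return z / s if s > 0 else z


def generate_tile_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate one H&E-like scene and its exact ternary mask.

    Returns ``(rgb, mask)`` where ``rgb`` is uint8 ``(H, W, 3)`` and ``mask``
    is uint8 ``(H, W)`` over {0: stroma, 1: tumor, 2: lymphocyte}.  Identical
    parameters (including seed) give bit-identical output.
    """
    size = tuple(params.image_size_px)
    rng = np.random.default_rng(params.seed)

    tumor, lumen = _paint_glands(rng, size, params.tumor_gland_count)
    lymph = _paint_lymphocytes(rng, size, params.lymphocyte_cluster_count)

    mask = np.zeros(size, dtype=np.uint8)
    mask[tumor] = TUMOR
    mask[lymph] = LYMPHOCYTE  # lymphocytes painted on top of glands

    # stain concentrations per pixel (hematoxylin, eosin), scaled to give
    # pale-pink stroma, purple gland epithelium and dark basophilic discs
    c_h = np.full(size, 0.12)
    c_e = np.full(size, 0.28)
    fibers = _smooth_noise(rng, size, sigma=(6.0, 1.5))  # anisotropic streaks
    c_e += 0.12 * params.stroma_fiber_density * fibers
    c_h += 0.04 * _smooth_noise(rng, size, sigma=2.0)

    c_h[tumor], c_e[tumor] = 0.55, 0.30
    c_h[lumen], c_e[lumen] = 0.03, 0.03
    c_h[lymph], c_e[lymph] = 1.20, 0.15

    grain = 0.03 * rng.standard_normal(size)
    conc = np.stack([np.clip(c_h + grain, 0, None), np.clip(c_e + grain, 0, None)])

    od = np.tensordot(HE_STAIN_MATRIX, conc, axes=([1], [0]))  # (3, H, W)
    if params.stain_jitter > 0:
        od *= np.exp(params.stain_jitter * rng.standard_normal(3))[:, None, None]
    rgb = np.clip(255.0 * np.power(10.0, -od), 0, 255)
    return rgb.transpose(1, 2, 0).round().astype(np.uint8), mask


def default_roi_polygon(slide_shape: tuple[int, int], inset: int = 4) -> list:
    """Rectangular ROI strictly inside the slide, inset on every side."""
    h, w = slide_shape
    if 2 * inset >= min(h, w):
        raise ValueError("inset too large for slide")
    return [(inset, inset), (w - inset, inset), (w - inset, h - inset), (inset, h - inset)]


def generate_slide(
    scene_grid: tuple[int, int],
    params: SceneParams,
    roi_polygon: Sequence[Sequence[float]] | None = None,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Assemble a slide from a grid of abutting scenes.

    Returns ``(slide_rgb, roi_polygon, full_mask)``.  Scene ``(i, j)`` uses a
    seed derived deterministically from ``params.seed``; the full mask is the
    concatenation of the per-scene masks (ROI membership is applied later by
    stitching/quantification, not baked into the mask).
    """
    gy, gx = scene_grid
    if gy < 1 or gx < 1:
        raise ValueError("scene_grid must be at least 1x1")
    h, w = params.image_size_px
    slide = np.empty((gy * h, gx * w, 3), dtype=np.uint8)
    full_mask = np.empty((gy * h, gx * w), dtype=np.uint8)
    for i in range(gy):
        for j in range(gx):
            sub = SceneParams(
                image_size_px=params.image_size_px,
                tumor_gland_count=params.tumor_gland_count,
                lymphocyte_cluster_count=params.lymphocyte_cluster_count,
                stroma_fiber_density=params.stroma_fiber_density,
                stain_jitter=params.stain_jitter,
                seed=params.seed * 100003 + i * gx + j,
            )
            rgb, m = generate_tile_scene(sub)
            slide[i * h : (i + 1) * h, j * w : (j + 1) * w] = rgb
            full_mask[i * h : (i + 1) * h, j * w : (j + 1) * w] = m
    if roi_polygon is None:
        roi_polygon = default_roi_polygon(slide.shape[:2])
    else:
        verts = np.asarray(roi_polygon, dtype=float)
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > slide.shape[1]
            or verts[:, 1].max() > slide.shape[0]
        ):
            raise ValueError("roi_polygon must lie inside the slide bounds")
        roi_polygon = [tuple(v) for v in verts]
    return slide, list(roi_polygon), full_mask


# ---------------------------------------------------------------------------
# survival cohorts


def _default_hazards() -> dict:
    # per-month exponential rates; intermediate SIP and high LIP protective
    return {
        ("intermediate", "high"): 0.015,
        ("intermediate", "low"): 0.029,
        ("LH", "high"): 0.029,
        ("LH", "low"): 0.058,
    }


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a simulated survival cohort.

    ``sip_distribution`` / ``lip_distribution`` are ``(name, *args)`` tuples
    with name in {"uniform", "beta"} on [0, 1].  ``hazard_by_group`` maps
    ``(sip group, lip group)`` with sip group in {"intermediate", "LH"} and
    lip group in {"high", "low"} to an exponential event rate per month.
    """

    n_patients: int = 500
    sip_distribution: tuple = ("uniform", 0.20, 0.95)
    lip_distribution: tuple = ("beta", 2.0, 80.0)
    sip_cuts_true: tuple[float, float] = (0.54, 0.75)
    lip_cut_true: float = 0.02
    hazard_by_group: dict = field(default_factory=_default_hazards)
    censoring_rate: float = 0.005
    admin_censor_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        c1, c2 = self.sip_cuts_true
        if not 0 < c1 < c2 < 1:
            raise ValueError("sip_cuts_true must satisfy 0 < c1 < c2 < 1")
        if not 0 < self.lip_cut_true < 1:
            raise ValueError("lip_cut_true must lie in (0, 1)")
        if any(rate <= 0 for rate in self.hazard_by_group.values()):
            raise ValueError("hazard rates must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")


def _draw(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    name, *args = dist
    if name == "uniform":
        lo, hi = args
        return rng.uniform(lo, hi, n)
    if name == "beta":
        a, b = args
        return rng.beta(a, b, n)
    raise ValueError(f"unknown distribution {name!r}")


def true_groups(
    sip: np.ndarray, lip: np.ndarray, sip_cuts: tuple[float, float], lip_cut: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth SIP (intermediate/LH) and LIP (high/low) group labels."""
    c1, c2 = sip_cuts
    sip_group = np.where((sip > c1) & (sip <= c2), "intermediate", "LH")
    lip_group = np.where(lip > lip_cut, "high", "low")
    return sip_group, lip_group


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a survival cohort with SIP/LIP-dependent exponential hazard.

    Returns one row per patient with columns ``patient_id, age, sex, sip,
    lip, os_months, event`` plus ground-truth labels ``true_sip_group,
    true_lip_group`` (the latter are for validation, not inputs to any
    analysis).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    sip = _draw(rng, params.sip_distribution, n)
    lip = _draw(rng, params.lip_distribution, n)
    sip_group, lip_group = true_groups(sip, lip, params.sip_cuts_true, params.lip_cut_true)

    rates = np.array(
        [params.hazard_by_group[(s, l)] for s, l in zip(sip_group, lip_group)]
    )
    t_event = rng.exponential(1.0 / rates)
    if params.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / params.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, params.admin_censor_months)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(rng.normal(66.0, 9.0, n), 1),
            "sex": rng.choice(["F", "M"], n),
            "sip": sip,
            "lip": lip,
            "os_months": os_months,
            "event": event,
            "true_sip_group": sip_group,
            "true_lip_group": lip_group,
        }
    )


def save_image(path, array: np.ndarray) -> None:
    """Write an RGB image or a single-channel mask as PNG."""
    from PIL import Image

    Image.fromarray(array).save(path)
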