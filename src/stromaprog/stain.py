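"""Macenko stain estimation and color normalization for H&E tiles.

The method converts RGB to optical density (OD) via the Beer–Lambert law,
discards near-transparent pixels below an OD floor, finds the dominant
two-dimensional stain plane by eigen-decomposition of the OD scatter, and
takes the extreme percentile angles within that plane as the hematoxylin and
eosin stain vectors.  Tiles are normalized by re-expressing their per-pixel
stain concentrations in a reference stain basis, after rescaling by the
ratio of robust (99th-percentile) maximum concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np


class StainEstimationError(ValueError):
    """Raised when a tile has too few stained pixels to estimate a profile."""


@dataclass(frozen=True)
class StainProfile:
    """Two-stain OD basis (columns: hematoxylin, eosin) + robust maxima."""

    stain_matrix: np.ndarray  # (3, 2), unit columns, non-negative
    max_concentrations: np.ndarray  # (2,), > 0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        c = np.asarray(self.max_concentrations, dtype=float)
        if m.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if not np.allclose(np.linalg.norm(m, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must have unit norm")
        if (m < -1e-9).any():
            raise ValueError("stain_matrix entries must be non-negative")
        if c.shape != (2,) or (c <= 0).any():
            raise ValueError("max_concentrations must be two positive values")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "max_concentrations", c)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stain_matrix": self.stain_matrix.tolist(),
                "max_concentrations": self.max_concentrations.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StainProfile":
        d = json.loads(text)
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]))


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel; input uint8 or float in [0, 255]."""
    i = np.maximum(np.asarray(rgb, dtype=float), 1.0)
    return -np.log10(i / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(255.0 * np.power(10.0, -od), 0, 255).round().astype(np.uint8)


def nnls_concentrations(stain_matrix: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Non-negative least-squares stain concentrations, vectorized.

    Solves ``min ||M c - od||, c >= 0`` per pixel for the 3x2 matrix ``M``
    using the closed form of the two-variable case: take the unconstrained
    solution where feasible, else the better of the two single-stain fits.

    Parameters
    ----------
    stain_matrix : (3, 2)
    od : (n, 3) optical densities

    Returns
    -------
    (n, 2) concentrations
    """
    m = np.asarray(stain_matrix, dtype=float)
    y = np.asarray(od, dtype=float)
    gram = m.T @ m
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("stain matrix is singular")
    c_free = y @ m @ np.linalg.inv(gram).T  # (n, 2)
    feasible = (c_free >= 0).all(axis=1)
    c = np.where(c_free < 0, 0.0, c_free)
    bad = ~feasible
    if bad.any():
        yb = y[bad]
        # single-stain projections (clipped at zero)
        c1 = np.clip(yb @ m[:, 0] / gram[0, 0], 0, None)
        c2 = np.clip(yb @ m[:, 1] / gram[1, 1], 0, None)
        r1 = ((yb - np.outer(c1, m[:, 0])) ** 2).sum(axis=1)
        r2 = ((yb - np.outer(c2, m[:, 1])) ** 2).sum(axis=1)
        use1 = r1 <= r2
        cb = np.zeros((bad.sum(), 2))
        cb[use1, 0] = c1[use1]
        cb[~use1, 1] = c2[~use1]
        c[bad] = cb
    return c


def estimate_stain_profile(
    rgb_tile: np.ndarray,
    beta_od: float = 0.15,
    alpha_pct: float = 1.0,
    min_pixels: int = 100,
) -> StainProfile:
    """Estimate the two-stain profile of a tile by the Macenko method.

    Pixels with any channel OD below ``beta_od`` are discarded; the two
    leading eigenvectors of the remaining OD scatter span the stain plane;
    the directions at the ``alpha_pct`` and ``100 - alpha_pct`` percentile
    angles within the plane are the stain vectors.  The first column is the
    hematoxylin-like stain (larger red-channel absorption).

    Raises
    ------
    StainEstimationError
        if fewer than ``min_pixels`` pixels survive the OD floor (e.g. a
        blank tile); callers should fall back to a reference profile.
    """
    od = rgb_to_od(rgb_tile).reshape(-1, 3)
    # drop near-transparent pixels: every channel below the OD floor
    od = od[od.max(axis=1) >= beta_od]
    if len(od) < min_pixels:
        raise StainEstimationError(
            f"only {len(od)} pixels above OD {beta_od}; need {min_pixels}"
        )
    cov = np.cov(od, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    plane = evecs[:, [2, 1]]  # two leading eigenvectors
    # orient the plane axes toward positive OD so angles are well defined
    for k in range(2):
        if plane[:, k].sum() < 0:
            plane[:, k] = -plane[:, k]
    proj = od @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha_pct, 100.0 - alpha_pct])
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])
    vecs = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0, None)
        vecs.append(v / np.linalg.norm(v))
    # hematoxylin absorbs red more strongly than eosin does
    if vecs[0][0] < vecs[1][0]:
        vecs = vecs[::-1]
    matrix = np.column_stack(vecs)
    conc = nnls_concentrations(matrix, od)
    max_c = np.percentile(conc, 99.0, axis=0)
    max_c = np.maximum(max_c, 1e-6)
    return StainProfile(matrix, max_c)


def normalize_tile(
    rgb_tile: np.ndarray, source: StainProfile, reference: StainProfile
) -> np.ndarray:
    """Re-composite a tile's stain concentrations in a reference basis.

    Concentrations under ``source`` are rescaled by the ratio of reference to
    source robust maxima and recombined with the reference stain matrix.  For
    a tile whose OD lies in the source stain plane, normalizing with
    ``source == reference`` is an identity up to rounding.
    """
    shape = rgb_tile.shape
    od = rgb_to_od(rgb_tile).reshape(-1, 3)
    conc = nnls_concentrations(source.stain_matrix, od)
    conc *= reference.max_concentrations / source.max_concentrations
    od_out = conc @ reference.stain_matrix.T
    return od_to_rgb(od_out).reshape(shape)


@lru_cache(maxsize=1)
def default_reference_profile() -> StainProfile:
    """Reference profile estimated once from a fixed synthetic H&E scene."""
    from .synthetic import SceneParams, generate_tile_scene

    rgb, _ = generate_tile_scene(SceneParams(seed=20))
    return estimate_stain_profile(rgb)
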