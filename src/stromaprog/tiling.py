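"""ROI tessellation and the overlapping-tile strategy.

A whole-slide region of interest (ROI) is partitioned into abutting square
*output* windows (default 212 px).  Each output window is served by a larger
*input* window (default 396 px) centred on it, so that a network using only
valid (unpadded) convolutions still produces seamless, gap-free predictions
when the per-tile outputs are stitched back together.  Input-window pixels
falling outside the slide are filled by mirror reflection about the slide
edge, the convention of the original valid-convolution U-Net design.

At 0.25 micron per pixel a 396-px tile covers 99 μm of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: sentinel for pixels outside the ROI / to be ignored in losses and areas
IGNORE = 255


@dataclass(frozen=True)
class TileSpec:
    """Geometry of the overlapping-tile scheme.

    Parameters
    ----------
    input_px : side of the window fed to the segmenter, in pixels.
    output_px : side of the predicted window, in pixels.  Must be smaller
        than ``input_px`` with an even difference so the margin splits
        symmetrically.
    microns_per_px : physical sampling of the slide raster.
    """

    input_px: int = 396
    output_px: int = 212
    microns_per_px: float = 0.25

    def __post_init__(self) -> None:
        if self.input_px <= 0 or self.output_px <= 0:
            raise ValueError("tile sides must be positive")
        if self.output_px >= self.input_px:
            raise ValueError("output_px must be smaller than input_px")
        if (self.input_px - self.output_px) % 2:
            raise ValueError("input_px - output_px must be even")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def margin(self) -> int:
        """Half-width of the context border, (input − output) / 2."""
        return (self.input_px - self.output_px) // 2

    @property
    def physical_side_um(self) -> float:
        """Physical side length of the input window in microns."""
        return self.input_px * self.microns_per_px


@dataclass(frozen=True)
class TileCoord:
    """Top-left corner of an output window, 0-based slide coordinates."""

    slide_id: str
    x0: int
    y0: int


def rasterize_polygon(
    polygon: Sequence[Sequence[float]], shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd rasterization of a polygon at pixel centres.

    A pixel ``(row, col)`` belongs to the mask iff its centre
    ``(col + 0.5, row + 0.5)`` lies inside the polygon under the even-odd
    (crossing-number) rule.  Vertices are ``(x, y)`` pairs in pixel
    coordinates.

    Returns a boolean array of the given ``(rows, cols)`` shape.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon must be a sequence of >=3 (x, y) vertices")
    rows, cols = shape
    out = np.zeros((rows, cols), dtype=bool)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    xc = np.arange(cols) + 0.5
    for r in range(rows):
        yc = r + 0.5
        # edges straddling the scanline under the half-open convention
        straddle = (y1 <= yc) != (y2 <= yc)
        if not straddle.any():
            continue
        t = (yc - y1[straddle]) / (y2[straddle] - y1[straddle])
        xs = x1[straddle] + t * (x2[straddle] - x1[straddle])
        # crossing count to the right of each pixel centre; odd -> inside
        out[r] = (xs[None, :] > xc[:, None]).sum(axis=1) % 2 == 1
    return out


def polygon_bounds(polygon: Sequence[Sequence[float]]) -> tuple[int, int, int, int]:
    """Integer pixel bounding box (x_min, y_min, x_max, y_max), half-open."""
    verts = np.asarray(polygon, dtype=float)
    x_min = int(np.floor(verts[:, 0].min()))
    y_min = int(np.floor(verts[:, 1].min()))
    x_max = int(np.ceil(verts[:, 0].max()))
    y_max = int(np.ceil(verts[:, 1].max()))
    return x_min, y_min, x_max, y_max


def plan_tiles(
    roi_polygon: Sequence[Sequence[float]],
    tile_spec: TileSpec = TileSpec(),
    slide_id: str = "slide",
) -> list[TileCoord]:
    """Plan output windows forming a disjoint cover of the ROI.

    Output windows sit on a regular grid of stride ``output_px`` anchored at
    the ROI bounding-box corner; a window is kept iff it contains at least
    one ROI pixel.  Together the kept windows cover every ROI pixel exactly
    once.  Returns an empty list for an empty (zero-pixel) ROI.
    """
    x_min, y_min, x_max, y_max = polygon_bounds(roi_polygon)
    if x_max <= x_min or y_max <= y_min:
        return []
    s = tile_spec.output_px
    # rasterize the ROI once over its bounding box
    bbox_shape = (y_max - y_min, x_max - x_min)
    local = rasterize_polygon(
        [(x - x_min, y - y_min) for x, y in roi_polygon], bbox_shape
    )
    if not local.any():
        return []
    coords: list[TileCoord] = []
    for gy in range(0, bbox_shape[0], s):
        for gx in range(0, bbox_shape[1], s):
            if local[gy : gy + s, gx : gx + s].any():
                coords.append(TileCoord(slide_id, x_min + gx, y_min + gy))
    return coords


def _reflect_indices(start: int, length: int, n: int) -> np.ndarray:
    """Symmetric-reflection index map for a window [start, start+length)."""
    if n <= 0:
        raise ValueError("axis length must be positive")
    i = np.arange(start, start + length)
    m = np.mod(i, 2 * n)
    return np.where(m < n, m, 2 * n - 1 - m)


def extract_input_window(
    slide_image: np.ndarray, coord: TileCoord, tile_spec: TileSpec = TileSpec()
) -> np.ndarray:
    """Crop the input window serving ``coord``, mirror-padding at slide edges.

    The input window is the output window dilated by ``tile_spec.margin`` on
    every side.  Out-of-slide pixels are filled by symmetric reflection about
    the slide boundary (edge row/column included once in the mirror).
    """
    m = tile_spec.margin
    h, w = slide_image.shape[:2]
    ry = _reflect_indices(coord.y0 - m, tile_spec.input_px, h)
    rx = _reflect_indices(coord.x0 - m, tile_spec.input_px, w)
    return slide_image[np.ix_(ry, rx)]


def stitch(
    per_tile_masks: Sequence[tuple[TileCoord, np.ndarray]],
    roi_polygon: Sequence[Sequence[float]],
    slide_shape: tuple[int, int],
    tile_spec: TileSpec = TileSpec(),
) -> np.ndarray:
    """Assemble per-tile output masks into a slide-level class map.

    Each ROI pixel takes its class from the unique output window containing
    it; pixels outside the ROI are set to :data:`IGNORE`.  Raises if any ROI
    pixel is covered by no supplied tile.
    """
    s = tile_spec.output_px
    out = np.full(slide_shape, IGNORE, dtype=np.uint8)
    covered = np.zeros(slide_shape, dtype=bool)
    for coord, mask in per_tile_masks:
        if mask.shape != (s, s):
            raise ValueError(
                f"tile mask must be {s}x{s}, got {mask.shape} at {coord}"
            )
        y1 = min(coord.y0 + s, slide_shape[0])
        x1 = min(coord.x0 + s, slide_shape[1])
        if y1 <= coord.y0 or x1 <= coord.x0:
            continue
        out[coord.y0 : y1, coord.x0 : x1] = mask[: y1 - coord.y0, : x1 - coord.x0]
        covered[coord.y0 : y1, coord.x0 : x1] = True
    roi = rasterize_polygon(roi_polygon, slide_shape)
    if (roi & ~covered).any():
        n_missing = int((roi & ~covered).sum())
        raise ValueError(f"incomplete tile coverage: {n_missing} ROI pixels unassigned")
    out[~roi] = IGNORE
    return out


def tile_manifest_frame(coords: Sequence[TileCoord]):
    """Tile manifest as a pandas DataFrame (slide_id, x0, y0)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": [c.slide_id for c in coords],
            "x0": [c.x0 for c in coords],
            "y0": [c.y0 for c in coords],
        }
    )
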