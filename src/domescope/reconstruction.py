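"""Extended-depth-of-field fusion and mosaic stitching.

Each z-stack is fused into a single all-in-focus composite by selecting,
per pixel, the focal plane with the highest local focus score; the
winning plane indices form a topography height map of the specimen
surface (plane index x z-step = height in um). Tiled composites and
height maps are then registered by phase correlation on their overlap
regions and stitched into a whole-monolayer mosaic. Height maps are
categorical (plane indices), so they are always assembled by
nearest-tile provenance, never intensity-blended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import sobel_h, sobel_v
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .scene import Tile, ZStack

__all__ = [
    "CompositeResult",
    "TileOffsets",
    "Mosaic",
    "focus_measure",
    "edf_compose",
    "register_tiles",
    "stitch",
]


@dataclass
class CompositeResult:
    """All-in-focus composite plus the per-pixel in-focus plane index."""

    composite: np.ndarray
    height_map: np.ndarray  # integer plane indices
    focus_quality: np.ndarray
    z_step_um: float = 1.0
    pixel_size_um: float = 1.0

    @property
    def height_um(self) -> np.ndarray:
        """Height map converted to um above the lowest plane."""
        return self.height_map.astype(float) * self.z_step_um

    def save(self, outdir, stem: str = "composite") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / f"{stem}.tif", self.composite.astype(np.float32))
        tifffile.imwrite(
            outdir / f"{stem}_heightmap.tif", self.height_map.astype(np.uint16)
        )


@dataclass
class TileOffsets:
    """Residual (dy, dx) placements in px relative to the nominal grid."""

    residuals: np.ndarray           # (n_tiles, 2) int
    flagged: np.ndarray             # (n_tiles,) bool: fell back to nominal
    search_radius_px: int

    def to_csv(self, path, tiles: list[Tile] | None = None) -> None:
        rows = []
        for i, (dy, dx) in enumerate(self.residuals):
            r, c = tiles[i].grid_index if tiles else (i, 0)
            rows.append((r, c, int(dy), int(dx), bool(self.flagged[i])))
        pd.DataFrame(
            rows, columns=["row", "col", "dy_px", "dx_px", "flagged"]
        ).to_csv(path, index=False)


@dataclass
class Mosaic:
    """Stitched composite + height map with per-pixel source-tile provenance."""

    composite: np.ndarray
    height_map: np.ndarray | None
    provenance: np.ndarray  # source tile index per pixel, -1 outside coverage
    origin: tuple[int, int]  # mosaic (y, x) of the canvas origin in nominal frame


def focus_measure(
    image: np.ndarray, method: str = "variance", window_px: int = 7
) -> np.ndarray:
    """Local focus score: windowed variance or tenengrad (Sobel energy).

    Scores are non-negative and translation-equivariant away from the
    borders; borders are handled by reflection padding.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("focus_measure expects a 2D image")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > min(image.shape):
        raise ValueError("window_px larger than image")
    if method == "variance":
        mean = ndimage.uniform_filter(image, window_px, mode="reflect")
        sq = ndimage.uniform_filter(image * image, window_px, mode="reflect")
        return np.clip(sq - mean * mean, 0.0, None)
    if method == "tenengrad":
        gx = sobel_v(image)
        gy = sobel_h(image)
        return ndimage.uniform_filter(gx * gx + gy * gy, window_px, mode="reflect")
    raise ValueError(f"unknown focus method {method!r}")


def edf_compose(
    stack: ZStack,
    method: str = "variance",
    window_px: int = 7,
    smooth_radius_px: int = 2,
) -> CompositeResult:
    """Fuse a z-stack into an all-in-focus composite and a height map.

    The raw height map is the per-pixel argmax of the focus score over z
    (ties resolved to the lowest plane index), median-smoothed with a
    disk footprint of the given radius to suppress isolated argmax
    noise; the composite samples each pixel from its smoothed plane.
    """
    data = stack.data
    if stack.n_planes == 1:
        warnings.warn(
            "single-plane stack: passthrough composite with constant height map",
            RuntimeWarning, stacklevel=2,
        )
        plane = data[0].astype(np.float64)
        return CompositeResult(
            composite=plane,
            height_map=np.zeros(plane.shape, dtype=np.int32),
            focus_quality=focus_measure(plane, method, window_px),
            z_step_um=stack.z_step_um,
            pixel_size_um=stack.pixel_size_um,
        )
    scores = np.stack(
        [focus_measure(data[k], method, window_px) for k in range(stack.n_planes)]
    )
    raw = np.argmax(scores, axis=0).astype(np.int32)  # ties -> lowest index
    if smooth_radius_px > 0:
        height = ndimage.median_filter(
            raw, footprint=disk(smooth_radius_px), mode="nearest"
        ).astype(np.int32)
    else:
        height = raw
    rows, cols = np.indices(height.shape)
    composite = data[height, rows, cols].astype(np.float64)
    return CompositeResult(
        composite=composite,
        height_map=height,
        focus_quality=scores.max(axis=0),
        z_step_um=stack.z_step_um,
        pixel_size_um=stack.pixel_size_um,
    )


def _overlap_windows(
    shape_a: tuple[int, int],
    shape_b: tuple[int, int],
    off_a: tuple[int, int],
    off_b: tuple[int, int],
) -> tuple[tuple[slice, slice], tuple[slice, slice]] | None:
    """Slices of the nominal overlap region within each of two tiles."""
    ya, xa = off_a
    yb, xb = off_b
    y0 = max(ya, yb)
    x0 = max(xa, xb)
    y1 = min(ya + shape_a[0], yb + shape_b[0])
    x1 = min(xa + shape_a[1], xb + shape_b[1])
    if y1 <= y0 or x1 <= x0:
        return None
    win_a = (slice(y0 - ya, y1 - ya), slice(x0 - xa, x1 - xa))
    win_b = (slice(y0 - yb, y1 - yb), slice(x0 - xb, x1 - xb))
    return win_a, win_b


def _round_half_toward_zero(x: float) -> int:
    """Round to nearest integer, exact halves toward zero (smaller |shift|)."""
    ax = abs(x)
    frac = ax - np.floor(ax)
    if abs(frac - 0.5) < 1e-12:
        return int(np.sign(x) * np.floor(ax))
    return int(np.sign(x) * np.floor(ax + 0.5))


def register_tiles(
    tiles: list[np.ndarray] | list[Tile],
    nominal_offsets: list[tuple[int, int]] | None = None,
    search_radius_px: int = 8,
    min_overlap_px: int = 16,
    feature_std_floor: float = 1e-6,
) -> TileOffsets:
    """Estimate integer residual offsets by phase correlation on overlaps.

    Pairwise shifts between neighboring tiles are reconciled over the
    grid by a breadth-first sweep from the anchor tile (smallest nominal
    offset, residual fixed at zero), averaging the estimates available
    from already-placed neighbors (exact half-pixel averages round
    toward zero). Featureless overlaps (near-constant, or correlation
    peak out of range) fall back to the nominal offset and are flagged.
    """
    if tiles and isinstance(tiles[0], Tile):
        if nominal_offsets is None:
            nominal_offsets = [t.nominal_offset for t in tiles]
        images = [
            t.stack.data[0] if t.stack.data.ndim == 3 else t.stack.data
            for t in tiles
        ]
    else:
        images = [np.asarray(t, dtype=float) for t in tiles]
        if nominal_offsets is None:
            raise ValueError("nominal_offsets required for raw-array tiles")
    n = len(images)
    residuals = np.zeros((n, 2), dtype=int)
    flagged = np.zeros(n, dtype=bool)
    if n == 0:
        return TileOffsets(residuals, flagged, search_radius_px)

    # pairwise estimates on nominal overlap regions
    pair_shift: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            win = _overlap_windows(
                images[i].shape, images[j].shape,
                nominal_offsets[i], nominal_offsets[j],
            )
            if win is None:
                continue
            a = images[i][win[0]]
            b = images[j][win[1]]
            if min(a.shape) < min_overlap_px:
                continue
            if a.std() < feature_std_floor or b.std() < feature_std_floor:
                continue
            # shift returned registers b onto a; equals residual_j - residual_i
            shift, _, _ = phase_cross_correlation(a, b, normalization="phase")
            if np.any(np.abs(shift) > search_radius_px):
                continue
            pair_shift[(i, j)] = np.asarray(shift, dtype=float)
            pair_shift[(j, i)] = -pair_shift[(i, j)]

    neighbors: dict[int, list[int]] = {i: [] for i in range(n)}
    for (i, j) in pair_shift:
        neighbors[i].append(j)

    anchor = int(np.lexsort((
        [o[1] for o in nominal_offsets], [o[0] for o in nominal_offsets]
    ))[0])
    placed = {anchor}
    residuals[anchor] = (0, 0)
    frontier = [anchor]
    order = []
    while frontier:
        nxt = []
        for i in frontier:
            for j in sorted(neighbors[i]):
                if j not in placed:
                    placed.add(j)
                    nxt.append(j)
                    order.append(j)
        frontier = nxt
    done = {anchor}
    for j in order:
        ests = [residuals[i] + pair_shift[(i, j)]
                for i in neighbors[j] if i in done and not flagged[i]]
        done.add(j)
        if not ests:
            flagged[j] = True
            continue
        mean = np.mean(ests, axis=0)
        residuals[j] = [
            int(np.clip(_round_half_toward_zero(v), -search_radius_px,
                        search_radius_px))
            for v in mean
        ]
    for i in range(n):
        if i not in placed:
            flagged[i] = True
    return TileOffsets(residuals=residuals, flagged=flagged,
                       search_radius_px=search_radius_px)


def stitch(
    tiles: list[CompositeResult] | list[np.ndarray],
    nominal_offsets: list[tuple[int, int]],
    offsets: TileOffsets | None = None,
    blend: str = "feather",
) -> Mosaic:
    """Assemble tiles into a mosaic at nominal + residual placements.

    ``blend='feather'`` linearly feathers composite intensities across
    overlaps (weight = distance to the tile border); ``'nearest'``
    assigns every pixel to the tile whose center is closest, which makes
    reassembly of exactly-cut tiles bit-exact. Height maps always use
    nearest-tile provenance. Uncovered pixels inside the mosaic bounding
    box raise an error listing the gap.
    """
    if blend not in ("feather", "nearest"):
        raise ValueError(f"unknown blend mode {blend!r}")
    n = len(tiles)
    if n == 0:
        raise ValueError("no tiles to stitch")
    if offsets is None:
        residuals = np.zeros((n, 2), dtype=int)
    else:
        residuals = offsets.residuals
    comps = []
    heights = []
    for t in tiles:
        if isinstance(t, CompositeResult):
            comps.append(t.composite)
            heights.append(t.height_map)
        else:
            comps.append(np.asarray(t))
            heights.append(None)
    have_heights = all(h is not None for h in heights)

    pos = [
        (nominal_offsets[i][0] + int(residuals[i][0]),
         nominal_offsets[i][1] + int(residuals[i][1]))
        for i in range(n)
    ]
    y0 = min(p[0] for p in pos)
    x0 = min(p[1] for p in pos)
    y1 = max(p[0] + comps[i].shape[0] for i, p in enumerate(pos))
    x1 = max(p[1] + comps[i].shape[1] for i, p in enumerate(pos))
    H, W = y1 - y0, x1 - x0

    prov = np.full((H, W), -1, dtype=np.int32)
    best_d2 = np.full((H, W), np.inf)
    for i, (py, px) in enumerate(pos):
        h, w = comps[i].shape
        yy = np.arange(h)[:, None] - (h - 1) / 2.0
        xx = np.arange(w)[None, :] - (w - 1) / 2.0
        d2 = yy * yy + xx * xx
        sl = (slice(py - y0, py - y0 + h), slice(px - x0, px - x0 + w))
        closer = d2 < best_d2[sl]
        best_d2[sl] = np.where(closer, d2, best_d2[sl])
        prov[sl] = np.where(closer, i, prov[sl])

    # residual offsets can leave thin uncovered strips at the canvas border;
    # those are trimmed after blending, but an interior gap is an error
    # greedy: repeatedly trim the border row/col with the most gap pixels,
    # but never deeper than the largest residual offset on that axis —
    # anything beyond that is a genuine coverage error, not a border strip
    max_trim_y = int(np.abs(residuals[:, 0]).max(initial=0))
    max_trim_x = int(np.abs(residuals[:, 1]).max(initial=0))
    trims = {"top": 0, "bottom": 0, "left": 0, "right": 0}
    limits = {"top": max_trim_y, "bottom": max_trim_y,
              "left": max_trim_x, "right": max_trim_x}
    top, bottom, left, right = 0, H, 0, W
    gap = prov < 0
    while top < bottom and left < right:
        counts = {
            "top": int(gap[top, left:right].sum()),
            "bottom": int(gap[bottom - 1, left:right].sum()),
            "left": int(gap[top:bottom, left].sum()),
            "right": int(gap[top:bottom, right - 1].sum()),
        }
        open_sides = {s: c for s, c in counts.items()
                      if trims[s] < limits[s] and c > 0}
        if not open_sides:
            break
        side = max(open_sides, key=open_sides.get)
        trims[side] += 1
        if side == "top":
            top += 1
        elif side == "bottom":
            bottom -= 1
        elif side == "left":
            left += 1
        else:
            right -= 1
    uncovered = prov[top:bottom, left:right] < 0
    if uncovered.any():
        ys, xs = np.nonzero(uncovered)
        raise ValueError(
            f"tile offsets leave {uncovered.sum()} uncovered pixels inside "
            f"the mosaic (first at ({ys[0] + y0 + top}, {xs[0] + x0 + left}))"
        )

    if blend == "nearest":
        out = np.zeros((H, W), dtype=comps[0].dtype)
        for i, (py, px) in enumerate(pos):
            h, w = comps[i].shape
            sl = (slice(py - y0, py - y0 + h), slice(px - x0, px - x0 + w))
            m = prov[sl] == i
            out[sl][m] = comps[i][m]
    else:
        acc = np.zeros((H, W), dtype=np.float64)
        wsum = np.zeros((H, W), dtype=np.float64)
        for i, (py, px) in enumerate(pos):
            h, w = comps[i].shape
            wy = np.minimum(np.arange(h), np.arange(h)[::-1]) + 1.0
            wx = np.minimum(np.arange(w), np.arange(w)[::-1]) + 1.0
            wt = wy[:, None] * wx[None, :]
            sl = (slice(py - y0, py - y0 + h), slice(px - x0, px - x0 + w))
            acc[sl] += comps[i] * wt
            wsum[sl] += wt
        out = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)

    hm = None
    if have_heights:
        hm = np.zeros((H, W), dtype=heights[0].dtype)
        for i, (py, px) in enumerate(pos):
            h, w = heights[i].shape
            sl = (slice(py - y0, py - y0 + h), slice(px - x0, px - x0 + w))
            m = prov[sl] == i
            hm[sl][m] = heights[i][m]
    crop = (slice(top, bottom), slice(left, right))
    return Mosaic(
        composite=out[crop],
        height_map=hm[crop] if hm is not None else None,
        provenance=prov[crop],
        origin=(y0 + top, x0 + left),
    )
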