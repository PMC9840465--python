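"""Synthetic monolayer scenes with known ground truth.

Emulates a confluent renal epithelial monolayer imaged as tiled
z-stacks: fluid-filled domes raise patches of the cell sheet off the
plate (spherical-cap surface profile), nuclei / mitochondria /
autophagosome puncta populate separate fluorescence channels, and a
textured brightfield channel carries the cell-sheet contrast that
focus-stacking relies on. Rendering applies defocus blur whose Gaussian
sigma grows linearly with the distance between the focal plane and the
local specimen surface, followed by shot and read noise, so every
downstream stage (focus fusion, height-map segmentation, stitching,
object counting) can be validated against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ScenePars",
    "SceneGroundTruth",
    "SurfaceMap",
    "ZStack",
    "Tile",
    "generate_scene",
    "render_zstack",
    "defocus_sigma",
    "tile_mosaic",
    "random_dome_specs",
    "save_tiles",
    "load_tiles",
    "save_ground_truth",
]

# stable per-purpose stream keys (seeded as SeedSequence((seed, key)))
_STREAM_KEYS = {
    "texture": 11,
    "nuclei": 12,
    "mito": 13,
    "autophagosome": 14,
    "noise_brightfield": 21,
    "noise_nuclear": 22,
    "noise_mito": 23,
    "noise_autophagosome": 24,
}

CHANNELS = ("brightfield", "nuclear", "mito", "autophagosome")


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAM_KEYS[purpose])))


@dataclass(frozen=True)
class ScenePars:
    """Scene geometry, content densities and optics for one synthetic well.

    Dome specs are ``((cx_um, cy_um), radius_um, apex_height_um)``
    triples; the default apex used by :func:`random_dome_specs` is
    0.8 x radius, a blister-like aspect typical of epithelial fluid
    domes, and must not exceed the radius (a height field cannot
    represent an overhanging cap).
    """

    field_size_um: float = 512.0
    pixel_size_um: float = 1.0
    z_step_um: float = 5.0
    n_planes: int = 20
    n_nuclei: int = 0
    nucleus_radius_um: tuple[float, float] = (3.0, 5.0)
    dome_specs: tuple = ()
    mito_density: float = 0.0          # objects per 100 um^2
    mito_area_um2: tuple[float, float] = (0.3, 1.5)
    enlarged_fraction: float = 0.0
    enlarged_area_um2: tuple[float, float] = (3.0, 8.0)
    n_autophagosomes: int = 0
    autophagosome_area_um2: tuple[float, float] = (1.0, 12.0)
    autophagosome_areas: tuple = ()    # explicit per-punctum areas (overrides range)
    blur_rate_px_per_um: float = 0.3
    noise: tuple[float, float] = (3.0, 1.0)  # (gaussian_sd, poisson photons/unit)
    base_height_um: float = 0.0
    background: float = 150.0
    texture_amplitude: float = 25.0   # SD of the intracellular texture, counts
    cell_diameter_um: float = 12.0    # mean cell size for the boundary lattice
    cell_edge_contrast: float = 60.0  # depth of the dark cell-boundary lines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if not (0.0 <= self.enlarged_fraction <= 1.0):
            raise ValueError("enlarged_fraction must be in [0, 1]")
        if self.mito_density > 0 and self.enlarged_fraction > 0:
            if self.enlarged_area_um2[0] <= self.mito_area_um2[1]:
                raise ValueError(
                    "enlarged mitochondrion area range must lie strictly above "
                    "the regular range"
                )
        for (cx, cy), r, h in self.dome_specs:
            if r <= 0 or h <= 0:
                raise ValueError("dome radius and apex height must be positive")
            if h > r:
                raise ValueError(
                    f"dome apex {h} um exceeds radius {r} um: spherical cap "
                    "would overhang and cannot be a height field"
                )
            if not (r <= cx <= self.field_size_um - r
                    and r <= cy <= self.field_size_um - r):
                raise ValueError(f"dome at ({cx}, {cy}) r={r} does not fit the field")

    @property
    def shape_px(self) -> tuple[int, int]:
        n = self.field_size_um / self.pixel_size_um
        npx = int(round(n))
        if abs(n - npx) > 1e-9:
            raise ValueError("field_size_um must be an integer number of pixels")
        return npx, npx


@dataclass
class SurfaceMap:
    """Monolayer surface height in um above the plate."""

    height_um: np.ndarray
    base_height_um: float

    @property
    def max_height_um(self) -> float:
        return float(self.height_um.max())


@dataclass
class SceneGroundTruth:
    """Exact object-level truth for one generated scene."""

    nuclei: np.ndarray                       # (N, 2) centroids, um (x, y)
    nucleus_radii_um: np.ndarray             # (N,)
    domes: tuple                             # ((cx, cy), r_um, apex_um)
    mito_objects: pd.DataFrame               # cx_um, cy_um, area_um2, class
    autophagosomes: pd.DataFrame             # cx_um, cy_um, area_um2
    true_total_dome_area_um2: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.true_total_dome_area_um2 = float(
            sum(np.pi * r * r for _, r, _ in self.domes)
        )


@dataclass
class ZStack:
    """One channel's z-stack: planes x rows x cols, plane 0 lowest."""

    data: np.ndarray
    z_step_um: float
    pixel_size_um: float
    channel_label: str = "brightfield"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("z-stack must be planes x rows x cols")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def plane_height_um(self, k: int) -> float:
        return k * self.z_step_um


def random_dome_specs(
    n_domes: int,
    field_size_um: float,
    rng: np.random.Generator,
    radius_range_um: tuple[float, float] = (25.0, 45.0),
    apex_ratio: float = 0.8,
    margin_um: float = 5.0,
    max_tries: int = 2000,
) -> tuple:
    """Place non-overlapping domes uniformly inside the field.

    Apex height defaults to 0.8 x radius (steep, blister-like caps).
    """
    specs: list = []
    tries = 0
    while len(specs) < n_domes:
        if tries > max_tries:
            raise RuntimeError("domes: could not place requested domes in the field")
        tries += 1
        r = float(rng.uniform(*radius_range_um))
        lo, hi = r + margin_um, field_size_um - r - margin_um
        if hi <= lo:
            raise RuntimeError("domes: field too small for requested dome radius")
        cx, cy = float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))
        if all(
            np.hypot(cx - ox, cy - oy) >= r + orr + margin_um
            for (ox, oy), orr, _ in specs
        ):
            specs.append(((cx, cy), r, apex_ratio * r))
    return tuple(specs)


def field_area_of(pars: ScenePars) -> float:
    return pars.field_size_um**2


def _pixel_grid_um(pars: ScenePars) -> tuple[np.ndarray, np.ndarray]:
    n, _ = pars.shape_px
    coords = (np.arange(n) + 0.5) * pars.pixel_size_um
    return np.meshgrid(coords, coords)  # X (cols), Y (rows)


def _surface_from_domes(pars: ScenePars) -> SurfaceMap:
    X, Y = _pixel_grid_um(pars)
    h = np.full_like(X, pars.base_height_um, dtype=float)
    for (cx, cy), r, apex in pars.dome_specs:
        # spherical cap: sphere radius R = (r^2 + apex^2) / (2 apex)
        R = (r * r + apex * apex) / (2.0 * apex)
        rho2 = (X - cx) ** 2 + (Y - cy) ** 2
        inside = rho2 <= r * r
        cap = np.sqrt(np.clip(R * R - rho2, 0.0, None)) - (R - apex)
        h[inside] = np.maximum(h[inside], pars.base_height_um + cap[inside])
    return SurfaceMap(height_um=h, base_height_um=pars.base_height_um)


def _place_points(
    rng: np.random.Generator,
    n: int,
    field_size_um: float,
    min_sep_um: float,
    margin_um: float,
    label: str,
    max_tries_per_obj: int = 400,
) -> np.ndarray:
    """Uniform rejection sampling with a minimum pairwise separation."""
    pts: list[tuple[float, float]] = []
    lo, hi = margin_um, field_size_um - margin_um
    if hi <= lo and n > 0:
        raise RuntimeError(f"{label}: field too small for requested objects")
    tries = 0
    while len(pts) < n:
        if tries > max_tries_per_obj * max(n, 1):
            raise RuntimeError(
                f"{label}: could not place {n} objects with separation "
                f">= {min_sep_um} um (field too crowded)"
            )
        tries += 1
        x, y = rng.uniform(lo, hi), rng.uniform(lo, hi)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep_um**2 for px, py in pts):
            pts.append((x, y))
    return np.array(pts, dtype=float).reshape(n, 2)


def _place_sized_objects(
    rng: np.random.Generator,
    radii_um: np.ndarray,
    field_size_um: float,
    gap_um: float,
    label: str,
    max_tries_per_obj: int = 400,
) -> np.ndarray:
    """Place non-overlapping objects of given radii (largest first)."""
    n = len(radii_um)
    order = np.argsort(radii_um)[::-1]
    centers = np.zeros((n, 2), dtype=float)
    placed: list[int] = []
    tries = 0
    for idx in order:
        r = radii_um[idx]
        lo, hi = r + gap_um, field_size_um - r - gap_um
        if hi <= lo:
            raise RuntimeError(f"{label}: field too small for object radius {r}")
        while True:
            if tries > max_tries_per_obj * max(n, 1):
                raise RuntimeError(
                    f"{label}: could not place {n} objects without overlap "
                    "(field too crowded)"
                )
            tries += 1
            x, y = rng.uniform(lo, hi), rng.uniform(lo, hi)
            if all(
                np.hypot(x - centers[j, 0], y - centers[j, 1])
                >= r + radii_um[j] + gap_um
                for j in placed
            ):
                centers[idx] = (x, y)
                placed.append(idx)
                break
    return centers


def _bbox_slices(
    pars: ScenePars, cx: float, cy: float, r_um: float
) -> tuple[slice, slice]:
    n = pars.shape_px[0]
    px = pars.pixel_size_um
    x0 = max(int((cx - r_um) / px) - 1, 0)
    x1 = min(int((cx + r_um) / px) + 2, n)
    y0 = max(int((cy - r_um) / px) - 1, 0)
    y1 = min(int((cy + r_um) / px) + 2, n)
    return slice(y0, y1), slice(x0, x1)


def _raster_discs(
    pars: ScenePars, centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    X, Y = _pixel_grid_um(pars)
    mask = np.zeros(pars.shape_px, dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        sl = _bbox_slices(pars, cx, cy, r)
        mask[sl] |= (X[sl] - cx) ** 2 + (Y[sl] - cy) ** 2 <= r * r
    return mask


def _raster_ellipses(
    pars: ScenePars,
    centers: np.ndarray,
    areas_um2: np.ndarray,
    angles: np.ndarray,
    aspect: float = 2.0,
) -> np.ndarray:
    """Ellipses of given area with semi-axis ratio ``aspect`` (a/b)."""
    X, Y = _pixel_grid_um(pars)
    mask = np.zeros(pars.shape_px, dtype=bool)
    for (cx, cy), area, th in zip(centers, areas_um2, angles):
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        sl = _bbox_slices(pars, cx, cy, a)
        dx, dy = X[sl] - cx, Y[sl] - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        mask[sl] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def generate_scene(
    pars: ScenePars,
) -> tuple[SceneGroundTruth, SurfaceMap, dict[str, np.ndarray]]:
    """Build ground truth, the surface height map and sharp ideal images.

    Ideal images carry no defocus blur and no noise; they are the input
    to :func:`render_zstack`. Deterministic for a fixed ``pars.seed``.
    """
    surface = _surface_from_domes(pars)
    shape = pars.shape_px
    ideal: dict[str, np.ndarray] = {}

    # brightfield: the confluent cell sheet. Dark cell-boundary lines on a
    # Voronoi lattice (cells tile the plane, so edge contrast is present
    # everywhere at ~cell-size spacing) plus band-limited intracellular
    # texture of fixed standard deviation.
    t_rng = _rng(pars.seed, "texture")
    noise_field = t_rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise_field, 1.0, mode="reflect")
    tex /= max(tex.std(), 1e-12)
    n_cells = max(int(round(field_area_of(pars) / pars.cell_diameter_um**2)), 1)
    seeds_um = t_rng.uniform(0, pars.field_size_um, size=(n_cells, 2))
    X, Y = _pixel_grid_um(pars)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    d, _ = cKDTree(seeds_um).query(pts, k=2)
    # edge strength peaks where the two nearest cell centers are equidistant
    gap = (d[:, 1] - d[:, 0]).reshape(shape)
    edges = np.exp(-((gap / (0.15 * pars.cell_diameter_um)) ** 2))
    ideal["brightfield"] = np.clip(
        pars.background
        + pars.texture_amplitude * tex
        - pars.cell_edge_contrast * edges,
        0.0,
        None,
    ).astype(np.float64)

    # nuclei
    n_rng = _rng(pars.seed, "nuclei")
    r_lo, r_hi = pars.nucleus_radius_um
    min_sep = 2.0 * r_hi  # one nucleus diameter
    centers = _place_points(
        n_rng, pars.n_nuclei, pars.field_size_um, min_sep, r_hi + 1.0, "nuclei"
    )
    radii = n_rng.uniform(r_lo, r_hi, size=pars.n_nuclei)
    nuc_mask = _raster_discs(pars, centers, radii)
    ideal["nuclear"] = np.where(nuc_mask, 180.0, 10.0)

    # mitochondria: ellipses, a fraction enlarged (area range strictly above)
    m_rng = _rng(pars.seed, "mito")
    field_area = pars.field_size_um**2
    n_mito = int(round(pars.mito_density * field_area / 100.0))
    n_enl = int(round(n_mito * pars.enlarged_fraction))
    areas = np.concatenate(
        [
            m_rng.uniform(*pars.mito_area_um2, size=n_mito - n_enl),
            m_rng.uniform(*pars.enlarged_area_um2, size=n_enl),
        ]
    )
    classes = np.array(["regular"] * (n_mito - n_enl) + ["enlarged"] * n_enl)
    order = m_rng.permutation(n_mito)
    areas, classes = areas[order], classes[order]
    # ellipse major semi-axis bounds the footprint for overlap-free placement
    aspect = 2.0
    major_r = np.sqrt(aspect * areas / np.pi) if n_mito else np.zeros(0)
    mito_centers = _place_sized_objects(
        m_rng, major_r, pars.field_size_um, 2.0 * pars.pixel_size_um,
        "mitochondria",
    )
    angles = m_rng.uniform(0, np.pi, size=n_mito)
    mito_mask = _raster_ellipses(pars, mito_centers, areas, angles)
    ideal["mito"] = np.where(mito_mask, 160.0, 8.0)
    mito_tbl = pd.DataFrame(
        {
            "cx_um": mito_centers[:, 0] if n_mito else np.zeros(0),
            "cy_um": mito_centers[:, 1] if n_mito else np.zeros(0),
            "area_um2": areas,
            "class": classes,
        }
    )

    # autophagosome puncta: discs of explicit or range-drawn areas
    a_rng = _rng(pars.seed, "autophagosome")
    if pars.autophagosome_areas:
        a_areas = np.asarray(pars.autophagosome_areas, dtype=float)
    else:
        a_areas = a_rng.uniform(
            *pars.autophagosome_area_um2, size=pars.n_autophagosomes
        )
    n_auto = a_areas.size
    a_r = np.sqrt(a_areas / np.pi) if n_auto else np.zeros(0)
    a_centers = _place_sized_objects(
        a_rng, a_r, pars.field_size_um, 3.0 * pars.pixel_size_um,
        "autophagosomes",
    )
    auto_mask = _raster_discs(pars, a_centers, a_r)
    ideal["autophagosome"] = np.where(auto_mask, 150.0, 5.0)
    auto_tbl = pd.DataFrame(
        {
            "cx_um": a_centers[:, 0] if n_auto else np.zeros(0),
            "cy_um": a_centers[:, 1] if n_auto else np.zeros(0),
            "area_um2": a_areas,
        }
    )

    gt = SceneGroundTruth(
        nuclei=centers,
        nucleus_radii_um=radii,
        domes=tuple(pars.dome_specs),
        mito_objects=mito_tbl,
        autophagosomes=auto_tbl,
    )
    return gt, surface, ideal


def defocus_sigma(
    z_plane_um: float, height_um: float | np.ndarray, blur_rate_px_per_um: float
) -> float | np.ndarray:
    """Gaussian blur sigma (px) at focal plane z for surface height h."""
    return blur_rate_px_per_um * np.abs(z_plane_um - height_um)


def _sigma_bins(max_sigma: float) -> np.ndarray:
    """Representative blur sigmas: fine steps near focus, geometric beyond.

    Blur is quantized to these values when rendering; the mapping is
    monotone in the true sigma so focus ordering across planes is
    preserved.
    """
    fine = np.arange(0.0, 2.0 + 1e-9, 0.125)
    vals = list(fine)
    s = 2.0
    while s < max_sigma:
        s *= 1.25
        vals.append(s)
    return np.asarray(vals)


def render_zstack(
    ideal_image: np.ndarray,
    surface: SurfaceMap,
    pars: ScenePars,
    channel_label: str = "brightfield",
    add_noise: bool = True,
) -> ZStack:
    """Render a z-stack with height-dependent defocus blur and noise.

    Per-pixel blur sigma is ``blur_rate_px_per_um * |z_plane - height|``
    (quantized to a monotone sigma ladder for speed); shot (Poisson) and
    read (Gaussian) noise are applied after blurring. The focal plane
    closest to the local surface height is always the sharpest.
    """
    if ideal_image.shape != surface.height_um.shape:
        raise ValueError("ideal image and surface map must share geometry")
    if channel_label not in CHANNELS:
        raise ValueError(f"unknown channel {channel_label!r}")
    z_top = (pars.n_planes - 1) * pars.z_step_um
    if surface.max_height_um > z_top + 1e-9:
        raise ValueError(
            f"stack of {pars.n_planes} planes x {pars.z_step_um} um does not "
            f"cover max surface height {surface.max_height_um} um"
        )

    h = surface.height_um
    max_sigma = float(defocus_sigma(0.0, h.max() + z_top, pars.blur_rate_px_per_um))
    bins = _sigma_bins(max_sigma + 1.0)
    # blurred library, computed lazily per used bin
    blurred: dict[int, np.ndarray] = {}

    def _blur(idx: int) -> np.ndarray:
        if idx not in blurred:
            s = bins[idx]
            blurred[idx] = (
                ideal_image
                if s == 0.0
                else ndimage.gaussian_filter(ideal_image, s, mode="reflect")
            )
        return blurred[idx]

    planes = np.empty((pars.n_planes,) + ideal_image.shape, dtype=np.float64)
    for k in range(pars.n_planes):
        z = k * pars.z_step_um
        sig = defocus_sigma(z, h, pars.blur_rate_px_per_um)
        idx = np.searchsorted(bins, sig, side="left")
        # snap to nearest bin below/above, preferring the closer one
        idx = np.clip(idx, 0, len(bins) - 1)
        below = np.clip(idx - 1, 0, len(bins) - 1)
        choose_below = np.abs(bins[below] - sig) <= np.abs(bins[idx] - sig)
        idx = np.where(choose_below, below, idx)
        out = np.empty_like(ideal_image)
        for b in np.unique(idx):
            m = idx == b
            out[m] = _blur(int(b))[m]
        planes[k] = out

    if add_noise:
        gaussian_sd, poisson_scale = pars.noise
        n_rng = _rng(pars.seed, f"noise_{channel_label}")
        if poisson_scale > 0:
            planes = n_rng.poisson(np.clip(planes, 0, None) * poisson_scale) / poisson_scale
        if gaussian_sd > 0:
            planes = planes + n_rng.normal(0.0, gaussian_sd, size=planes.shape)
    planes = np.clip(planes, 0.0, None).astype(np.float32)
    return ZStack(
        data=planes,
        z_step_um=pars.z_step_um,
        pixel_size_um=pars.pixel_size_um,
        channel_label=channel_label,
    )


@dataclass
class Tile:
    """One grid tile of a stack with its nominal placement in the mosaic."""

    stack: ZStack
    nominal_offset: tuple[int, int]  # (y, x) px of tile origin in the mosaic
    grid_index: tuple[int, int]      # (row, col)
    jitter: tuple[int, int] = (0, 0)  # actual cut position minus nominal


def _tile_geometry(dim: int, n: int, overlap_fraction: float) -> tuple[int, int]:
    """Solve tile size and stride for exact coverage; error when non-integer."""
    t_f = dim / (1.0 + (n - 1) * (1.0 - overlap_fraction))
    t = int(round(t_f))
    stride_f = t * (1.0 - overlap_fraction)
    stride = int(round(stride_f))
    if n == 1:
        return dim, dim
    if abs(t_f - t) > 1e-9 or abs(stride_f - stride) > 1e-9 or (
        (n - 1) * stride + t != dim
    ):
        # suggest the nearest image dimension with integral geometry
        for delta in range(1, 65):
            for cand in (dim - delta, dim + delta):
                c_f = cand / (1.0 + (n - 1) * (1.0 - overlap_fraction))
                if (
                    abs(c_f - round(c_f)) < 1e-9
                    and abs(c_f * (1 - overlap_fraction)
                            - round(c_f * (1 - overlap_fraction))) < 1e-9
                ):
                    raise ValueError(
                        f"grid of {n} tiles with overlap {overlap_fraction} does "
                        f"not divide size {dim} into integer tiles; nearest valid "
                        f"size is {cand}"
                    )
        raise ValueError(
            f"grid of {n} tiles with overlap {overlap_fraction} does not divide "
            f"size {dim} into integer tiles"
        )
    return t, stride


def random_tile_jitter(
    full_stack: ZStack,
    grid: tuple[int, int],
    overlap_fraction: float,
    max_px: int,
    rng: np.random.Generator,
    anchor_zero: bool = True,
) -> np.ndarray:
    """Sample integer stage jitter per tile, clipped to stay in bounds.

    Returns an array of shape (rows, cols, 2); with ``anchor_zero`` the
    top-left tile keeps zero jitter so recovered offsets are directly
    comparable (registration anchors that tile).
    """
    rows, cols = grid
    _, H, W = full_stack.data.shape
    th, sy = _tile_geometry(H, rows, overlap_fraction)
    tw, sx = _tile_geometry(W, cols, overlap_fraction)
    jitter = np.zeros((rows, cols, 2), dtype=int)
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * sy, c * sx
            jy = int(rng.integers(-max_px, max_px + 1))
            jx = int(rng.integers(-max_px, max_px + 1))
            jitter[r, c, 0] = np.clip(jy, -y0, H - th - y0)
            jitter[r, c, 1] = np.clip(jx, -x0, W - tw - x0)
    if anchor_zero:
        jitter[0, 0] = (0, 0)
    return jitter


def tile_mosaic(
    full_stack: ZStack,
    grid: tuple[int, int],
    overlap_fraction: float,
    jitter: np.ndarray | None = None,
) -> list[Tile]:
    """Cut a full-field stack into an overlapping grid of tiles.

    Adjacent tiles share ``overlap_fraction`` of their width/height and
    nominal offsets are recorded so that pasting the tiles back at those
    offsets reproduces the full stack exactly. Optional integer
    ``jitter`` of shape (rows, cols, 2) displaces each cut (but not the
    recorded nominal offset), emulating imperfect stage positioning.
    """
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    rows, cols = grid
    _, H, W = full_stack.data.shape
    th, sy = _tile_geometry(H, rows, overlap_fraction)
    tw, sx = _tile_geometry(W, cols, overlap_fraction)
    if jitter is None:
        jitter = np.zeros((rows, cols, 2), dtype=int)
    jitter = np.asarray(jitter, dtype=int)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * sy, c * sx
            jy, jx = int(jitter[r, c, 0]), int(jitter[r, c, 1])
            yc, xc = y0 + jy, x0 + jx
            if not (0 <= yc <= H - th and 0 <= xc <= W - tw):
                raise ValueError(
                    f"jitter ({jy}, {jx}) pushes tile ({r}, {c}) out of bounds"
                )
            sub = ZStack(
                data=full_stack.data[:, yc : yc + th, xc : xc + tw].copy(),
                z_step_um=full_stack.z_step_um,
                pixel_size_um=full_stack.pixel_size_um,
                channel_label=full_stack.channel_label,
            )
            tiles.append(
                Tile(stack=sub, nominal_offset=(y0, x0), grid_index=(r, c),
                     jitter=(jy, jx))
            )
    return tiles


# ---------------------------------------------------------------------------
# on-disk layout: one multi-page TIFF per tile per channel + sidecar metadata


def save_tiles(outdir, tiles_by_channel: dict[str, list[Tile]],
               pars: ScenePars, grid: tuple[int, int],
               overlap_fraction: float) -> None:
    """Write per-tile multi-page TIFFs (z ascending) plus a JSON metadata record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel, tiles in tiles_by_channel.items():
        for t in tiles:
            r, c = t.grid_index
            tifffile.imwrite(
                outdir / f"tile_r{r}_c{c}_{channel}.tif",
                t.stack.data.astype(np.float32),
            )
    meta = {
        "pixel_size_um": pars.pixel_size_um,
        "z_step_um": pars.z_step_um,
        "n_planes": pars.n_planes,
        "grid": list(grid),
        "overlap_fraction": overlap_fraction,
        "seed": pars.seed,
        "channels": sorted(tiles_by_channel),
        "nominal_offsets": {
            f"{t.grid_index[0]},{t.grid_index[1]}": list(t.nominal_offset)
            for t in next(iter(tiles_by_channel.values()))
        },
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_tiles(indir, channel: str) -> tuple[list[Tile], dict]:
    """Read tiles written by :func:`save_tiles` for one channel."""
    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    tiles = []
    rows, cols = meta["grid"]
    for r in range(rows):
        for c in range(cols):
            data = tifffile.imread(indir / f"tile_r{r}_c{c}_{channel}.tif")
            if data.ndim == 2:
                data = data[None]
            stack = ZStack(
                data=data.astype(np.float32),
                z_step_um=meta["z_step_um"],
                pixel_size_um=meta["pixel_size_um"],
                channel_label=channel,
            )
            off = meta["nominal_offsets"][f"{r},{c}"]
            tiles.append(Tile(stack=stack, nominal_offset=tuple(off),
                              grid_index=(r, c)))
    return tiles, meta


def save_ground_truth(outdir, gt: SceneGroundTruth) -> None:
    """Sidecar CSV of all ground-truth objects (class, centroid, size, height)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (x, y), r in zip(gt.nuclei, gt.nucleus_radii_um):
        rows.append(("nucleus", x, y, np.pi * r * r, ""))
    for (cx, cy), r, apex in gt.domes:
        rows.append(("dome", cx, cy, np.pi * r * r, apex))
    for _, m in gt.mito_objects.iterrows():
        rows.append((f"mito_{m['class']}", m["cx_um"], m["cy_um"], m["area_um2"], ""))
    for _, a in gt.autophagosomes.iterrows():
        rows.append(("autophagosome", a["cx_um"], a["cy_um"], a["area_um2"], ""))
    pd.DataFrame(
        rows, columns=["class", "cx_um", "cy_um", "area_um2", "apex_height_um"]
    ).to_csv(outdir / "ground_truth.csv", index=False)
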