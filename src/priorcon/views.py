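"""Prior-guided view construction.

The redness prior picks the pixel with the maximum CIELAB a* (red-green)
response as the most pathology-suspect location; a fixed square crop
around it is the *prior view*. The same box decides which of the nine
jigsaw tiles of the *distorted view* keep appearance-preserving
transforms, and which region is zeroed to form the *within-instance
negative* (WIN) view.

Coordinates are 0-based, half-open ``(top, left, bottom, right)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from scipy import ndimage

from .seeding import rng_for
from .transforms import TransformSet, default_transform_set, resize_image


@dataclass(frozen=True)
class PriorBox:
    """Square prior-view crop geometry."""

    center: tuple[int, int]
    side: int
    box: tuple[int, int, int, int]  # (top, left, bottom, right), half-open

    def __post_init__(self):
        top, left, bottom, right = self.box
        if not (bottom - top == right - left == self.side):
            raise ValueError("box must be square with the declared side")
        if top < 0 or left < 0:
            raise ValueError("box must lie inside the image")


@dataclass
class ViewBundle:
    """The three views of one image plus provenance."""

    prior_view: np.ndarray  # out_size x out_size x 3, float [0,1]
    distorted_tiles: list[np.ndarray]  # 9 tiles, permuted order
    tile_permutation: np.ndarray  # grid index -> position in distorted_tiles
    shared_tile_mask: np.ndarray  # 9 bools in fixed row-major grid order
    win_view: np.ndarray
    prior_box: PriorBox
    seed: int


def to_cielab(image: np.ndarray) -> np.ndarray:
    """sRGB (8-bit, D65) to CIELAB; returns an HxWx3 float array (L*, a*, b*)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB, got shape {image.shape}")
    return rgb2lab(image.astype(np.float64) / 255.0)


def locate_prior_center(image: np.ndarray, presmooth_sigma: float = 0.0) -> tuple[int, int]:
    """Pixel with the maximum a* response; ties break first in row-major order.

    ``presmooth_sigma > 0`` applies a Gaussian filter to the a* channel
    before the argmax; the default 0 is the raw single-pixel maximum.
    """
    if presmooth_sigma < 0:
        raise ValueError("presmooth_sigma must be >= 0")
    a_star = to_cielab(image)[..., 1]
    if presmooth_sigma > 0:
        a_star = ndimage.gaussian_filter(a_star, presmooth_sigma)
    flat_idx = int(np.argmax(a_star))
    return tuple(int(v) for v in np.unravel_index(flat_idx, a_star.shape))


def prior_box_at(center: tuple[int, int], side: int, image_shape: tuple[int, int]) -> PriorBox:
    """Square box of given side centred at ``center``, clamped inside the image."""
    h, w = image_shape[:2]
    if side > min(h, w):
        raise ValueError(f"crop side {side} exceeds image size {h}x{w}")
    top = int(np.clip(center[0] - side // 2, 0, h - side))
    left = int(np.clip(center[1] - side // 2, 0, w - side))
    return PriorBox(center=center, side=side, box=(top, left, top + side, left + side))


def extract_prior_view(
    image: np.ndarray,
    crop_side: int,
    out_size: int = 120,
    seed: int = 0,
    transform: TransformSet | None = None,
    presmooth_sigma: float = 0.0,
) -> tuple[np.ndarray, PriorBox]:
    """Crop the redness-prior square, resize to ``out_size``, apply a T_p draw."""
    center = locate_prior_center(image, presmooth_sigma)
    pbox = prior_box_at(center, crop_side, image.shape[:2])
    top, left, bottom, right = pbox.box
    crop = np.asarray(image, dtype=np.float64)[top:bottom, left:right] / 255.0
    view = resize_image(crop, out_size)
    tset = default_transform_set("T_p") if transform is None else transform
    view = tset.apply(view, rng_for(seed, "prior", "T_p"))
    return view, pbox


def _grid_edges(n: int) -> list[int]:
    return [round(i * n / 3) for i in range(4)]


def shared_tiles(prior_box: PriorBox, image_shape: tuple[int, int],
                 min_overlap_frac: float = 0.0) -> np.ndarray:
    """Which of the 9 grid cells overlap the prior box (row-major order).

    A tile counts as shared when the pixel intersection of its cell with
    the prior box exceeds ``min_overlap_frac`` of the cell area (default:
    any nonzero overlap).
    """
    h, w = image_shape[:2]
    t, l, b, r = prior_box.box
    rows, cols = _grid_edges(h), _grid_edges(w)
    mask = np.zeros(9, dtype=bool)
    for i in range(3):
        for j in range(3):
            it = max(t, rows[i]); ib = min(b, rows[i + 1])
            jl = max(l, cols[j]); jr = min(r, cols[j + 1])
            inter = max(0, ib - it) * max(0, jr - jl)
            area = (rows[i + 1] - rows[i]) * (cols[j + 1] - cols[j])
            mask[3 * i + j] = inter > min_overlap_frac * area
    return mask


def make_distorted_view(
    image: np.ndarray,
    prior_box: PriorBox,
    seed: int = 0,
    tile_size: int = 40,
    t_p: TransformSet | None = None,
    t_d: TransformSet | None = None,
    min_overlap_frac: float = 0.0,
    permute: bool = True,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Nine-tile jigsaw: shared tiles get T_p draws, the rest T_d draws.

    Returns ``(tiles, shared_tile_mask, permutation)`` where ``tiles`` is in
    permuted order and ``permutation[g]`` is the position of grid cell ``g``.
    """
    h, w = image.shape[:2]
    if h < 3 or w < 3:
        raise ValueError("image too small for a 3x3 tile grid")
    t, l, b, r = prior_box.box
    if b <= t or r <= l or b > h or r > w:
        raise ValueError(f"degenerate or out-of-bounds prior box {prior_box.box}")
    t_p = default_transform_set("T_p") if t_p is None else t_p
    t_d = default_transform_set("T_d") if t_d is None else t_d
    shared = shared_tiles(prior_box, (h, w), min_overlap_frac)
    img = np.asarray(image, dtype=np.float64) / 255.0
    rows, cols = _grid_edges(h), _grid_edges(w)
    tiles_grid = []
    for i in range(3):
        for j in range(3):
            g = 3 * i + j
            tile = img[rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
            tile = resize_image(tile, tile_size)
            tset = t_p if shared[g] else t_d
            tile = tset.apply(tile, rng_for(seed, "tile", g, tset.set_id))
            tiles_grid.append(tile)
    if permute:
        perm = rng_for(seed, "jigsaw-perm").permutation(9)
    else:
        perm = np.arange(9)
    tiles = [None] * 9
    for g in range(9):
        tiles[perm[g]] = tiles_grid[g]
    return tiles, shared, perm


def make_win_view(
    image: np.ndarray,
    prior_box: PriorBox,
    seed: int = 0,
    out_size: int = 120,
    transform: TransformSet | None = None,
) -> np.ndarray:
    """Zero the prior-box region, resize, apply a T_win draw.

    The zeroed region removes the suspected-pathology content, leaving a
    pathology-ignorant view of the same instance.
    """
    img = np.asarray(image, dtype=np.float64) / 255.0
    t, l, b, r = prior_box.box
    masked = img.copy()
    masked[t:b, l:r] = 0.0
    if (b - t) >= img.shape[0] and (r - l) >= img.shape[1]:
        warnings.warn("prior box covers the whole image; WIN view is all zeros")
    view = resize_image(masked, out_size)
    tset = default_transform_set("T_win") if transform is None else transform
    return tset.apply(view, rng_for(seed, "win", "T_win"))


def build_view_bundle(
    image: np.ndarray,
    crop_side: int,
    seed: int,
    out_size: int = 120,
    tile_size: int = 40,
    t_p: TransformSet | None = None,
    t_d: TransformSet | None = None,
    t_win: TransformSet | None = None,
    min_overlap_frac: float = 0.0,
    prior_center: tuple[int, int] | None = None,
) -> ViewBundle:
    """Construct all three views of one image with shared provenance.

    ``prior_center`` overrides the a*-argmax (used for cached centers and
    for the random-crop baseline); the three views then all share the same
    prior box.
    """
    if prior_center is None:
        prior_center = locate_prior_center(image)
    pbox = prior_box_at(prior_center, crop_side, image.shape[:2])
    top, left, bottom, right = pbox.box
    crop = np.asarray(image, dtype=np.float64)[top:bottom, left:right] / 255.0
    tset_p = default_transform_set("T_p") if t_p is None else t_p
    prior = tset_p.apply(resize_image(crop, out_size), rng_for(seed, "prior", "T_p"))
    tiles, shared, perm = make_distorted_view(
        image, pbox, seed=seed, tile_size=tile_size, t_p=tset_p, t_d=t_d,
        min_overlap_frac=min_overlap_frac,
    )
    win = make_win_view(image, pbox, seed=seed, out_size=out_size, transform=t_win)
    return ViewBundle(
        prior_view=prior,
        distorted_tiles=tiles,
        tile_permutation=perm,
        shared_tile_mask=shared,
        win_view=win,
        prior_box=pbox,
        seed=seed,
    )
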