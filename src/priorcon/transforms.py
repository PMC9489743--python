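"""Stochastic image transform sets for view construction.

Three named sets mirror the roles the views play:

* ``T_p`` — appearance-preserving: flips, axis-aligned rotations, mild
  photometric jitter (±10%), a small random resized crop (scale 0.8–1.0).
  Applied to the prior view and to jigsaw tiles it overlaps, so that the
  mutual (suspected-pathology) content differs only by transforms drawn
  from the same distribution.
* ``T_d`` — purposefully degrading: strong Gaussian blur, heavy colour
  jitter (±40%), probabilistic grayscale, random cutout. Applied to
  non-shared jigsaw tiles to discourage learning their content.
* ``T_win`` — flips plus mild jitter only, applied to the masked
  within-instance-negative image.

All operators map float RGB in [0, 1] to float RGB in [0, 1] of the same
size and draw every random parameter from the supplied generator, so a
transform application is fully determined by ``(set_id, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


def resize_image(img: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize of an HxWx3 float image to out_size x out_size."""
    if img.shape[0] == out_size and img.shape[1] == out_size:
        return img
    return _sk_resize(
        img, (out_size, out_size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


# --- individual operators --------------------------------------------------

def _op_hflip(img, rng, p=0.5):
    return img[:, ::-1] if rng.random() < p else img


def _op_vflip(img, rng, p=0.5):
    return img[::-1] if rng.random() < p else img


def _op_rot90(img, rng):
    k = int(rng.integers(0, 4))
    return np.rot90(img, k) if k else img


def _op_color_jitter(img, rng, strength=0.1):
    out = img
    b = 1.0 + rng.uniform(-strength, strength)
    out = out * b
    c = 1.0 + rng.uniform(-strength, strength)
    mean = out.mean()
    out = (out - mean) * c + mean
    s = 1.0 + rng.uniform(-strength, strength)
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * s
    return np.clip(out, 0.0, 1.0)


def _op_random_resized_crop(img, rng, scale_min=0.8, scale_max=1.0):
    h, w = img.shape[:2]
    s = rng.uniform(scale_min, scale_max)
    ch, cw = max(1, int(round(h * s))), max(1, int(round(w * s)))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    crop = img[top : top + ch, left : left + cw]
    return resize_image(crop, h) if h == w else _sk_resize(
        crop, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def _op_gaussian_blur(img, rng, sigma_min=1.0, sigma_max=3.0):
    sigma = rng.uniform(sigma_min, sigma_max)
    return ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))


def _op_grayscale(img, rng, p=0.3):
    if rng.random() < p:
        gray = img.mean(axis=2, keepdims=True)
        return np.repeat(gray, 3, axis=2)
    return img


def _op_cutout(img, rng, frac=0.3):
    h, w = img.shape[:2]
    ch, cw = max(1, int(h * frac)), max(1, int(w * frac))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    out = img.copy()
    out[top : top + ch, left : left + cw] = 0.0
    return out


_OPS = {
    "hflip": _op_hflip,
    "vflip": _op_vflip,
    "rot90": _op_rot90,
    "color_jitter": _op_color_jitter,
    "random_resized_crop": _op_random_resized_crop,
    "gaussian_blur": _op_gaussian_blur,
    "grayscale": _op_grayscale,
    "cutout": _op_cutout,
}


@dataclass(frozen=True)
class TransformSet:
    """An ordered list of stochastic operators identified by a set id."""

    set_id: str  # one of {"T_p", "T_d", "T_win"}
    op_list: tuple[tuple[str, dict[str, Any]], ...] = field(default_factory=tuple)

    def __post_init__(self):
        for name, _ in self.op_list:
            if name not in _OPS:
                raise ValueError(f"unknown transform op {name!r}; allowed: {sorted(_OPS)}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Apply all ops in order; float [0,1] in, float [0,1] out, same size."""
        out = np.asarray(img, dtype=np.float64)
        for name, kwargs in self.op_list:
            out = _OPS[name](out, rng, **kwargs)
        return np.clip(out, 0.0, 1.0)

    @classmethod
    def from_config(cls, set_id: str, ops: list) -> "TransformSet":
        parsed = []
        for entry in ops:
            if isinstance(entry, str):
                parsed.append((entry, {}))
            else:
                (name, kwargs), = entry.items()
                parsed.append((name, dict(kwargs or {})))
        return cls(set_id=set_id, op_list=tuple(parsed))


def default_transform_set(set_id: str) -> TransformSet:
    if set_id == "T_p":
        ops = (
            ("hflip", {}),
            ("vflip", {}),
            ("rot90", {}),
            ("color_jitter", {"strength": 0.1}),
            ("random_resized_crop", {"scale_min": 0.8, "scale_max": 1.0}),
        )
    elif set_id == "T_d":
        ops = (
            ("gaussian_blur", {"sigma_min": 1.0, "sigma_max": 3.0}),
            ("color_jitter", {"strength": 0.4}),
            ("grayscale", {"p": 0.3}),
            ("cutout", {"frac": 0.3}),
        )
    elif set_id == "T_win":
        ops = (
            ("hflip", {}),
            ("vflip", {}),
            ("color_jitter", {"strength": 0.1}),
        )
    else:
        raise ValueError(f"unknown transform set id {set_id!r}")
    return TransformSet(set_id=set_id, op_list=ops)


def identity_transform_set(set_id: str) -> TransformSet:
    """A no-op set, used for deterministic evaluation-time views."""
    return TransformSet(set_id=set_id, op_list=())
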