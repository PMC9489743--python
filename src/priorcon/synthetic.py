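"""Seeded synthetic capsule-endoscopy-like scenes with ground truth.

Real small-bowel frames mix many local factors: mucosal texture, bubbles,
specular highlights, illumination fall-off, and — occasionally — a small
local pathology. This module emulates that multi-factor structure at desk
scale: a low-frequency pink-tan mucosal background, nuisance elements that
only push pixels toward white (so they can never out-redden a lesion), and
one of three lesion phenotypes with a per-scene ground-truth mask:

``red_lesion``
    a compact disc with a raised CIELAB a* (red-green) response, the
    phenotype the redness prior targets;
``pale_bump``
    a pale, slightly yellowish raised disc with a shaded rim — a lesion
    whose signature is shape/lightness rather than redness;
``vascular_streak``
    a thin elongated reddish streak, mimicking an angiectasia-like vessel
    pattern.

Every scene is a pure function of its :class:`SceneSpec` (including the
seed), which makes all downstream recovery tests exactly reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

from .seeding import child_seed

LesionClass = Literal["none", "red_lesion", "pale_bump", "vascular_streak"]

LESION_CLASSES: tuple[str, ...] = ("none", "red_lesion", "pale_bump", "vascular_streak")

MANIFEST_COLUMNS = ["filename", "class_label", "center_row", "center_col", "seed"]


class SceneSpec(BaseModel):
    """Full parameterisation of one synthetic scene."""

    model_config = ConfigDict(extra="forbid")

    image_size: int = 128
    lesion_class: LesionClass = "red_lesion"
    lesion_radius_range: tuple[int, int] = (8, 14)
    lesion_redness_gain: float = 1.0
    n_bubbles: int = 6
    illum_gradient_strength: float = 0.35
    texture_scale: int = 8
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneSpec":
        if self.image_size < 48:
            raise ValueError("image_size must be >= 48 (room for a 3x3 tile grid)")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        if hi >= self.image_size / 2:
            raise ValueError("lesion_radius_range max must be < image_size/2")
        if self.lesion_class == "red_lesion" and self.lesion_redness_gain <= 0:
            raise ValueError("lesion_redness_gain must be > 0 for red_lesion")
        if not 0.0 <= self.illum_gradient_strength <= 1.0:
            raise ValueError("illum_gradient_strength must lie in [0, 1]")
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be >= 0")
        if self.texture_scale < 1:
            raise ValueError("texture_scale must be >= 1")
        return self

    def to_json(self) -> str:
        return json.dumps(self.model_dump())

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        return cls.model_validate(json.loads(text))


class SceneRecord(BaseModel):
    """A rendered scene plus its ground truth."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    image: np.ndarray  # H x W x 3 uint8
    lesion_mask: np.ndarray  # H x W bool
    lesion_center: tuple[int, int] | None
    class_label: str
    spec: SceneSpec


def _soft_disc(size: int, center: tuple[float, float], radius: float, softness: float = 1.5):
    rr, cc = np.mgrid[0:size, 0:size]
    d = np.hypot(rr - center[0], cc - center[1])
    return 1.0 / (1.0 + np.exp((d - radius) / softness))


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    noise = rng.standard_normal((size, size))
    tex = ndimage.gaussian_filter(noise, spec.texture_scale)
    tex = (tex - tex.mean()) / (tex.std() + 1e-9)
    t = 0.5 + 0.18 * tex  # texture modulation in [~0.1, ~0.9]
    img = np.empty((size, size, 3))
    img[..., 0] = 0.72 + 0.16 * t
    img[..., 1] = 0.42 + 0.14 * t
    img[..., 2] = 0.38 + 0.12 * t
    return img


def _add_illumination(img: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    if strength <= 0:
        return img
    size = img.shape[0]
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[0:size, 0:size]
    ramp = (np.cos(theta) * rr + np.sin(theta) * cc) / size  # in [-1, 1]
    ramp = (ramp - ramp.min()) / (ramp.max() - ramp.min() + 1e-12)
    gain = 1.0 - strength * 0.5 + strength * 0.5 * ramp  # purely multiplicative
    return img * gain[..., None]


def _add_bubbles(img: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    # bubbles/speculars push pixels toward white, which lowers chroma and can
    # therefore never create a redder point than the lesion interior
    size = img.shape[0]
    out = img.copy()
    for _ in range(n):
        r = rng.uniform(2, 6)
        center = rng.uniform(r, size - r, size=2)
        disc = _soft_disc(size, (center[0], center[1]), r, softness=0.8)
        ring = disc * (1 - _soft_disc(size, (center[0], center[1]), max(r - 1.8, 0.5), 0.8))
        w = (0.55 * ring + 0.25 * disc)[..., None]
        out = out + w * (1.0 - out)
    return out


# pathologies co-occur with globally shifted mucosal tone (inflamed frames
# look redder overall, lymphangiectasia-like frames paler); the shift keeps
# classes non-degenerate in pixel space while the lesion stays the local cue
_CLASS_TONE = {
    "none": (0.0, 0.0, 0.0),
    "red_lesion": (0.035, -0.02, -0.01),
    "pale_bump": (0.03, 0.045, 0.03),
    "vascular_streak": (-0.025, -0.01, 0.025),
}


def _apply_class_tone(img: np.ndarray, lesion_class: str) -> np.ndarray:
    return img + np.asarray(_CLASS_TONE[lesion_class])


def _lesion_geometry(spec: SceneSpec, rng: np.random.Generator):
    size = spec.image_size
    lo, hi = spec.lesion_radius_range
    radius = rng.uniform(lo, hi)
    margin = hi + 4
    center = rng.uniform(margin, size - margin, size=2)
    return center, radius


def _render_red_lesion(img, spec, rng):
    center, radius = _lesion_geometry(spec, rng)
    soft = _soft_disc(spec.image_size, tuple(center), radius)
    g = spec.lesion_redness_gain
    img = img.copy()
    img[..., 0] += 0.22 * g * soft
    img[..., 1] -= 0.20 * g * soft
    img[..., 2] -= 0.08 * g * soft
    mask = soft > 0.5
    return img, mask, (int(round(center[0])), int(round(center[1])))


def _render_pale_bump(img, spec, rng):
    center, radius = _lesion_geometry(spec, rng)
    size = spec.image_size
    soft = _soft_disc(size, tuple(center), radius)
    rim = soft * (1 - _soft_disc(size, tuple(center), radius * 0.55))
    img = img.copy()
    # pale, slightly yellow interior with a darker rim (pseudo-3d shading)
    img[..., 0] += 0.16 * soft
    img[..., 1] += 0.22 * soft
    img[..., 2] += 0.10 * soft
    img -= 0.15 * rim[..., None]
    mask = soft > 0.5
    return img, mask, (int(round(center[0])), int(round(center[1])))


def _render_vascular_streak(img, spec, rng):
    size = spec.image_size
    lo, hi = spec.lesion_radius_range
    length = rng.uniform(2.2 * lo, 2.2 * hi)
    theta = rng.uniform(0, np.pi)
    margin = length / 2 + 6
    center = rng.uniform(margin, size - margin, size=2)
    t = np.linspace(-0.5, 0.5, 80)
    curve = rng.uniform(-0.25, 0.25)
    rows = center[0] + length * (t * np.cos(theta) - curve * (t**2 - 0.25) * np.sin(theta))
    cols = center[1] + length * (t * np.sin(theta) + curve * (t**2 - 0.25) * np.cos(theta))
    canvas = np.zeros((size, size))
    ri = np.clip(np.round(rows).astype(int), 0, size - 1)
    ci = np.clip(np.round(cols).astype(int), 0, size - 1)
    canvas[ri, ci] = 1.0
    soft = ndimage.gaussian_filter(canvas, 1.3)
    soft = soft / (soft.max() + 1e-12)
    img = img.copy()
    img[..., 0] += 0.20 * soft
    img[..., 1] -= 0.16 * soft
    img[..., 2] -= 0.06 * soft
    mask = soft > 0.25
    center_px = (int(ri[len(ri) // 2]), int(ci[len(ci) // 2]))
    return img, mask, center_px


_RENDERERS = {
    "red_lesion": _render_red_lesion,
    "pale_bump": _render_pale_bump,
    "vascular_streak": _render_vascular_streak,
}


def generate_scene(spec: SceneSpec) -> SceneRecord:
    """Render one scene deterministically from its spec.

    The lesion (if any) is composited before the nuisance factors so that
    illumination and bubbles act on lesion and background alike; nuisance
    factors are constructed to be chroma-reducing, so for ``red_lesion``
    scenes the global a* maximum stays inside the lesion.
    """
    rng = np.random.default_rng(spec.seed)
    img = _apply_class_tone(_background(spec, rng), spec.lesion_class)
    if spec.lesion_class == "none":
        mask = np.zeros((spec.image_size, spec.image_size), dtype=bool)
        center = None
    else:
        img, mask, center = _RENDERERS[spec.lesion_class](img, spec, rng)
    img = _add_illumination(img, spec.illum_gradient_strength, rng)
    img = _add_bubbles(img, spec.n_bubbles, rng)
    img_u8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    return SceneRecord(
        image=img_u8,
        lesion_mask=mask,
        lesion_center=center,
        class_label=spec.lesion_class,
        spec=spec,
    )


def _class_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    for cls in class_mix:
        if cls not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {cls!r}")
    # largest-remainder apportionment
    raw = {c: n * p for c, p in class_mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_dataset(
    spec_template: SceneSpec,
    n: int,
    class_mix: dict[str, float],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write ``n`` scene PNGs plus a CSV manifest; returns the manifest.

    Per-scene seeds are derived from ``spec_template.seed`` and the scene
    index, so re-running with the same template reproduces the dataset
    byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = _class_counts(n, class_mix)
    rows = []
    idx = 0
    for cls in sorted(counts):
        for _ in range(counts[cls]):
            seed = child_seed(spec_template.seed, "scene", idx)
            spec = spec_template.model_copy(update={"lesion_class": cls, "seed": seed})
            rec = generate_scene(spec)
            fname = f"scene_{idx:04d}.png"
            Image.fromarray(rec.image).save(out_dir / fname)
            cr, cc = rec.lesion_center if rec.lesion_center is not None else ("", "")
            rows.append({
                "filename": fname,
                "class_label": cls,
                "center_row": cr,
                "center_col": cc,
                "seed": seed,
            })
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
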