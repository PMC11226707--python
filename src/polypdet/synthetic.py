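"""Synthetic colonoscopy-like scenes with exact ground truth.

Scenes emulate the stated characteristics of clinical colonoscopy frames:
a reddish mucosal background with a radial vignette, curved haustral-fold
streaks and sensor noise; one to four polyps per image rendered as rotated
ellipses with Gaussian-feathered borders, a luminance offset controlled by a
``contrast`` parameter, and optional specular highlights.  The ground-truth
box of a polyp is the tight bounding box of its rendered support, so labels
are exact by construction.

This generator exercises the low-contrast / small-object regime the detector
targets; it does not attempt photorealistic endoscopy (no depth, no motion
blur, no instrument artefacts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .data import LabeledImage, split_dataset, write_label_file
from .loss import Box

__all__ = ["SceneSpec", "BackgroundSpec", "generate_scene", "generate_dataset",
           "PRESETS"]


@dataclass(frozen=True)
class BackgroundSpec:
    base_hue: tuple[int, int, int] = (168, 92, 84)     # mucosal pink, RGB
    vignette_strength: float = 0.55
    fold_count: int = 3
    noise_sd: float = 6.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one generated scene.

    ``contrast`` in (0, 1] scales the polyp/background luminance separation
    (distance of their ratio from 1); sizes are the polyp's major-axis range
    in pixels.
    """

    image_size: int = 640
    n_polyps: int = 2
    size_range_px: tuple[float, float] = (32.0, 160.0)
    contrast: float = 0.35
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    specular_count: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_polyps <= 4):
            raise ValueError("n_polyps must lie in [1, 4]")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        lo, hi = self.size_range_px
        if lo <= 0 or hi > self.image_size / 2:
            raise ValueError("polyp sizes must be positive and <= image_size/2")


# difficulty presets mirroring hard clinical cases: weak polyp/background
# contrast, tiny polyps (8-16 px at 640, scaled with image size), and
# crowded multi-polyp frames
PRESETS = {
    "default": {},
    "low_contrast": {"contrast": 0.10},
    "tiny": {"size_range_px": (8.0, 16.0), "specular_count": 0},
    "multi": {"n_polyps": 4},
}


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    bg = spec.background
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64) / s
    lum = np.ones((s, s))
    # low-frequency mottling
    for _ in range(3):
        fx, fy = rng.uniform(1.5, 4.0, 2)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        lum += 0.04 * np.sin(2 * np.pi * fx * xx + px) * np.sin(2 * np.pi * fy * yy + py)
    # radial vignette toward the lumen
    cx, cy = rng.uniform(0.35, 0.65, 2)
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    lum *= 1.0 - bg.vignette_strength * np.clip(r / 0.75, 0, 1) ** 2
    # curved fold streaks: bands at fixed distance from off-centre circles
    for _ in range(bg.fold_count):
        fcx, fcy = rng.uniform(-0.5, 1.5, 2)
        rad = rng.uniform(0.3, 1.0)
        width = rng.uniform(0.01, 0.03)
        d = np.abs(np.sqrt((xx - fcx) ** 2 + (yy - fcy) ** 2) - rad)
        lum += 0.10 * np.exp(-(d / width) ** 2)
    base = np.asarray(bg.base_hue, dtype=np.float64)
    img = lum[..., None] * base[None, None, :]
    img += rng.normal(0.0, bg.noise_sd, img.shape)
    return img


def _render_polyp(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator,
                  occupied: list[tuple[float, float, float]],
                  max_tries: int = 60) -> Box:
    s = spec.image_size
    lo, hi = spec.size_range_px
    for _ in range(max_tries):
        major = rng.uniform(lo, hi)
        minor = major * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        margin = major / 2 + 2
        cx = rng.uniform(margin, s - margin)
        cy = rng.uniform(margin, s - margin)
        if all(np.hypot(cx - ox, cy - oy) > (major + osz) / 2 + 4
               for ox, oy, osz in occupied):
            break
    else:
        raise RuntimeError(
            "could not place a non-overlapping polyp; use fewer or smaller polyps")
    occupied.append((cx, cy, major))

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    d = np.sqrt((xr / (major / 2)) ** 2 + (yr / (minor / 2)) ** 2)
    feather = max(1.5 / (major / 2), 0.04)
    alpha = np.clip((1.0 - d) / feather, 0.0, 1.0)
    alpha = alpha ** 1.5                                   # soft Gaussian-like edge

    # luminance offset monotone in contrast; direction fixed brighter
    local = img * (1.0 + 0.9 * spec.contrast)
    tint = np.array([1.0, 1.04, 1.02])                     # slightly desaturated
    img[:] = img * (1 - alpha[..., None]) + (local * tint[None, None, :]) * alpha[..., None]

    for _ in range(spec.specular_count):
        gx = cx + rng.uniform(-0.25, 0.25) * major
        gy = cy + rng.uniform(-0.25, 0.25) * minor
        grad = rng.uniform(1.0, 2.5)
        blob = np.exp(-(((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * grad ** 2)))
        img[:] = np.clip(img + 140.0 * (blob * (alpha > 0.5))[..., None], 0, 600)

    support = alpha > 0.02
    ys, xs = np.nonzero(support)
    x1, x2 = xs.min(), xs.max() + 1
    y1, y2 = ys.min(), ys.max() + 1
    inside = support[y1:y2, x1:x2].sum()
    assert inside >= 0.6 * support.sum(), "gt box must cover the rendered support"
    return Box("cxcywh_norm", (((x1 + x2) / 2) / s, ((y1 + y2) / 2) / s,
                               (x2 - x1) / s, (y2 - y1) / s))


def generate_scene(spec: SceneSpec) -> LabeledImage:
    """Render one scene; bit-identical for identical specs (seed included)."""
    rng = np.random.default_rng(spec.rng_seed)
    img = _background(spec, rng)
    occupied: list[tuple[float, float, float]] = []
    boxes = [_render_polyp(img, spec, rng, occupied) for _ in range(spec.n_polyps)]
    out = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledImage(image=out, boxes=boxes, class_ids=[0] * spec.n_polyps,
                        source_id=f"scene_{spec.rng_seed:06d}")


def sample_polyp_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-image polyp counts, uniform on 1..4 (population mean 2.5)."""
    return rng.integers(1, 5, size=n)


def generate_dataset(n_images: int, out_dir: Path, seed: int = 0,
                     base_spec: SceneSpec | None = None,
                     preset: str = "default") -> Path:
    """Write a dataset of scenes with labels, dataset YAML and 8:1:1 split.

    Per-image polyp counts are drawn uniformly from 1..4 and the scene seed
    derives deterministically from ``seed``; regeneration reproduces the
    manifest bit for bit.  Returns the dataset YAML path.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    base = base_spec or SceneSpec()
    base = replace(base, **PRESETS[preset])
    rng = np.random.default_rng(seed)
    counts = sample_polyp_counts(n_images, rng)
    ids = []
    for i in range(n_images):
        n_polyps = int(counts[i])
        scene_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = replace(base, n_polyps=n_polyps, rng_seed=scene_seed)
        item = generate_scene(spec)
        sid = f"{preset}_{i:05d}"
        Image.fromarray(item.image).save(out_dir / "images" / f"{sid}.png")
        write_label_file(out_dir / "labels" / f"{sid}.txt", item.boxes, item.class_ids)
        ids.append(sid)
    splits = split_dataset(ids, seed=seed)
    manifest = {
        "path": str(out_dir.resolve()),
        "images_dir": "images",
        "labels_dir": "labels",
        "names": ["polyp"],
        "image_size": base.image_size,
        "split_seed": seed,
        "splits": splits,
    }
    yaml_path = out_dir / "dataset.yaml"
    yaml_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out_dir / "split.json").write_text(json.dumps(splits, indent=1))
    return yaml_path
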