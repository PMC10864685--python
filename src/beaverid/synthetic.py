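"""Synthetic tail-scale pattern benchmark.

Real tail photographs of the study population are not redistributable, so
this module generates a stand-in benchmark with the same design: a set of
individuals, each with a unique scale-like mosaic pattern, photographed
several times under rotation, scale change, illumination change, blur and
noise, in two quality tiers.  The ``close`` tier emulates close-up captures
(sharp, well exposed); the ``far`` tier emulates whole-tail captures taken
from further away (stronger blur, more noise, darker exposure).

A pattern is a seed-deterministic Voronoi-style tessellation: jittered-grid
seed points partition the canvas into cells ("scutes"), each cell gets a
random base shade, cell boundaries are darkened, and an elliptical mask
plays the role of the tail silhouette.  All randomness flows through named
seeds; regenerating a benchmark from the same global seed is bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import save_image

logger = logging.getLogger(__name__)

__all__ = [
    "PatternSpec",
    "TransformParams",
    "TransformRanges",
    "SyntheticDataset",
    "make_pattern",
    "render_view",
    "make_benchmark",
]


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for one individual's tessellation pattern.

    ``canvas`` defaults to the original capture resolution (1330 x 889) so
    the working-resolution resize path is exercised downstream.  400 cells
    on that canvas give a scute spacing of roughly 50 px, which after the
    640 x 480 resize leaves the default feature extractor in the range of
    tens to a few hundred keypoints per image.
    """

    individual_seed: int
    n_cells: int = 400
    cell_jitter: float = 0.45       # fraction of the mean cell spacing
    boundary_width: float = 4.0     # px
    boundary_darkness: float = 0.5  # intensity drop in (0, 1]
    cell_shade_sd: float = 0.14
    canvas: tuple[int, int] = (1330, 889)   # width, height

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        if not 0.0 <= self.boundary_darkness <= 1.0:
            raise ValueError("boundary_darkness must lie in [0, 1]")


@dataclass(frozen=True)
class TransformParams:
    """Imaging transform applied to a pattern to render one view."""

    rotation: float = 0.0       # degrees
    scale: float = 1.0
    gain: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    tier: str = "close"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class TransformRanges:
    """Uniform ranges the benchmark draws view transforms from, plus the
    fixed tier conditions (the 'far' tier is blurrier, noisier and darker,
    mirroring the lower detail of whole-tail captures)."""

    rotation: tuple[float, float] = (-15.0, 15.0)
    scale: tuple[float, float] = (0.9, 1.1)
    gain: tuple[float, float] = (0.8, 1.2)
    gamma: tuple[float, float] = (0.8, 1.25)
    close_blur: float = 0.5
    close_noise: float = 0.01
    far_blur: float = 1.2
    far_noise: float = 0.02
    far_gain_factor: float = 0.85


#: Ranges with every transform at identity (for limiting-case tests).
IDENTITY_RANGES = TransformRanges(
    rotation=(0.0, 0.0), scale=(1.0, 1.0), gain=(1.0, 1.0),
    gamma=(1.0, 1.0), close_blur=0.0, close_noise=0.0,
    far_blur=0.0, far_noise=0.0, far_gain_factor=1.0)


@dataclass
class SyntheticDataset:
    """Generated benchmark: manifest plus in-memory images.

    ``manifest`` has columns image_id, image_path, individual_id, group;
    ``images`` maps image_id to the rendered array (kept so tests can run
    without touching disk; ``image_path`` is empty when not written).
    """

    manifest: pd.DataFrame
    global_seed: int
    images: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def make_pattern(spec: PatternSpec) -> np.ndarray:
    """Render one individual's scale pattern (seed-deterministic).

    Jittered-grid seed points define a Voronoi tessellation; each cell is
    filled with a base intensity plus a Gaussian shade, boundaries between
    cells are darkened over ``boundary_width`` pixels, and an elliptical
    tail silhouette masks the canvas.
    """
    w, h = spec.canvas
    rng = np.random.default_rng(spec.individual_seed)

    nx = max(2, int(round(math.sqrt(spec.n_cells * w / h))))
    ny = max(2, int(round(spec.n_cells / nx)))
    sx, sy = w / nx, h / ny
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * sx, (np.arange(ny) + 0.5) * sy)
    jit = rng.uniform(-spec.cell_jitter, spec.cell_jitter, size=(ny, nx, 2))
    pts = np.stack([gx + jit[:, :, 0] * sx, gy + jit[:, :, 1] * sy], axis=-1)
    pts = pts.reshape(-1, 2)

    shades = np.clip(0.55 + rng.normal(0.0, spec.cell_shade_sd, len(pts)),
                     0.15, 0.95)

    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    dist, idx = cKDTree(pts).query(coords, k=2)
    d1 = dist[:, 0].reshape(h, w)
    d2 = dist[:, 1].reshape(h, w)
    img = shades[idx[:, 0]].reshape(h, w)

    if spec.boundary_darkness > 0 and spec.boundary_width > 0:
        ridge = np.clip(1.0 - (d2 - d1) / spec.boundary_width, 0.0, 1.0)
        img = img * (1.0 - spec.boundary_darkness * ridge)

    # elliptical tail silhouette
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a, b = 0.48 * w, 0.46 * h
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return np.where(mask, np.clip(img, 0.0, 1.0), 0.0)


def render_view(pattern: np.ndarray, t: TransformParams,
                view_seed: int = 0) -> np.ndarray:
    """Apply one imaging transform to a pattern.

    Order: rotation -> rescaling (single bilinear resampling about the
    centre, same canvas) -> intensity map (gain, offset, gamma as
    ``clip(gain * x + offset) ** gamma``) -> Gaussian blur -> additive
    Gaussian noise (seed-deterministic) -> clip to [0, 1].  Stages at their
    identity settings are skipped, so the identity transform returns the
    input unchanged.
    """
    img = np.asarray(pattern, dtype=np.float64)

    if t.rotation != 0.0 or t.scale != 1.0:
        h, w = img.shape
        c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        th = math.radians(t.rotation)
        # output (row, col) -> input: rotate by -theta and divide by scale
        rot = np.array([[math.cos(th), math.sin(th)],
                        [-math.sin(th), math.cos(th)]]) / t.scale
        img = ndimage.affine_transform(
            img, rot, offset=c - rot @ c, order=1, mode="constant", cval=0.0)

    if t.gain != 1.0 or t.offset != 0.0:
        img = np.clip(img * t.gain + t.offset, 0.0, 1.0)
    if t.gamma != 1.0:
        img = np.power(np.clip(img, 0.0, 1.0), t.gamma)
    if t.blur_sigma > 0.0:
        img = ndimage.gaussian_filter(img, t.blur_sigma, mode="reflect")
    if t.noise_sd > 0.0:
        rng = np.random.default_rng(view_seed)
        img = img + rng.normal(0.0, t.noise_sd, img.shape)
        img = np.clip(img, 0.0, 1.0)
    return img


def make_benchmark(n_individuals: int = 25,
                   images_per_individual: int = 8,
                   global_seed: int = 42,
                   out_dir: str | Path | None = None,
                   pattern_defaults: PatternSpec | None = None,
                   transform_ranges: TransformRanges = TransformRanges(),
                   ) -> SyntheticDataset:
    """Generate a labelled benchmark dataset.

    Each individual gets one unique pattern (seed derived from the global
    seed) and ``images_per_individual`` rendered views with transforms drawn
    uniformly from ``transform_ranges``; the first half of each individual's
    views belongs to the ``close`` tier and the second half to ``far``
    (mirroring the two acquisition heights).  Images and a manifest CSV are
    written when ``out_dir`` is given; arrays are always returned in memory.
    """
    if n_individuals < 2 or images_per_individual < 2:
        raise ValueError("need >= 2 individuals and >= 2 images each")
    base = pattern_defaults or PatternSpec(individual_seed=0)
    rng = np.random.default_rng(global_seed)
    pattern_seeds = rng.integers(0, 2 ** 31 - 1, size=n_individuals)
    view_seeds = rng.integers(0, 2 ** 31 - 1,
                              size=(n_individuals, images_per_individual))
    tr = transform_ranges

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    images: dict[str, np.ndarray] = {}
    n_close = images_per_individual // 2
    for i in range(n_individuals):
        ind = f"ind{i + 1:03d}"
        pattern = make_pattern(replace(base,
                                       individual_seed=int(pattern_seeds[i])))
        for v in range(images_per_individual):
            tier = "close" if v < n_close else "far"
            params = TransformParams(
                rotation=float(rng.uniform(*tr.rotation)),
                scale=float(rng.uniform(*tr.scale)),
                gain=float(rng.uniform(*tr.gain))
                * (tr.far_gain_factor if tier == "far" else 1.0),
                gamma=float(rng.uniform(*tr.gamma)),
                blur_sigma=tr.far_blur if tier == "far" else tr.close_blur,
                noise_sd=tr.far_noise if tier == "far" else tr.close_noise,
                tier=tier,
            )
            image_id = f"{ind}_v{v + 1:02d}"
            img = render_view(pattern, params, int(view_seeds[i, v]))
            images[image_id] = img
            path = ""
            if out is not None:
                path = str(out / f"{image_id}.png")
                save_image(path, img)
            rows.append({
                "image_id": image_id,
                "image_path": path,
                "individual_id": ind,
                "group": tier,
                "rotation": params.rotation,
                "scale": params.scale,
                "gain": params.gain,
                "gamma": params.gamma,
            })
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return SyntheticDataset(manifest=manifest, global_seed=global_seed,
                            images=images)
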