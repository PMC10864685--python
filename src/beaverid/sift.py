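"""From-scratch SIFT feature extraction.

The scale-invariant feature transform turns a gray working image into a set
of located, scaled, oriented keypoints with 128-value descriptors, in four
stages:

1. **Scale-space extrema detection.**  A Gaussian pyramid (4 octaves x 5
   scale levels by default, base blur sigma = 1.6, scale step k = sqrt(2))
   is differenced into a difference-of-Gaussians (DoG) pyramid, and every
   pixel that is strictly larger or strictly smaller than all 26 of its
   scale-space neighbours becomes a candidate keypoint.
2. **Keypoint refinement.**  A second-order Taylor fit around each candidate
   yields a sub-pixel offset and interpolated response; candidates with
   |response| < 0.03 (low contrast) or with an edge-like 2x2 spatial Hessian
   (trace^2/det >= (r+1)^2/r with r = 10) are rejected.
3. **Orientation assignment.**  Gradient magnitudes m(x, y) and orientations
   theta(x, y), computed from pixel differences, are accumulated into a
   36-bin histogram over a Gaussian-weighted circular window (sigma = 1.5 x
   keypoint scale); the highest peak and any peak above 80% of it each
   produce an oriented keypoint.
4. **Descriptor.**  A 16 x 16 sample grid around the keypoint, rotated to
   the keypoint orientation, is divided into 4 x 4 sub-blocks; each
   sub-block accumulates an 8-bin orientation histogram with trilinear
   interpolation, giving 128 values that are normalized, clamped at 0.2 and
   renormalized.

Where the four-stage recipe leaves standard details open they are fixed
following Lowe's published method (trilinear descriptor binning, the 0.2
descriptor clamp, parabolic peak interpolation, iterative sub-pixel
refinement, 1-px scale-space border exclusion).  There is no initial 2x
upsampling: octave 0 is the working image itself.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .imaging import as_gray_image

logger = logging.getLogger(__name__)

__all__ = [
    "SIFTConfig",
    "GaussianPyramid",
    "DoGPyramid",
    "Keypoint",
    "FeatureSet",
    "build_scale_space",
    "build_dog",
    "detect_extrema",
    "refine_candidate",
    "gradient_at",
    "passes_edge_test",
    "assign_orientations",
    "compute_descriptor",
    "extract_features",
]


@dataclass(frozen=True)
class SIFTConfig:
    """Tunable parameters of the feature extractor (defaults as used for the
    tail-pattern study: 4 octaves, 5 scale levels, sigma 1.6, k = sqrt(2),
    contrast threshold 0.03, edge ratio 10, 36 orientation bins with the 80%
    secondary-peak rule, 16 x 16 descriptor window in 4 x 4 sub-blocks of 8
    bins = 128 values)."""

    n_octaves: int = 4
    n_scale_levels: int = 5
    base_sigma: float = 1.6
    k_factor: float = math.sqrt(2.0)
    contrast_threshold: float = 0.03
    edge_r: float = 10.0
    n_orientation_bins: int = 36
    peak_fraction: float = 0.8
    orientation_sigma_factor: float = 1.5
    descriptor_window: int = 16
    descriptor_subblocks: int = 4
    descriptor_bins: int = 8
    descriptor_clamp: float = 0.2

    def __post_init__(self) -> None:
        if self.contrast_threshold <= 0:
            raise ValueError("contrast_threshold must be positive")
        if self.edge_r < 1:
            raise ValueError("edge_r must be >= 1")
        if self.k_factor <= 1:
            raise ValueError("k_factor must exceed 1")
        if self.n_scale_levels < 4:
            raise ValueError("need at least 4 scale levels (3 DoG images)")

    @property
    def descriptor_length(self) -> int:
        return self.descriptor_subblocks ** 2 * self.descriptor_bins

    def digest(self) -> str:
        """Short stable digest identifying this configuration."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GaussianPyramid:
    """Gaussian scale space: ``octaves[o][j]`` is the image blurred to
    absolute scale ``sigmas[o][j] = base_sigma * k^j * 2^o``; each octave's
    base is the previous octave's level with doubled base sigma, downsampled
    by taking every second pixel."""

    octaves: list[list[np.ndarray]]
    sigmas: list[list[float]]
    config: SIFTConfig

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)


@dataclass
class DoGPyramid:
    """Difference-of-Gaussians pyramid: per octave, ``n_scale_levels - 1``
    images D_j = L_{j+1} - L_j (higher sigma minus lower)."""

    octaves: list[list[np.ndarray]]
    config: SIFTConfig


@dataclass(frozen=True)
class Keypoint:
    """A located, scaled interest point in working-image coordinates
    (x = column, y = row; orientation in degrees, 0 pointing toward +x,
    measured with the row index increasing downward)."""

    x: float
    y: float
    octave: int
    level: int
    sigma: float
    response: float
    orientation: float = 0.0


@dataclass
class FeatureSet:
    """Keypoints and their descriptors for one labelled image."""

    image_id: str
    individual_id: str | None
    group: str
    keypoints: list[Keypoint] = field(default_factory=list)
    descriptors: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 128), dtype=np.float64))
    config_digest: str = ""

    def __post_init__(self) -> None:
        if len(self.keypoints) != self.descriptors.shape[0]:
            raise ValueError("keypoints and descriptors must be parallel")

    def __len__(self) -> int:
        return len(self.keypoints)


# ---------------------------------------------------------------------------
# Stage 1: scale space and DoG
# ---------------------------------------------------------------------------


def build_scale_space(image: np.ndarray, cfg: SIFTConfig = SIFTConfig()
                      ) -> GaussianPyramid:
    """Build the Gaussian pyramid.

    Level j of octave o carries absolute scale ``base_sigma * k^j * 2^o``.
    The working image is taken as (effectively) unblurred, so octave 0
    level 0 is the input convolved with a Gaussian of ``base_sigma``; within
    an octave each level is blurred from the octave base by the incremental
    sigma that composes to the target scale.  The next octave starts from
    the level with twice the base sigma (level index such that
    k^j = 2), downsampled by taking every second pixel.

    Images too small for the requested octave count (less than
    ``2**(n_octaves-1) * 8`` pixels per side) get a reduced octave count
    with a logged warning.
    """
    img = as_gray_image(image)
    h, w = img.shape
    n_oct = cfg.n_octaves
    while n_oct > 1 and min(h, w) < 2 ** (n_oct - 1) * 8:
        n_oct -= 1
    if n_oct != cfg.n_octaves:
        logger.warning(
            "image %dx%d too small for %d octaves; using %d",
            w, h, cfg.n_octaves, n_oct)

    # Index of the level whose relative sigma is twice the base sigma.
    double_j = round(math.log(2.0) / math.log(cfg.k_factor))
    if double_j >= cfg.n_scale_levels:
        double_j = cfg.n_scale_levels - 1

    octaves: list[list[np.ndarray]] = []
    sigmas: list[list[float]] = []
    base = ndimage.gaussian_filter(img, cfg.base_sigma, mode="reflect")
    for o in range(n_oct):
        levels = [base]
        lv_sigmas = [cfg.base_sigma * 2 ** o]
        for j in range(1, cfg.n_scale_levels):
            rel = cfg.base_sigma * cfg.k_factor ** j
            # incremental blur from the octave base (relative sigma units,
            # valid at the octave's own sampling rate)
            inc = math.sqrt(rel ** 2 - cfg.base_sigma ** 2)
            levels.append(ndimage.gaussian_filter(base, inc, mode="reflect"))
            lv_sigmas.append(rel * 2 ** o)
        octaves.append(levels)
        sigmas.append(lv_sigmas)
        base = levels[double_j][::2, ::2]
    return GaussianPyramid(octaves=octaves, sigmas=sigmas,
                           config=replace(cfg, n_octaves=n_oct))


def build_dog(pyr: GaussianPyramid) -> DoGPyramid:
    """Difference adjacent Gaussian levels (higher sigma minus lower)."""
    octs = [[lv[j + 1] - lv[j] for j in range(len(lv) - 1)]
            for lv in pyr.octaves]
    return DoGPyramid(octaves=octs, config=pyr.config)


def detect_extrema(dog: DoGPyramid) -> list[tuple[int, int, int, int]]:
    """Scale-space extrema: (octave, level, x, y) of every interior pixel
    strictly greater or strictly smaller than all 26 neighbours (8 in its
    own DoG level, 9 in the level above, 9 below).  Only levels with both
    neighbours are searched and 1-px image borders are excluded; plateaus
    (ties) produce no candidate.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    out: list[tuple[int, int, int, int]] = []
    for o, levels in enumerate(dog.octaves):
        if len(levels) < 3:
            continue
        stack = np.stack(levels)  # (L, h, w)
        nb_max = ndimage.maximum_filter(stack, footprint=footprint,
                                        mode="constant", cval=-np.inf)
        nb_min = ndimage.minimum_filter(stack, footprint=footprint,
                                        mode="constant", cval=np.inf)
        is_ext = (stack > nb_max) | (stack < nb_min)
        is_ext[0] = is_ext[-1] = False
        is_ext[:, :1, :] = is_ext[:, -1:, :] = False
        is_ext[:, :, :1] = is_ext[:, :, -1:] = False
        for l, y, x in zip(*np.nonzero(is_ext)):
            out.append((o, int(l), int(x), int(y)))
    return out


# ---------------------------------------------------------------------------
# Stage 2: keypoint refinement
# ---------------------------------------------------------------------------


def passes_edge_test(dxx: float, dyy: float, dxy: float,
                     edge_r: float = 10.0) -> bool:
    """Edge rejection from the 2x2 spatial Hessian: keep a point only when
    ``det > 0`` and ``trace^2 / det < (r + 1)^2 / r``.

    E.g. (dxx, dyy, dxy) = (10, 10, 0) gives trace^2/det = 4 < 12.1 (kept)
    while (100, 1, 0) gives 102.01 (rejected) at the default r = 10.
    """
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    tr = dxx + dyy
    return tr * tr / det < (edge_r + 1.0) ** 2 / edge_r


def refine_candidate(candidate: tuple[int, int, int, int], dog: DoGPyramid,
                     cfg: SIFTConfig = SIFTConfig()
                     ) -> tuple[Keypoint | None, str | None]:
    """Sub-pixel refinement and filtering of one extremum candidate.

    Fits a 3-D quadratic (second-order Taylor expansion of the DoG response
    in x, y and scale) around the candidate.  If the fitted offset exceeds
    0.5 in any dimension the candidate moves to the neighbouring pixel and
    is re-fitted (at most 5 iterations).  Returns ``(keypoint, None)`` on
    success or ``(None, reason)`` with reason one of ``"unstable"``,
    ``"outside"``, ``"singular"``, ``"low_contrast"``, ``"edge"``.
    """
    o, l, x, y = candidate
    levels = dog.octaves[o]
    n_lev = len(levels)
    h, w = levels[0].shape

    offset = np.zeros(3)
    grad = np.zeros(3)
    converged = False
    for _ in range(5):
        d0, d1, d2 = levels[l - 1], levels[l], levels[l + 1]
        grad[0] = 0.5 * (d1[y, x + 1] - d1[y, x - 1])
        grad[1] = 0.5 * (d1[y + 1, x] - d1[y - 1, x])
        grad[2] = 0.5 * (d2[y, x] - d0[y, x])
        dxx = d1[y, x + 1] + d1[y, x - 1] - 2.0 * d1[y, x]
        dyy = d1[y + 1, x] + d1[y - 1, x] - 2.0 * d1[y, x]
        dss = d2[y, x] + d0[y, x] - 2.0 * d1[y, x]
        dxy = 0.25 * (d1[y + 1, x + 1] - d1[y + 1, x - 1]
                      - d1[y - 1, x + 1] + d1[y - 1, x - 1])
        dxs = 0.25 * (d2[y, x + 1] - d2[y, x - 1]
                      - d0[y, x + 1] + d0[y, x - 1])
        dys = 0.25 * (d2[y + 1, x] - d2[y - 1, x]
                      - d0[y + 1, x] + d0[y - 1, x])
        hess = np.array([[dxx, dxy, dxs],
                         [dxy, dyy, dys],
                         [dxs, dys, dss]])
        try:
            offset = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            return None, "singular"
        if np.all(np.abs(offset) < 0.5):
            converged = True
            break
        x += int(round(float(np.clip(offset[0], -1, 1))))
        y += int(round(float(np.clip(offset[1], -1, 1))))
        l += int(round(float(np.clip(offset[2], -1, 1))))
        if not (1 <= l <= n_lev - 2 and 1 <= x <= w - 2 and 1 <= y <= h - 2):
            return None, "outside"
    if not converged:
        return None, "unstable"

    d_hat = levels[l][y, x] + 0.5 * float(grad @ offset)
    if abs(d_hat) < cfg.contrast_threshold:
        return None, "low_contrast"

    d1 = levels[l]
    dxx = d1[y, x + 1] + d1[y, x - 1] - 2.0 * d1[y, x]
    dyy = d1[y + 1, x] + d1[y - 1, x] - 2.0 * d1[y, x]
    dxy = 0.25 * (d1[y + 1, x + 1] - d1[y + 1, x - 1]
                  - d1[y - 1, x + 1] + d1[y - 1, x - 1])
    if not passes_edge_test(dxx, dyy, dxy, cfg.edge_r):
        return None, "edge"

    scale_factor = 2.0 ** o
    kp = Keypoint(
        x=(x + float(offset[0])) * scale_factor,
        y=(y + float(offset[1])) * scale_factor,
        octave=o,
        level=l,
        sigma=cfg.base_sigma * cfg.k_factor ** (l + float(offset[2]))
        * scale_factor,
        response=d_hat,
    )
    return kp, None


# ---------------------------------------------------------------------------
# Stage 3: gradients and orientation assignment
# ---------------------------------------------------------------------------


def gradient_at(L: np.ndarray, x: int, y: int) -> tuple[float, float]:
    """Gradient magnitude and orientation at an interior pixel of a blurred
    image, from plain pixel differences:

        m     = sqrt((L(x+1,y) - L(x-1,y))^2 + (L(x,y+1) - L(x,y-1))^2)
        theta = atan2(L(x,y+1) - L(x,y-1), L(x+1,y) - L(x-1,y))

    mapped to degrees in [0, 360); a flat neighbourhood returns (0, 0).
    """
    h, w = L.shape
    if not (1 <= x <= w - 2 and 1 <= y <= h - 2):
        raise ValueError(f"({x}, {y}) is not an interior pixel")
    dx = L[y, x + 1] - L[y, x - 1]
    dy = L[y + 1, x] - L[y - 1, x]
    m = math.hypot(dx, dy)
    if m == 0.0:
        return 0.0, 0.0
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    return m, theta


def _gradient_maps(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-image dx and dy difference maps (zero on the 1-px border)."""
    dx = np.zeros_like(L)
    dy = np.zeros_like(L)
    dx[:, 1:-1] = L[:, 2:] - L[:, :-2]
    dy[1:-1, :] = L[2:, :] - L[:-2, :]
    return dx, dy


def _interp_peak(hist: np.ndarray, b: int) -> float:
    """Parabolic interpolation of a circular-histogram peak; returns the
    fractional bin position of the refined maximum."""
    n = len(hist)
    hl, hc, hr = hist[(b - 1) % n], hist[b], hist[(b + 1) % n]
    denom = hl - 2.0 * hc + hr
    if denom == 0.0:
        return float(b)
    return b + 0.5 * (hl - hr) / denom


def assign_orientations(kp: Keypoint, pyr: GaussianPyramid,
                        cfg: SIFTConfig = SIFTConfig(),
                        grad_maps=None) -> list[Keypoint]:
    """Orientation histogram around a keypoint; one oriented keypoint per
    qualifying peak.

    Gradient samples within radius ``3 * orientation_sigma_factor * sigma``
    (octave-local scale) are accumulated into ``n_orientation_bins`` bins,
    each weighted by magnitude times a Gaussian of the distance with sigma
    1.5 x keypoint scale.  Bins are centred on multiples of the bin width.
    Every peak that is a circular local maximum and reaches
    ``peak_fraction`` of the global maximum yields a keypoint, its angle
    refined by parabolic interpolation.  A flat patch (all-zero histogram)
    discards the keypoint.
    """
    o = kp.octave
    L = pyr.octaves[o][min(kp.level, len(pyr.octaves[o]) - 1)]
    if grad_maps is None:
        dx_map, dy_map = _gradient_maps(L)
    else:
        dx_map, dy_map = grad_maps
    h, w = L.shape
    scale_factor = 2.0 ** o
    xc = kp.x / scale_factor
    yc = kp.y / scale_factor
    sigma_oct = kp.sigma / scale_factor
    sigma_w = cfg.orientation_sigma_factor * sigma_oct
    radius = max(1, int(round(3.0 * sigma_w)))

    xi, yi = int(round(xc)), int(round(yc))
    x0, x1 = max(1, xi - radius), min(w - 2, xi + radius)
    y0, y1 = max(1, yi - radius), min(h - 2, yi + radius)
    if x0 > x1 or y0 > y1:
        return []

    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    dx = dx_map[y0:y1 + 1, x0:x1 + 1]
    dy = dy_map[y0:y1 + 1, x0:x1 + 1]
    r2 = (xx - xc) ** 2 + (yy - yc) ** 2
    in_circle = r2 <= radius * radius
    mag = np.hypot(dx, dy) * np.exp(-r2 / (2.0 * sigma_w ** 2)) * in_circle
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    nbins = cfg.n_orientation_bins
    width = 360.0 / nbins
    bins = np.rint(theta / width).astype(int) % nbins
    hist = np.bincount(bins.ravel(), weights=mag.ravel(), minlength=nbins)

    peak = hist.max()
    if peak <= 0.0:
        return []
    out = []
    for b in range(nbins):
        hb = hist[b]
        if hb < cfg.peak_fraction * peak:
            continue
        if not (hb > hist[(b - 1) % nbins] and hb > hist[(b + 1) % nbins]):
            continue
        angle = (_interp_peak(hist, b) * width) % 360.0
        out.append(replace(kp, orientation=angle))
    return out


# ---------------------------------------------------------------------------
# Stage 4: descriptor
# ---------------------------------------------------------------------------


def compute_descriptor(kp: Keypoint, pyr: GaussianPyramid,
                       cfg: SIFTConfig = SIFTConfig(),
                       grad_maps=None) -> np.ndarray:
    """128-value descriptor of one oriented keypoint (see module docstring).

    Samples outside the image contribute zero.  The histogram vector is
    normalized to unit length, clamped at ``descriptor_clamp`` and
    renormalized; a degenerate flat patch yields the all-zero vector.
    """
    return _descriptors_batch([kp], pyr, cfg, grad_maps)[0]


def _descriptors_batch(kps: list[Keypoint], pyr: GaussianPyramid,
                       cfg: SIFTConfig, grad_maps=None) -> np.ndarray:
    """Vectorized descriptor computation for keypoints sharing an octave and
    level (general lists are split internally)."""
    if not kps:
        return np.zeros((0, cfg.descriptor_length))
    key = (kps[0].octave, kps[0].level)
    if any((k.octave, k.level) != key for k in kps):
        parts = {}
        for i, k in enumerate(kps):
            parts.setdefault((k.octave, k.level), []).append(i)
        out = np.zeros((len(kps), cfg.descriptor_length))
        for idx in parts.values():
            out[idx] = _descriptors_batch([kps[i] for i in idx], pyr, cfg,
                                          None)
        return out

    o, lev = key
    L = pyr.octaves[o][min(lev, len(pyr.octaves[o]) - 1)]
    if grad_maps is None:
        dx_map, dy_map = _gradient_maps(L)
    else:
        dx_map, dy_map = grad_maps

    n = len(kps)
    win = cfg.descriptor_window
    d = cfg.descriptor_subblocks
    nb = cfg.descriptor_bins
    sub = win // d
    scale_factor = 2.0 ** o

    # sample-grid offsets in the descriptor frame, pixel units
    g = np.arange(win) - (win - 1) / 2.0
    uu, vv = np.meshgrid(g, g)           # (win, win)
    u = uu.ravel()
    v = vv.ravel()                       # (S,) with S = win^2
    gauss_w = np.exp(-(u ** 2 + v ** 2) / (2.0 * (win / 2.0) ** 2))

    ori = np.array([k.orientation for k in kps])
    rad = np.radians(ori)
    cos_t = np.cos(rad)[:, None]
    sin_t = np.sin(rad)[:, None]
    xc = np.array([k.x for k in kps])[:, None] / scale_factor
    yc = np.array([k.y for k in kps])[:, None] / scale_factor

    # rotate the grid into the image frame
    xs = xc + u[None, :] * cos_t - v[None, :] * sin_t    # (n, S)
    ys = yc + u[None, :] * sin_t + v[None, :] * cos_t

    coords = np.stack([ys.ravel(), xs.ravel()])
    dxs = ndimage.map_coordinates(dx_map, coords, order=1,
                                  mode="constant", cval=0.0).reshape(n, -1)
    dys = ndimage.map_coordinates(dy_map, coords, order=1,
                                  mode="constant", cval=0.0).reshape(n, -1)
    mag = np.hypot(dxs, dys) * gauss_w[None, :]
    theta = (np.degrees(np.arctan2(dys, dxs)) - ori[:, None]) % 360.0

    # trilinear interpolation into (d, d, nb) histograms, padded in space
    rbin = v[None, :] / sub + (d - 1) / 2.0              # (n, S), in [-?, d)
    cbin = u[None, :] / sub + (d - 1) / 2.0
    obin = theta / (360.0 / nb)
    rbin = np.broadcast_to(rbin, mag.shape)
    cbin = np.broadcast_to(cbin, mag.shape)

    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    fr = rbin - r0
    fc = cbin - c0
    fo = obin - o0

    hist = np.zeros((n, d + 2, d + 2, nb))
    kidx = np.broadcast_to(np.arange(n)[:, None], mag.shape)
    for dr in (0, 1):
        wr = np.where(dr, fr, 1 - fr)
        for dc in (0, 1):
            wc = np.where(dc, fc, 1 - fc)
            for do in (0, 1):
                wo = np.where(do, fo, 1 - fo)
                np.add.at(
                    hist,
                    (kidx, np.clip(r0 + dr + 1, 0, d + 1),
                     np.clip(c0 + dc + 1, 0, d + 1), (o0 + do) % nb),
                    mag * wr * wc * wo)

    vec = hist[:, 1:d + 1, 1:d + 1, :].reshape(n, -1)
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    nonzero = norms[:, 0] > 0
    vec[nonzero] /= norms[nonzero]
    vec = np.minimum(vec, cfg.descriptor_clamp)
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    nonzero = norms[:, 0] > 0
    vec[nonzero] /= norms[nonzero]
    return vec


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def extract_features(image: np.ndarray, cfg: SIFTConfig = SIFTConfig(),
                     image_id: str = "", individual_id: str | None = None,
                     group: str = "") -> FeatureSet:
    """Run the full four-stage extraction on a preprocessed working image.

    Deterministic for a fixed input and configuration.  An image with no
    surviving keypoints yields a valid empty feature set (with a logged
    warning)."""
    pyr = build_scale_space(image, cfg)
    dog = build_dog(pyr)
    candidates = detect_extrema(dog)

    refined: list[Keypoint] = []
    for cand in candidates:
        kp, _reason = refine_candidate(cand, dog, cfg)
        if kp is not None:
            h, w = pyr.octaves[0][0].shape
            if 0 <= kp.x < w and 0 <= kp.y < h:
                refined.append(kp)

    # cache gradient maps per (octave, level)
    grad_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def maps_for(o: int, lev: int):
        key = (o, lev)
        if key not in grad_cache:
            L = pyr.octaves[o][min(lev, len(pyr.octaves[o]) - 1)]
            grad_cache[key] = _gradient_maps(L)
        return grad_cache[key]

    oriented: list[Keypoint] = []
    for kp in refined:
        oriented.extend(
            assign_orientations(kp, pyr, cfg, maps_for(kp.octave, kp.level)))

    by_level: dict[tuple[int, int], list[int]] = {}
    for i, kp in enumerate(oriented):
        by_level.setdefault((kp.octave, kp.level), []).append(i)
    descs = np.zeros((len(oriented), cfg.descriptor_length))
    for (o, lev), idx in by_level.items():
        descs[idx] = _descriptors_batch(
            [oriented[i] for i in idx], pyr, cfg, maps_for(o, lev))

    if not oriented:
        logger.warning("no keypoints found in image %r", image_id or "<array>")
    return FeatureSet(image_id=image_id, individual_id=individual_id,
                      group=group, keypoints=oriented, descriptors=descs,
                      config_digest=cfg.digest())
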