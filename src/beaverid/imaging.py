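"""Image preprocessing for tail-pattern extraction.

Photographs of patterned surfaces enter the pipeline as 8/16-bit files and
are converted to a single working representation: a 2-D float array of
intensities in [0, 1] ("gray image").  The preprocessing recipe mirrors the
manual editing workflow used to make the scale pattern visible before
feature extraction: grayscale conversion, elliptical region-of-interest
cropping, a fixed sequence of enhancement operators, and resizing to the
working resolution (640 x 480 by default).

The consumer-editor sliders behind the enhancement recipe are proprietary;
each is re-expressed here as a standard, documented operator so the pipeline
is deterministic and reproducible:

* sharpen        -> unsharp mask (Gaussian sigma = 1.0, amount = slider - 1)
* exposure       -> multiplicative gain
* lightness      -> additive shift of offset/255 before clipping
* contrast c     -> linear stretch about 0.5 with slope 1 + c/100
* gamma g        -> power law ``out = in ** (1/g)``
* backlight/intensify/brighten -> CLAHE (8 x 8 tiles) with clip limit
  proportional to the backlight strength

Two presets, ``CLOSE`` and ``FAR``, encode the editing recipes used for the
two image-acquisition heights (close-up and whole-tail framings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure as _sk_exposure
from skimage import transform as _sk_transform

__all__ = [
    "EllipseROI",
    "EnhanceParams",
    "CLOSE",
    "FAR",
    "IDENTITY",
    "as_gray_image",
    "load_image",
    "save_image",
    "to_grayscale",
    "crop_ellipse",
    "enhance",
    "resize_working",
    "preprocess",
]

#: Rec.601 luma weights used for grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default working resolution, width x height.
WORKING_SIZE = (640, 480)


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a gray image (2-D float64 array in [0, 1])."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("gray image must be non-empty")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < -1e-12 or hi > 1 + 1e-12:
        raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
    return np.clip(arr, 0.0, 1.0)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as a float array scaled to [0, 1].

    Returns a 2-D array for grayscale files and an (H, W, 3) array for
    colour files (an alpha channel, if present, is dropped).
    """
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.dtype == np.uint8:
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(np.float64) / 65535.0
    else:
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def save_image(path, image: np.ndarray) -> None:
    """Write an intensity image as an 8-bit PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest, in pixel coordinates.

    The ellipse is centred at ``(center_x, center_y)`` (x = column,
    y = row), has semi-axes ``semi_axis_x`` / ``semi_axis_y`` along its own
    axes, and is rotated by ``rotation`` degrees counter-clockwise.
    """

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def bounding_box(self) -> tuple[float, float, float, float]:
        """Half-extents-based axis-aligned bounding box (x0, x1, y0, y1)."""
        t = math.radians(self.rotation)
        c, s = math.cos(t), math.sin(t)
        hx = math.hypot(self.semi_axis_x * c, self.semi_axis_y * s)
        hy = math.hypot(self.semi_axis_x * s, self.semi_axis_y * c)
        return (self.center_x - hx, self.center_x + hx,
                self.center_y - hy, self.center_y + hy)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean membership of pixel coordinates (boundary inclusive)."""
        t = math.radians(self.rotation)
        c, s = math.cos(t), math.sin(t)
        dx = np.asarray(x, dtype=np.float64) - self.center_x
        dy = np.asarray(y, dtype=np.float64) - self.center_y
        u = (dx * c + dy * s) / self.semi_axis_x
        v = (-dx * s + dy * c) / self.semi_axis_y
        return u * u + v * v <= 1.0


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the deterministic enhancement pipeline.

    ``sharpen_amount`` follows the editor's convention where 1.5 means
    "sharpness increased to 150%".  ``exposure_gain`` is a plain multiplier
    in [1, 5].  ``contrast`` and the ``intensify``/``brighten`` strengths use
    the editor's 0-100 sliders.  ``lightness_offset`` is a signed value on a
    -100..100 scale, applied as ``offset / 255``.  ``backlight_strength``
    expresses the editor's "+/-150%" / "+/-200%" backlight settings as 1.5 /
    2.0 (only the magnitude is meaningful).
    """

    sharpen_amount: float = 1.0
    exposure_gain: float = 1.0
    contrast: float = 0.0
    gamma: float = 1.0
    lightness_offset: float = 0.0
    backlight_strength: float = 0.0
    intensify: float = 0.0
    brighten: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.exposure_gain < 1:
            raise ValueError("exposure_gain must be >= 1")
        for name in ("contrast", "intensify", "brighten"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not -100 <= self.lightness_offset <= 100:
            raise ValueError("lightness_offset must be in [-100, 100]")
        if self.backlight_strength < 0:
            raise ValueError("backlight_strength must be >= 0")


#: Identity parameters: ``enhance(img, IDENTITY)`` returns ``img`` unchanged.
IDENTITY = EnhanceParams()

#: Recipe for the 'close' acquisition group: sharpness 150%, intensify and
#: brighten at their 0-100 maxima, exposure to the maximum gain 5, contrast
#: to 100, backlight 150%, gamma in 2.20-2.80 (midpoint used), lightness
#: lowered to the -35..-45 range (midpoint used).
CLOSE = EnhanceParams(
    sharpen_amount=1.5, exposure_gain=5.0, contrast=100.0, gamma=2.5,
    lightness_offset=-40.0, backlight_strength=1.5, intensify=100.0,
    brighten=100.0,
)

#: Recipe for the 'far' acquisition group: backlight 200%, gamma in
#: 3.00-3.80 (midpoint used), brightness lowered to the -10..-20 range.
FAR = EnhanceParams(
    sharpen_amount=1.5, exposure_gain=5.0, contrast=100.0, gamma=3.4,
    lightness_offset=-15.0, backlight_strength=2.0, intensify=100.0,
    brighten=100.0,
)

PRESETS = {"close": CLOSE, "far": FAR, "none": IDENTITY}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel colour image to a gray image (Rec.601 luma)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) colour image, got shape {arr.shape}")
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise ValueError("channel values must lie in [0, 1]")
    return np.clip(arr @ LUMA_WEIGHTS, 0.0, 1.0)


def crop_ellipse(image: np.ndarray, roi: EllipseROI) -> np.ndarray:
    """Crop to the axis-aligned bounding box of ``roi``, zeroing pixels
    outside the (possibly rotated) ellipse.

    Pixel (column x, row y) belongs to the ellipse when its centre
    coordinates satisfy the inclusive membership inequality.
    """
    img = as_gray_image(image)
    h, w = img.shape
    x0f, x1f, y0f, y1f = roi.bounding_box()
    x0 = max(0, int(math.ceil(x0f)))
    x1 = min(w - 1, int(math.floor(x1f)))
    y0 = max(0, int(math.ceil(y0f)))
    y1 = min(h - 1, int(math.floor(y1f)))
    if x0 > x1 or y0 > y1:
        raise ValueError("ellipse does not intersect the image bounds")
    sub = img[y0:y1 + 1, x0:x1 + 1]
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    mask = roi.contains(xx, yy)
    return np.where(mask, sub, 0.0)


def _clahe(img: np.ndarray, clip_limit: float) -> np.ndarray:
    # skimage's CLAHE; 8x8 tile grid regardless of image size.
    h, w = img.shape
    kernel = (max(1, h // 8), max(1, w // 8))
    return _sk_exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit)


def enhance(image: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Apply the enhancement pipeline in its fixed order.

    Order: backlight compensation (CLAHE) -> exposure gain -> lightness
    offset -> contrast stretch -> gamma map -> unsharp-mask sharpening.
    Each stage is skipped at its identity setting, so identity parameters
    return the input bit-exactly.  Output is clipped to [0, 1].
    """
    img = as_gray_image(image)

    if params.backlight_strength > 0 or params.intensify > 0 or params.brighten > 0:
        # Clip limit grows with the backlight strength; the 0-100 intensify
        # and brighten sliders add on the same (fractional) scale.
        clip = 0.01 * (params.backlight_strength
                       + params.intensify / 100.0
                       + params.brighten / 100.0)
        img = _clahe(img, clip)

    if params.exposure_gain != 1.0:
        img = np.clip(img * params.exposure_gain, 0.0, 1.0)

    if params.lightness_offset != 0.0:
        img = np.clip(img + params.lightness_offset / 255.0, 0.0, 1.0)

    if params.contrast != 0.0:
        slope = 1.0 + params.contrast / 100.0
        img = np.clip(0.5 + (img - 0.5) * slope, 0.0, 1.0)

    if params.gamma != 1.0:
        img = np.power(img, 1.0 / params.gamma)

    if params.sharpen_amount != 1.0:
        amount = params.sharpen_amount - 1.0
        blurred = ndimage.gaussian_filter(img, sigma=1.0, mode="reflect")
        img = np.clip(img + amount * (img - blurred), 0.0, 1.0)

    return img


def resize_working(image: np.ndarray,
                   target_width: int = WORKING_SIZE[0],
                   target_height: int = WORKING_SIZE[1]) -> np.ndarray:
    """Bilinear resize to exact target dimensions (aspect not preserved).

    The default maps original captures (e.g. 1330 x 889) onto the 640 x 480
    working frame, reproducing the pipeline's literal (aspect-distorting)
    rescale.
    """
    img = as_gray_image(image)
    if target_width < 3 or target_height < 3:
        raise ValueError("target dimensions must be at least 3 pixels")
    h, w = img.shape
    if (w, h) == (target_width, target_height):
        return img.copy()
    out = _sk_transform.resize(
        img, (target_height, target_width), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def preprocess(image: np.ndarray,
               roi: EllipseROI | None = None,
               params: EnhanceParams = IDENTITY,
               target_width: int = WORKING_SIZE[0],
               target_height: int = WORKING_SIZE[1]) -> np.ndarray:
    """Full preprocessing chain: grayscale, optional ROI crop, enhancement,
    resize to the working resolution."""
    arr = np.asarray(image, dtype=np.float64)
    img = to_grayscale(arr) if arr.ndim == 3 else as_gray_image(arr)
    if roi is not None:
        img = crop_ellipse(img, roi)
    img = enhance(img, params)
    return resize_working(img, target_width, target_height)
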