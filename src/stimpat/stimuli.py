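"""Image loading and synthetic stimulus generation.

All vision models in :mod:`stimpat.models` consume :class:`LuminanceImage`
objects: single-channel intensity grids in ``[0, 1]``, indexed ``(row, col)``
with row 0 at the top.  This module converts raster files to that
representation and generates parametric fixtures (Gabor patches, simple
shapes) so that every model can be exercised without external image
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "LuminanceImage",
    "load_image",
    "make_gabor_patch",
    "make_shape_set",
    "shift_image",
]

# ITU-R BT.601 luma weights for collapsing RGB to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LuminanceImage:
    """A 2D grayscale intensity grid with values in [0, 1].

    Parameters
    ----------
    pixels
        ``(height, width)`` float array; all values finite and in [0, 1].
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a 2D array with positive extent")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path, target_size: int | None = None) -> LuminanceImage:
    """Load a raster image (PNG/JPEG/BMP), convert to grayscale in [0, 1].

    RGB channels are collapsed with BT.601 luma weights (0.299, 0.587,
    0.114).  If `target_size` is given the image is resampled to
    ``target_size x target_size`` with bilinear interpolation.

    Raises
    ------
    FileNotFoundError, ValueError
        If the file is missing or not a decodable image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im, dtype=float)
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot decode image file: {path}") from exc

    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA  # drop alpha, collapse by luma
    arr = arr / 255.0

    if target_size is not None:
        if target_size < 1:
            raise ValueError("target_size must be >= 1")
        pil = Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8))
        pil = pil.resize((target_size, target_size), Image.BILINEAR)
        arr = np.asarray(pil, dtype=float) / 255.0

    return LuminanceImage(np.clip(arr, 0.0, 1.0))


def make_gabor_patch(
    size: int,
    sf: float,
    ori: float,
    phase: float = 0.0,
    sigma: float | None = None,
) -> LuminanceImage:
    """A cosine grating windowed by an isotropic Gaussian, centred in the image.

    Parameters
    ----------
    size
        Image side in pixels (>= 8).
    sf
        Spatial frequency in cycles per pixel.
    ori
        Grating orientation in degrees (0 = horizontal carrier variation
        along columns).
    phase
        Carrier phase in radians.
    sigma
        Gaussian envelope standard deviation in pixels; defaults to size/6.
    """
    if size < 8:
        raise ValueError("size must be >= 8 px")
    if sf <= 0:
        raise ValueError("sf must be positive")
    if sigma is None:
        sigma = size / 6.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    y = rows - c
    x = cols - c
    theta = np.deg2rad(ori)
    # carrier varies along the direction `ori` measured from the column axis
    u = x * np.cos(theta) + y * np.sin(theta)
    carrier = np.cos(2.0 * np.pi * sf * u + phase)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    patch = 0.5 + 0.5 * carrier * envelope
    return LuminanceImage(np.clip(patch, 0.0, 1.0))


def make_shape_set(n: int, kind: str = "bars", seed: int = 0) -> list[LuminanceImage]:
    """Generate `n` distinct centred binary-ish shapes on a uniform background.

    Deterministic given `seed`.  Kinds: ``bars`` (oriented bars),
    ``rectangles`` (filled axis-aligned rectangles of varying aspect),
    ``blobs`` (smoothed random blobs thresholded to binary).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in ("bars", "rectangles", "blobs"):
        raise ValueError(f"unknown shape kind: {kind!r}")

    rng = np.random.default_rng(seed)
    size = 64
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    y, x = rows - c, cols - c

    images: list[LuminanceImage] = []
    for i in range(n):
        if kind == "bars":
            # evenly spaced orientations guarantee pairwise distinctness
            theta = np.deg2rad(180.0 * i / n)
            u = x * np.cos(theta) + y * np.sin(theta)
            v = -x * np.sin(theta) + y * np.cos(theta)
            mask = (np.abs(u) < size * 0.35) & (np.abs(v) < size * 0.06)
        elif kind == "rectangles":
            w = size * (0.15 + 0.6 * (i + 1) / (n + 1))
            h = size * (0.15 + 0.6 * (n - i) / (n + 1))
            mask = (np.abs(x) < w / 2) & (np.abs(y) < h / 2)
        else:  # blobs
            field = rng.standard_normal((size, size))
            # isotropic Gaussian smoothing via FFT keeps this dependency-light
            fy = np.fft.fftfreq(size)[:, None]
            fx = np.fft.fftfreq(size)[None, :]
            lowpass = np.exp(-((fx**2 + fy**2) * (2.0 * np.pi * 4.0) ** 2) / 2.0)
            smooth = np.fft.ifft2(np.fft.fft2(field) * lowpass).real
            window = np.exp(-(x**2 + y**2) / (2.0 * (size / 5.0) ** 2))
            smooth *= window
            mask = smooth > np.quantile(smooth, 0.88)
        images.append(LuminanceImage(mask.astype(float)))
    return images


def shift_image(img: LuminanceImage, dx: int, dy: int, fill: float = 0.0) -> LuminanceImage:
    """Translate image content by (`dx`, `dy`) pixels; vacated pixels get `fill`.

    `dx` shifts columns rightward, `dy` shifts rows downward.  The output has
    the same size as the input.
    """
    h, w = img.height, img.width
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError("shift magnitude must be smaller than the image size")
    if not 0.0 <= fill <= 1.0:
        raise ValueError("fill must be in [0, 1]")
    out = np.full((h, w), float(fill))
    src = img.pixels
    rs_src = slice(max(0, -dy), h - max(0, dy))
    cs_src = slice(max(0, -dx), w - max(0, dx))
    rs_dst = slice(max(0, dy), h - max(0, -dy))
    cs_dst = slice(max(0, dx), w - max(0, -dx))
    out[rs_dst, cs_dst] = src[rs_src, cs_src]
    return LuminanceImage(out)
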