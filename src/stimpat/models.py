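"""Stimulus-control models with a uniform ``run``/``compare`` interface.

Three models of increasing biological sophistication quantify low-level
similarity between visual stimuli:

* **pixelwise** — Euclidean distance between grayscale pixel vectors;
* **gaborjet** — a V1-like descriptor sampling complex Gabor filter
  responses (5 spatial frequencies x 8 orientations, steps of 45 degrees)
  on a 10x10 grid, convolution done in the Fourier domain; descriptors are
  compared by the angular distance between magnitude vectors;
* **hmax** — a feedforward model of the ventral stream alternating
  template matching (S1, S2) and max pooling (C1, C2), yielding a
  256-element position/scale-tolerant C2 vector, optionally followed by
  Gaussian view-tuned units (VTUs) matched against stored training
  representations.

Every model's ``compare`` produces a labelled symmetric
:class:`DissimilarityMatrix` with a zero diagonal, so downstream analyses
can treat the models interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .stimuli import LuminanceImage, load_image

__all__ = [
    "WORKING_SIZE",
    "DissimilarityMatrix",
    "GaborJetDescriptor",
    "HMAXDescriptor",
    "S1Maps",
    "C1Maps",
    "S2Maps",
    "angular_distance",
    "pixelwise_compare",
    "gaborjet_run",
    "gaborjet_compare",
    "hmax_s1",
    "hmax_c1",
    "hmax_s2",
    "hmax_c2",
    "hmax_vtu",
    "hmax_run",
    "hmax_compare",
    "model_compare",
    "MODEL_NAMES",
]

#: Side length (px) at which both GaborJet and HMAX process images.  A power
#: of two keeps the FFT exact and divides evenly into the 10x10 jet grid.
WORKING_SIZE = 256

MODEL_NAMES = ("pixelwise", "gaborjet", "hmax")


# --------------------------------------------------------------------------
# dissimilarity container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DissimilarityMatrix:
    """Labelled n x n symmetric nonnegative distance matrix, zero diagonal."""

    values: np.ndarray
    labels: tuple
    model_name: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("dissimilarities must be finite")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be nonnegative")
        if not np.array_equal(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_csv(self, path) -> None:
        """Write as comma-delimited CSV with a label header row and column."""
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)


def _as_matrix(dist, images_repr, labels, model_name) -> DissimilarityMatrix:
    n = len(images_repr)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(images_repr[i], images_repr[j])
            vals[i, j] = vals[j, i] = d
    return DissimilarityMatrix(vals, tuple(labels), model_name)


# --------------------------------------------------------------------------
# pixelwise
# --------------------------------------------------------------------------

def pixelwise_compare(images, labels=None) -> DissimilarityMatrix:
    """Euclidean distance between all pairs of grayscale pixel vectors."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(
            f"images have mismatched sizes {sorted(shapes)}; resize first")
    if labels is None:
        labels = [f"im{i}" for i in range(len(images))]
    flat = [im.pixels.ravel() for im in images]
    return _as_matrix(
        lambda a, b: float(np.linalg.norm(a - b)), flat, labels, "pixelwise")


# --------------------------------------------------------------------------
# GaborJet
# --------------------------------------------------------------------------

N_GRID = 10          # grid points per side
N_ORI = 8            # orientations, steps of 45 degrees
N_FREQ = 5           # spatial-frequency levels
JET_SIGMA = 2.0 * np.pi  # Gaussian envelope parameter of the jet kernels


@dataclass(frozen=True)
class GaborJetDescriptor:
    """Magnitudes and phases of 100 jets x 5 frequencies x 8 orientations.

    Ordering is position-major, then frequency (low to high), then
    orientation (0 to 315 degrees): element ``p*40 + f*8 + o``.
    """

    magnitudes: np.ndarray   # (4000,) nonnegative
    phases: np.ndarray       # (4000,) radians in (-pi, pi]
    grid_positions: np.ndarray  # (100, 2) (row, col) pixel coordinates

    def __post_init__(self):
        m = np.asarray(self.magnitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        g = np.asarray(self.grid_positions, dtype=int)
        if m.shape != (N_GRID**2 * N_ORI * N_FREQ,) or p.shape != m.shape:
            raise ValueError("magnitudes and phases must have 4000 elements")
        if g.shape != (N_GRID**2, 2):
            raise ValueError("expected 100 (row, col) grid positions")
        if np.any(m < 0):
            raise ValueError("magnitudes must be nonnegative")
        object.__setattr__(self, "magnitudes", m)
        object.__setattr__(self, "phases", p)
        object.__setattr__(self, "grid_positions", g)


def _jet_grid(size: int = WORKING_SIZE) -> np.ndarray:
    """(row, col) centres of the 10x10 sampling grid, nearest-pixel rounded."""
    spacing = size / N_GRID
    coords = np.rint(spacing / 2.0 + spacing * np.arange(N_GRID)).astype(int)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def _jet_kernels_fft(size: int = WORKING_SIZE) -> np.ndarray:
    """Frequency-domain Gabor kernels, shape (N_FREQ, N_ORI, size, size).

    Classic dynamic-link-architecture parameterisation: centre frequency
    ``k_nu = (pi/2) / sqrt(2)**nu``, orientation ``mu * 45deg``, Gaussian
    envelope ``sigma = 2*pi``, with the DC response subtracted so constant
    images produce zero output.
    """
    f1 = np.fft.fftfreq(size) * 2.0 * np.pi  # radians per pixel
    fy, fx = np.meshgrid(f1, f1, indexing="ij")
    kernels = np.empty((N_FREQ, N_ORI, size, size))
    s2 = JET_SIGMA**2
    for nu in range(N_FREQ):
        k = (np.pi / 2.0) / np.sqrt(2.0) ** nu
        for mu in range(N_ORI):
            phi = mu * np.pi / 4.0
            kx = k * np.cos(phi)
            ky = k * np.sin(phi)
            bump = np.exp(-s2 * ((fx - kx) ** 2 + (fy - ky) ** 2) / (2.0 * k**2))
            dc = np.exp(-s2 * (fx**2 + fy**2 + k**2) / (2.0 * k**2))
            kernels[nu, mu] = bump - dc
    return kernels


_JET_CACHE: dict[int, np.ndarray] = {}


def gaborjet_run(image: LuminanceImage) -> GaborJetDescriptor:
    """Convolve with the jet filter bank in the Fourier domain and sample.

    Returns 4000 magnitudes, 4000 phases and the 100 grid positions.
    Constant images yield near-zero magnitudes (the kernels are DC-free).
    """
    px = image.pixels
    if px.shape != (WORKING_SIZE, WORKING_SIZE):
        raise ValueError(
            f"image must be {WORKING_SIZE}x{WORKING_SIZE}; resample first")
    if WORKING_SIZE not in _JET_CACHE:
        _JET_CACHE[WORKING_SIZE] = _jet_kernels_fft(WORKING_SIZE)
    kernels = _JET_CACHE[WORKING_SIZE]
    grid = _jet_grid(WORKING_SIZE)

    spectrum = np.fft.fft2(px)
    mags = np.empty((N_GRID**2, N_FREQ, N_ORI))
    phases = np.empty_like(mags)
    rows, cols = grid[:, 0], grid[:, 1]
    for nu in range(N_FREQ):
        for mu in range(N_ORI):
            resp = np.fft.ifft2(spectrum * kernels[nu, mu])
            samples = resp[rows, cols]
            mags[:, nu, mu] = np.abs(samples)
            phases[:, nu, mu] = np.angle(samples)
    return GaborJetDescriptor(mags.ravel(), phases.ravel(), grid)


def angular_distance(a, b) -> float:
    """Angle (radians) between two vectors: arccos of cosine similarity.

    For nonnegative inputs the result lies in [0, pi/2].
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angular distance undefined for zero-norm vectors")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def gaborjet_compare(images, labels=None) -> DissimilarityMatrix:
    """Pairwise angular distance between jet magnitude vectors."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if labels is None:
        labels = [f"im{i}" for i in range(len(images))]
    mags = [gaborjet_run(im).magnitudes for im in images]
    return _as_matrix(angular_distance, mags, labels, "gaborjet")


# --------------------------------------------------------------------------
# HMAX
# --------------------------------------------------------------------------

S1_SIZES = tuple(range(7, 30, 2))                 # 12 filter sizes, 7..29 px
S1_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)        # degrees
#: scale bands: consecutive triplets of S1 sizes
BANDS = ((7, 9, 11), (13, 15, 17), (19, 21, 23), (25, 27, 29))
C1_POOL_SIZES = (8, 10, 12, 14)                   # px, per band
C1_POOL_STRIDES = (4, 5, 6, 7)                    # half the neighbourhood
N_S2_CONFIGS = len(S1_ORIENTATIONS) ** 4          # 256 ordered assignments


@dataclass(frozen=True)
class S1Maps:
    """Absolute filter responses: ``maps[ori][size_index]`` valid-mode grids."""
    maps: tuple  # 4 orientations x 12 sizes of 2D arrays


@dataclass(frozen=True)
class C1Maps:
    """Per band, per orientation pooled grids: ``maps[band][ori]``."""
    maps: tuple  # 4 bands x 4 orientations of 2D arrays


@dataclass(frozen=True)
class S2Maps:
    """Per band, 256-configuration response stacks: ``maps[band]`` of
    shape (256, H-1, W-1)."""
    maps: tuple


@dataclass(frozen=True)
class HMAXDescriptor:
    """256-element C2 vector; `vtu` present iff training images were given."""

    c2: np.ndarray
    vtu: np.ndarray | None = None

    def __post_init__(self):
        c2 = np.asarray(self.c2, dtype=float)
        if c2.shape != (N_S2_CONFIGS,):
            raise ValueError("c2 must have 256 elements")
        object.__setattr__(self, "c2", c2)
        if self.vtu is not None:
            v = np.asarray(self.vtu, dtype=float)
            if np.any(v <= 0) or np.any(v > 1):
                raise ValueError("vtu activations must lie in (0, 1]")
            object.__setattr__(self, "vtu", v)


def _s1_kernel(size: int, ori_deg: float) -> np.ndarray:
    """Zero-mean, unit-norm Gabor kernel of the standard S1 recipe.

    sigma = 0.0036 s^2 + 0.35 s + 0.18, wavelength lambda = sigma / 0.8,
    aspect ratio 0.3.
    """
    sigma = 0.0036 * size**2 + 0.35 * size + 0.18
    lam = sigma / 0.8
    gamma = 0.3
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    # `ori_deg` names the preferred stimulus (stripe) orientation, so the
    # carrier runs perpendicular to it
    theta = np.deg2rad(ori_deg + 90.0)
    x0 = x * np.cos(theta) + y * np.sin(theta)
    y0 = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(x0**2 + (gamma * y0) ** 2) / (2.0 * sigma**2)) \
        * np.cos(2.0 * np.pi * x0 / lam)
    g -= g.mean()
    g /= np.linalg.norm(g)
    return g


_S1_KERNEL_CACHE: dict[tuple[int, float], np.ndarray] = {}


def hmax_s1(image: LuminanceImage) -> S1Maps:
    """S1: |valid-mode correlation| with 4 orientations x 12 filter sizes."""
    px = image.pixels
    if px.shape[0] < max(S1_SIZES) or px.shape[1] < max(S1_SIZES):
        raise ValueError(
            f"image smaller than the largest S1 filter ({max(S1_SIZES)} px)")
    maps = []
    for ori in S1_ORIENTATIONS:
        per_size = []
        for s in S1_SIZES:
            key = (s, ori)
            if key not in _S1_KERNEL_CACHE:
                _S1_KERNEL_CACHE[key] = _s1_kernel(s, ori)
            k = _S1_KERNEL_CACHE[key]
            # correlation = convolution with the flipped kernel
            resp = signal.fftconvolve(px, k[::-1, ::-1], mode="valid")
            per_size.append(np.abs(resp))
        maps.append(tuple(per_size))
    return S1Maps(tuple(maps))


def _center_crop(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    dr = (a.shape[0] - shape[0]) // 2
    dc = (a.shape[1] - shape[1]) // 2
    return a[dr:dr + shape[0], dc:dc + shape[1]]


def _max_pool(grid: np.ndarray, n: int, stride: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    if grid.shape[0] < n or grid.shape[1] < n:
        # degenerate: pool over whatever is available
        return np.array([[grid.max()]])
    w = sliding_window_view(grid, (n, n))[::stride, ::stride]
    return w.max(axis=(2, 3))


def hmax_c1(s1: S1Maps) -> C1Maps:
    """C1: per band and orientation, max over the band's 3 filter sizes
    (grids centre-cropped to a common extent), then local spatial max
    pooling with the band's neighbourhood and stride."""
    maps = []
    for b, band in enumerate(BANDS):
        size_idx = [S1_SIZES.index(s) for s in band]
        per_ori = []
        for o in range(len(S1_ORIENTATIONS)):
            grids = [s1.maps[o][i] for i in size_idx]
            common = (min(g.shape[0] for g in grids),
                      min(g.shape[1] for g in grids))
            stacked = np.stack([_center_crop(g, common) for g in grids])
            merged = stacked.max(axis=0)
            per_ori.append(_max_pool(merged, C1_POOL_SIZES[b],
                                     C1_POOL_STRIDES[b]))
        maps.append(tuple(per_ori))
    return C1Maps(tuple(maps))


def hmax_s2(c1: C1Maps) -> S2Maps:
    """S2: for each 2x2 C1 neighbourhood, all 256 ordered orientation
    assignments to the four cells, combined by the arithmetic mean."""
    n_ori = len(S1_ORIENTATIONS)
    out = []
    for band in c1.maps:
        stack = np.stack(band)  # (4, H, W)
        if stack.shape[1] < 2 or stack.shape[2] < 2:
            raise ValueError("C1 grid smaller than 2x2; image too small")
        tl = stack[:, :-1, :-1]
        tr = stack[:, :-1, 1:]
        bl = stack[:, 1:, :-1]
        br = stack[:, 1:, 1:]
        s2 = np.empty((N_S2_CONFIGS,) + tl.shape[1:])
        cfg = 0
        for a in range(n_ori):
            for b_ in range(n_ori):
                for c in range(n_ori):
                    for d in range(n_ori):
                        s2[cfg] = (tl[a] + tr[b_] + bl[c] + br[d]) / 4.0
                        cfg += 1
        out.append(s2)
    return S2Maps(tuple(out))


def hmax_c2(s2: S2Maps) -> np.ndarray:
    """C2: global max over positions and the four bands, per configuration."""
    per_band = np.stack([m.max(axis=(1, 2)) for m in s2.maps])
    return per_band.max(axis=0)


def hmax_vtu(c2, prototypes, sigma: float = 1.0) -> np.ndarray:
    """Gaussian view-tuned units: ``exp(-||c2 - w_k||^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    protos = [np.asarray(p, dtype=float) for p in prototypes]
    if not protos:
        raise ValueError("need at least one prototype")
    c2 = np.asarray(c2, dtype=float)
    d2 = np.array([np.sum((c2 - w) ** 2) for w in protos])
    return np.exp(-d2 / (2.0 * sigma**2))


def _c2_of(image: LuminanceImage) -> np.ndarray:
    return hmax_c2(hmax_s2(hmax_c1(hmax_s1(image))))


def hmax_run(test_ims, train_ims=None, vtu_sigma: float = 1.0):
    """Full S1->C1->S2->C2 stack per test image.

    If `train_ims` is given, their C2 vectors become VTU prototypes
    (unit-normalised) and every returned descriptor carries a `vtu` vector
    with one activation per training image.
    """
    if not test_ims:
        raise ValueError("test_ims must be nonempty")
    protos = None
    if train_ims is not None:
        if not train_ims:
            raise ValueError("train_ims, when given, must be nonempty")
        protos = [_unit(_c2_of(im)) for im in train_ims]
    out = []
    for im in test_ims:
        c2 = _c2_of(im)
        vtu = hmax_vtu(_unit(c2), protos, vtu_sigma) if protos is not None else None
        out.append(HMAXDescriptor(c2, vtu))
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def hmax_compare(images, labels=None) -> DissimilarityMatrix:
    """Euclidean distance between C2 vectors."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if labels is None:
        labels = [f"im{i}" for i in range(len(images))]
    c2s = [_c2_of(im) for im in images]
    return _as_matrix(
        lambda a, b: float(np.linalg.norm(a - b)), c2s, labels, "hmax")


# --------------------------------------------------------------------------
# uniform entry point
# --------------------------------------------------------------------------

def model_compare(model_name: str, image_paths) -> DissimilarityMatrix:
    """Load images at the model's working size, run it, return distances.

    Labels are the file stems.  Valid model names: pixelwise, gaborjet, hmax.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model_name!r}; valid names: {', '.join(MODEL_NAMES)}")
    if len(image_paths) < 2:
        raise ValueError("need at least 2 image paths")
    from pathlib import Path

    labels = [Path(p).stem for p in image_paths]
    images = [load_image(p, target_size=WORKING_SIZE) for p in image_paths]
    if model_name == "pixelwise":
        return pixelwise_compare(images, labels)
    if model_name == "gaborjet":
        return gaborjet_compare(images, labels)
    return hmax_compare(images, labels)
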