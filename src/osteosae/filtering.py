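"""Patch pre-processing: edge-preserving smoothing and contrast enhancement.

Histology patches are smoothed before feature extraction to suppress
stain-level pixel noise while keeping nuclear and stromal edges.  Two
smoothers are provided: a pure spatial Gaussian weighted average and a
(joint) bilateral filter whose kernel is the product of a spatial and an
intensity-range factor.

Kernel convention
-----------------
Both filters use ``exp(-d^2 / sigma^2)`` — note there is **no** factor of 2
in the denominator, unlike the textbook Gaussian ``exp(-d^2 / (2 sigma^2))``.
A ``sigma_s`` here therefore corresponds to ``sigma / sqrt(2)`` in the usual
parameterisation.  Kernels are truncated at ``radius`` and renormalised per
pixel over the in-image part of the window, so every output pixel is a convex
combination of input pixels and no padding is ever introduced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import imageio.v3 as iio
from skimage import exposure

__all__ = [
    "ImagePatch",
    "BilateralParams",
    "gaussian_filter",
    "bilateral_weight",
    "bilateral_filter",
    "enhance_contrast",
    "load_patches",
    "save_patch",
]

CLASS_NAMES = ("VT", "NVT", "NT")


class ParameterError(ValueError):
    """Invalid filter/model parameter."""


class InputError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass
class ImagePatch:
    """A 2-D (grayscale) or HxWx3 intensity patch with an optional class label.

    Intensities are expected in [0, 1] after :meth:`normalized`.
    """

    pixels: np.ndarray
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.size == 0:
            raise InputError("empty image")
        if self.pixels.ndim not in (2, 3):
            raise InputError(f"expected 2-D or HxWx3 pixels, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    def grayscale(self) -> "ImagePatch":
        """Channel-mean grayscale view (used for guide images)."""
        if not self.is_color:
            return self
        return ImagePatch(self.pixels.mean(axis=2), label=self.label, source=self.source)

    def normalized(self) -> "ImagePatch":
        """Rescale to [0, 1] from the native range (8-bit, 16-bit or float)."""
        px = self.pixels
        if px.max() > 1.0:
            scale = 65535.0 if px.max() > 255.0 else 255.0
            px = px / scale
        return ImagePatch(np.clip(px, 0.0, 1.0), label=self.label, source=self.source)


@dataclass
class BilateralParams:
    """Bilateral kernel scales.

    sigma_s : spatial scale in pixels; sigma_r : range scale in intensity
    units.  ``radius`` is the kernel half-width; by default wide enough
    (``ceil(2 * sigma_s)``) that truncation is negligible.
    """

    sigma_s: float = 2.0
    sigma_r: float = 0.1
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ParameterError("sigma_s and sigma_r must be strictly positive")
        if self.radius is None:
            self.radius = max(1, math.ceil(2.0 * self.sigma_s))
        if self.radius < 1:
            raise ParameterError("radius must be >= 1")


def _as_gray_array(img: ImagePatch | np.ndarray) -> np.ndarray:
    if isinstance(img, ImagePatch):
        return img.grayscale().pixels
    return np.asarray(img, dtype=float)


def gaussian_filter(img: ImagePatch, sigma_s: float, radius: int | None = None) -> ImagePatch:
    """Spatially weighted-average smoothing with a truncated Gaussian kernel.

    Color patches are filtered per channel.  The kernel is
    ``exp(-||p-q||^2 / sigma_s^2)`` truncated at ``radius`` and renormalised
    within each (possibly border-clipped) window, so the output is a convex
    combination of input pixels everywhere.
    """
    if sigma_s <= 0:
        raise ParameterError("sigma_s must be strictly positive")
    if radius is None:
        radius = max(1, math.ceil(2.0 * sigma_s))
    px = img.pixels
    if px.ndim == 3:
        out = np.stack(
            [_gaussian_2d(px[..., c], sigma_s, radius) for c in range(px.shape[2])], axis=2
        )
    else:
        out = _gaussian_2d(px, sigma_s, radius)
    return ImagePatch(out, label=img.label, source=img.source)


def _gaussian_2d(px: np.ndarray, sigma_s: float, radius: int) -> np.ndarray:
    # Separable: the 2-D kernel is a product, so row/column passes with a
    # shared renormalisation mask equal the windowed 2-D convolution.
    offsets = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(offsets**2) / sigma_s**2)
    num = _conv1d_trunc(_conv1d_trunc(px, k, axis=0), k, axis=1)
    ones = np.ones_like(px)
    den = _conv1d_trunc(_conv1d_trunc(ones, k, axis=0), k, axis=1)
    return num / den


def _conv1d_trunc(a: np.ndarray, k: np.ndarray, axis: int) -> np.ndarray:
    """Correlate along one axis, treating out-of-image samples as absent."""
    from scipy.ndimage import correlate1d

    return correlate1d(a, k, axis=axis, mode="constant", cval=0.0)


def bilateral_weight(
    p: tuple[int, int],
    q: tuple[int, int],
    P_q: float,
    Q_p: float,
    params: BilateralParams,
) -> float:
    """Unnormalised bilateral kernel weight between pixel sites ``p`` and ``q``.

    The spatial factor is ``exp(-||p-q||^2 / sigma_s^2)`` and the range factor
    ``exp(-(P_p - Q_q)^2 / sigma_r^2)`` where ``P_q``/``Q_p`` are the input and
    guide intensities entering the range term.  The product lies in (0, 1].
    """
    d2 = float((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
    spatial = math.exp(-d2 / params.sigma_s**2)
    rng = math.exp(-((P_q - Q_p) ** 2) / params.sigma_r**2)
    return spatial * rng


def bilateral_filter(
    img: ImagePatch,
    guide: ImagePatch | None = None,
    params: BilateralParams | None = None,
) -> ImagePatch:
    """Edge-preserving smoothing: per-pixel weighted average with bilateral weights.

    When ``guide`` is omitted the filter is self-guided (the classic single
    image bilateral form).  Weights are normalised to sum to one over the
    truncated window, which plays the role of the kernel's 1/n normaliser.
    Color patches are filtered per channel against a grayscale guide.
    """
    params = params or BilateralParams()
    px = img.pixels
    if guide is not None and guide.pixels.shape[:2] != px.shape[:2]:
        raise InputError(
            f"guide shape {guide.pixels.shape[:2]} != image shape {px.shape[:2]}"
        )
    if px.ndim == 3:
        guide_arr = _as_gray_array(guide) if guide is not None else None
        out = np.stack(
            [
                _bilateral_2d(px[..., c], guide_arr if guide_arr is not None else px[..., c], params)
                for c in range(px.shape[2])
            ],
            axis=2,
        )
    else:
        guide_arr = _as_gray_array(guide) if guide is not None else px
        out = _bilateral_2d(px, guide_arr, params)
    return ImagePatch(out, label=img.label, source=img.source)


def _bilateral_2d(px: np.ndarray, guide: np.ndarray, params: BilateralParams) -> np.ndarray:
    H, W = px.shape
    r = int(params.radius)
    num = np.zeros_like(px)
    den = np.zeros_like(px)
    inv_ss = 1.0 / params.sigma_s**2
    inv_sr = 1.0 / params.sigma_r**2
    # Accumulate one shifted contribution per window offset; out-of-image
    # offsets simply never contribute (truncation + renormalisation).
    for dy in range(-r, r + 1):
        ys_lo, ys_hi = max(0, -dy), H - max(0, dy)
        for dx in range(-r, r + 1):
            xs_lo, xs_hi = max(0, -dx), W - max(0, dx)
            if ys_hi <= ys_lo or xs_hi <= xs_lo:
                continue
            spatial = math.exp(-(dy * dy + dx * dx) * inv_ss)
            p_sl = (slice(ys_lo, ys_hi), slice(xs_lo, xs_hi))
            q_sl = (slice(ys_lo + dy, ys_hi + dy), slice(xs_lo + dx, xs_hi + dx))
            # Range term compares the input intensity at p with the guide at q.
            diff = px[p_sl] - guide[q_sl]
            w = spatial * np.exp(-(diff * diff) * inv_sr)
            num[p_sl] += w * px[q_sl]
            den[p_sl] += w
    return num / den


_ENHANCE_METHODS = ("histeq", "clahe", "minmax")


def enhance_contrast(img: ImagePatch, method: str = "clahe") -> ImagePatch:
    """Contrast enhancement on a [0, 1] patch.

    ``clahe`` (default, clip limit 0.01, 8x8 tiles) suits stain-variable
    histology; ``histeq`` is global equalisation; ``minmax`` is an affine
    stretch to full range.  Constant images pass through unchanged.
    """
    if method not in _ENHANCE_METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {_ENHANCE_METHODS}")
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo < -1e-9 or hi > 1.0 + 1e-9:
        raise InputError("enhance_contrast expects intensities in [0, 1]")
    if hi - lo < 1e-12:  # constant image: nothing to enhance
        return ImagePatch(px.copy(), label=img.label, source=img.source)
    if method == "minmax":
        out = (px - lo) / (hi - lo)
    elif method == "histeq":
        out = exposure.equalize_hist(px)
    else:
        kernel = tuple(max(2, s // 8) for s in px.shape[:2])
        out = exposure.equalize_adapthist(np.clip(px, 0, 1), kernel_size=kernel, clip_limit=0.01)
    return ImagePatch(np.clip(out, 0.0, 1.0), label=img.label, source=img.source)


# ---------------------------------------------------------------------------
# Patch I/O


def load_patches(
    source: str | Path,
    manifest: str | Path | None = None,
) -> list[ImagePatch]:
    """Load labelled patches from a directory tree or a CSV manifest.

    Without a manifest, immediate sub-directory names are the labels
    (``root/VT/img.png`` -> label ``VT``).  A manifest CSV needs columns
    ``path,label`` with paths relative to its own directory.
    """
    import pandas as pd

    root = Path(source)
    patches: list[ImagePatch] = []
    if manifest is not None:
        man = pd.read_csv(manifest)
        if not {"path", "label"} <= set(man.columns):
            raise InputError("manifest must have columns 'path' and 'label'")
        base = Path(manifest).parent
        for _, row in man.iterrows():
            px = iio.imread(base / row["path"])
            patches.append(ImagePatch(px, label=str(row["label"]), source=str(row["path"])).normalized())
        return patches
    if not root.is_dir():
        raise InputError(f"{root} is not a directory")
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
                patches.append(ImagePatch(iio.imread(f), label=sub.name, source=str(f)).normalized())
    if not patches:
        raise InputError(f"no image patches found under {root}")
    return patches


def save_patch(img: ImagePatch, path: str | Path) -> None:
    """Write a patch as 8-bit PNG plus a JSON sidecar recording normalisation."""
    path = Path(path)
    px = np.clip(img.pixels, 0.0, 1.0)
    iio.imwrite(path, (px * 255.0 + 0.5).astype(np.uint8))
    sidecar = {
        "scale": "uint8/255",
        "min": float(px.min()),
        "max": float(px.max()),
        "label": img.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
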