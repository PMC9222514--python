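"""Seeded three-class synthetic data: textured patches and feature tables.

The image generator emulates the appearance regimes of the three
osteosarcoma patch classes without any real data:

* ``VT`` (viable tumor) — dense high-frequency texture: many small dark
  ellipses (nuclei-like) on a bright background;
* ``NVT`` (non-viable/necrotic tumor) — fragmented texture: sparse, larger,
  irregular low-contrast blobs;
* ``NT`` (non-tumor) — smooth low-frequency background.

``separability`` in [0, 1] linearly interpolates every class-specific texture
parameter between a shared mid-point (0: classes indistinguishable) and the
fully distinct settings above (1).  Default class counts 345/263/536 mirror
the published benchmark's imbalance so that imbalance-sensitive metrics
(G-mean, MCC) are exercised realistically.

The feature generator draws a Gaussian mixture whose class means sit at a
controllable pairwise distance (in units of within-class standard deviation),
standing in for extracted network features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter as _ndi_gaussian

from .filtering import CLASS_NAMES, ImagePatch, InputError, ParameterError

__all__ = [
    "ImageGenSpec",
    "FeatureGenSpec",
    "generate_images",
    "generate_features",
    "stratified_split",
    "split",
    "write_dataset",
]


@dataclass
class ImageGenSpec:
    n_per_class: tuple[int, int, int] = (345, 263, 536)  # VT, NVT, NT
    patch_size: int = 128
    separability: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 32:
            raise ParameterError("patch_size must be >= 32")
        if not 0.0 <= self.separability <= 1.0:
            raise ParameterError("separability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# Class texture parameters at separability 1; the common point is their mean.
_TEXTURE = {
    "VT": dict(n_blobs=140, r_lo=2.0, r_hi=4.0, fg=0.15, bg=0.85, blur=0.6, smooth=0.0),
    "NVT": dict(n_blobs=18, r_lo=6.0, r_hi=12.0, fg=0.45, bg=0.65, blur=1.5, smooth=0.0),
    "NT": dict(n_blobs=0, r_lo=0.0, r_hi=0.0, fg=0.5, bg=0.55, blur=0.0, smooth=1.0),
}
_COMMON = {k: float(np.mean([v[k] for v in _TEXTURE.values()])) for k in _TEXTURE["VT"]}


def _blend(cls: str, s: float) -> dict:
    return {k: (1.0 - s) * _COMMON[k] + s * _TEXTURE[cls][k] for k in _COMMON}


def _draw_patch(cls: str, spec: ImageGenSpec, rng: np.random.Generator) -> np.ndarray:
    from skimage.draw import ellipse

    P = spec.patch_size
    par = _blend(cls, spec.separability)
    img = np.full((P, P), par["bg"])
    # Low-frequency background field, weighted by the class smoothness.
    field = _ndi_gaussian(rng.normal(size=(P, P)), sigma=P / 8.0)
    fr = field.max() - field.min()
    if fr > 0:
        img += par["smooth"] * 0.25 * (field - field.min()) / fr
    n_blobs = int(round(par["n_blobs"]))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, P, size=2)
        a = rng.uniform(max(0.5, par["r_lo"]), max(0.6, par["r_hi"]))
        b = a * rng.uniform(0.5, 1.0)
        rr, cc = ellipse(cy, cx, a, b, shape=(P, P), rotation=rng.uniform(0, math.pi))
        img[rr, cc] = par["fg"] + rng.normal(0, 0.03)
    if par["blur"] > 0.05:
        img = _ndi_gaussian(img, sigma=par["blur"])
    img += rng.normal(0, spec.noise_sd, size=(P, P))
    return np.clip(img, 0.0, 1.0)


def generate_images(spec: ImageGenSpec) -> list[ImagePatch]:
    """Generate labelled textured patches; deterministic for a fixed spec."""
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(CLASS_NAMES))
    patches: list[ImagePatch] = []
    for cls, n, ss in zip(CLASS_NAMES, spec.n_per_class, streams):
        rng = np.random.default_rng(ss)
        for i in range(n):
            patches.append(ImagePatch(_draw_patch(cls, spec, rng), label=cls, source=f"{cls}_{i:04d}"))
    return patches


@dataclass
class FeatureGenSpec:
    n_per_class: tuple[int, ...] = (150, 150, 150)
    dim: int = 10
    separation: float = 6.0  # pairwise class-mean distance, in within-class sd
    covariance: str = "isotropic"  # or "random_spd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ParameterError("dim must be >= 2")
        if self.separation < 0:
            raise ParameterError("separation must be >= 0")
        if self.covariance not in ("isotropic", "random_spd"):
            raise ParameterError("covariance must be 'isotropic' or 'random_spd'")


def generate_features(spec: FeatureGenSpec) -> tuple[np.ndarray, list[str]]:
    """Gaussian-mixture feature table with labels.

    Class means are placed on mutually orthogonal directions scaled so every
    pairwise mean distance equals ``separation`` (unit within-class sd along
    each axis for the isotropic case).
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.n_per_class)
    if k > spec.dim:
        raise ParameterError("need dim >= number of classes for orthogonal means")
    # Orthonormal directions via QR of a random matrix (seeded).
    Q, _ = np.linalg.qr(rng.normal(size=(spec.dim, k)))
    means = (spec.separation / math.sqrt(2.0)) * Q.T  # pairwise distance = separation
    if spec.covariance == "random_spd":
        A = rng.normal(size=(spec.dim, spec.dim)) / math.sqrt(spec.dim)
        cov = A @ A.T + 0.5 * np.eye(spec.dim)
        cov *= spec.dim / np.trace(cov)  # mean variance 1
        L = np.linalg.cholesky(cov)
    else:
        L = np.eye(spec.dim)
    X_parts, labels = [], []
    names = CLASS_NAMES[:k] if k <= len(CLASS_NAMES) else tuple(f"C{i}" for i in range(k))
    for mean, n, cls in zip(means, spec.n_per_class, names):
        X_parts.append(mean + rng.normal(size=(n, spec.dim)) @ L.T)
        labels.extend([cls] * n)
    return np.vstack(X_parts), labels


def stratified_split(
    labels: Sequence, train_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Index-level stratified split; per-class sizes within 1 of the exact product."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray([str(l) for l in labels])
    train_idx, test_idx = [], []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        if n_train == 0 or n_train == idx.size:
            import warnings

            warnings.warn(f"class {cls!r} has an empty side in the split")
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split(dataset: Sequence, fractions: tuple[float, float], seed: int = 0):
    """Stratified train/test partition of labelled items (``.label`` or (x, y)).

    ``fractions`` must sum to 1; presets (0.8, 0.2) and (0.7, 0.3) are the
    conventional choices.  Returns (train_items, test_items).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    labels = [getattr(item, "label", None) if hasattr(item, "label") else item[1] for item in dataset]
    tr, te = stratified_split(labels, fractions[0], seed=seed)
    return [dataset[i] for i in tr], [dataset[i] for i in te]


def write_dataset(patches: Sequence[ImagePatch], out_dir: str | Path,
                  spec: ImageGenSpec | None = None,
                  splits: dict[str, Sequence[int]] | None = None) -> Path:
    """Write patches as PNGs with a ``manifest.csv`` (path,label,split).

    The generation spec, when given, is echoed to ``genspec.yaml`` for
    provenance.
    """
    import pandas as pd
    import yaml

    from .filtering import save_patch

    out = Path(out_dir)
    rows = []
    split_of = {}
    if splits:
        for name, idxs in splits.items():
            for i in idxs:
                split_of[int(i)] = name
    for i, patch in enumerate(patches):
        label = patch.label or "unlabelled"
        sub = out / label
        sub.mkdir(parents=True, exist_ok=True)
        fname = f"{label}/{patch.source or f'patch_{i:05d}'}.png"
        save_patch(patch, out / fname)
        rows.append({"path": fname, "label": label, "split": split_of.get(i, "")})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if spec is not None:
        (out / "genspec.yaml").write_text(yaml.safe_dump(spec.__dict__))
    return out
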