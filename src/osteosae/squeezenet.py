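"""SqueezeNet-style convolutional feature extractor (NumPy forward pass).

The network follows the v1.1 layout: a strided 3x3 stem convolution, max
pooling, and eight *fire modules* — a 1x1 "squeeze" convolution feeding
parallel 1x1 and 3x3 "expand" branches whose outputs concatenate.  Replacing
3x3 kernels with 1x1 wherever possible divides the per-layer weight count by
9, which is what keeps the whole model around 1.2 M parameters (roughly 50x
smaller than an AlexNet-scale 60 M).

Here the network is used as a frozen transfer-learning feature extractor:
images pass through the convolutional trunk and the global-average-pool
activations (one value per channel, 512 for the default spec) form the
feature vector handed to the downstream classifier.  Weights come either
from a seeded He initialisation or from an imported weight container; only
the softmax head is trainable in-package (cross-entropy, mini-batch descent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .filtering import ImagePatch, InputError

__all__ = [
    "ConvLayerSpec",
    "FireModuleSpec",
    "MaxPoolSpec",
    "GlobalAvgPoolSpec",
    "ClassifierSpec",
    "NetworkSpec",
    "Network",
    "FeatureMatrix",
    "relu",
    "cross_entropy_cost",
    "build_network",
    "default_spec",
    "extract_features",
    "load_pretrained",
    "propagate_shapes",
]


class SpecError(ValueError):
    """Inconsistent network specification."""


def relu(x):
    """Rectified linear unit max(0, x), elementwise."""
    return np.maximum(0, x)


def cross_entropy_cost(predicted: np.ndarray, target: np.ndarray, m: int | None = None) -> float:
    """Mean cross-entropy -(1/m) * sum[x ln a + (1-x) ln(1-a)].

    ``predicted`` holds probabilities (clipped to [1e-12, 1-1e-12]);
    ``target`` the matching 0/1 (one-hot) values.  ``m`` defaults to the
    number of samples (rows for 2-D input, 1 for a vector/scalar).
    """
    a = np.clip(np.asarray(predicted, dtype=float), 1e-12, 1.0 - 1e-12)
    x = np.asarray(target, dtype=float)
    if a.shape != x.shape:
        raise InputError(f"shape mismatch: predicted {a.shape} vs target {x.shape}")
    if m is None:
        m = a.shape[0] if a.ndim >= 2 else 1
    return float(-np.sum(x * np.log(a) + (1.0 - x) * np.log(1.0 - a)) / m)


# ---------------------------------------------------------------------------
# Layer specifications


@dataclass
class ConvLayerSpec:
    name: str
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    stride: int = 1
    padding: int = 0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size not in (1, 3):
            raise SpecError(f"{self.name}: kernel_size must be 1 or 3")
        if self.in_channels < 1 or self.out_channels < 1 or self.stride < 1:
            raise SpecError(f"{self.name}: channel counts and stride must be positive")
        if self.activation not in ("relu", "none"):
            raise SpecError(f"{self.name}: activation must be 'relu' or 'none'")

    @property
    def n_params(self) -> int:
        return self.out_channels * (self.in_channels * self.kernel_size**2 + 1)


@dataclass
class FireModuleSpec:
    name: str
    in_channels: int
    squeeze_channels: int
    expand1_channels: int
    expand3_channels: int

    def __post_init__(self) -> None:
        if min(self.in_channels, self.squeeze_channels, self.expand1_channels, self.expand3_channels) < 1:
            raise SpecError(f"{self.name}: all channel counts must be positive")
        if self.squeeze_channels >= self.expand1_channels + self.expand3_channels:
            raise SpecError(f"{self.name}: squeeze must be narrower than the expand concat")

    @property
    def out_channels(self) -> int:
        return self.expand1_channels + self.expand3_channels

    @property
    def n_params(self) -> int:
        return (
            self.squeeze_channels * (self.in_channels + 1)
            + self.expand1_channels * (self.squeeze_channels + 1)
            + self.expand3_channels * (self.squeeze_channels * 9 + 1)
        )


@dataclass
class MaxPoolSpec:
    name: str
    kernel_size: int = 3
    stride: int = 2
    n_params: int = 0


@dataclass
class GlobalAvgPoolSpec:
    name: str
    n_params: int = 0


@dataclass
class ClassifierSpec:
    """Softmax head: a dense map on the pooled features (equivalent to a 1x1
    convolution applied before global average pooling)."""

    name: str
    in_features: int
    num_classes: int

    @property
    def n_params(self) -> int:
        return self.num_classes * (self.in_features + 1)


LayerSpec = ConvLayerSpec | FireModuleSpec | MaxPoolSpec | GlobalAvgPoolSpec | ClassifierSpec


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    tap_point: str = "gap"
    input_size: int = 128
    in_channels: int = 3

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(names) != len(set(names)):
            raise SpecError("duplicate layer names")
        if self.tap_point not in names:
            raise SpecError(f"tap_point {self.tap_point!r} names no layer")
        heads = [l for l in self.layers if isinstance(l, ClassifierSpec)]
        if len(heads) != 1 or not isinstance(self.layers[-1], ClassifierSpec):
            raise SpecError("exactly one classifier head, as the last layer")
        # Channel chaining.
        c = self.in_channels
        for l in self.layers:
            if isinstance(l, (ConvLayerSpec, FireModuleSpec)) and l.in_channels != c:
                raise SpecError(f"{l.name}: expects {l.in_channels} channels, receives {c}")
            if isinstance(l, ConvLayerSpec):
                c = l.out_channels
            elif isinstance(l, FireModuleSpec):
                c = l.out_channels
            elif isinstance(l, ClassifierSpec) and l.in_features != c:
                raise SpecError(f"{l.name}: expects {l.in_features} features, receives {c}")

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        doc = {
            "tap_point": self.tap_point,
            "input_size": self.input_size,
            "in_channels": self.in_channels,
            "layers": [
                {"type": type(l).__name__, **{k: v for k, v in l.__dict__.items()}}
                for l in self.layers
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        types = {t.__name__: t for t in (ConvLayerSpec, FireModuleSpec, MaxPoolSpec,
                                         GlobalAvgPoolSpec, ClassifierSpec)}
        layers = []
        for entry in doc["layers"]:
            entry = dict(entry)
            t = types[entry.pop("type")]
            entry.pop("n_params", None)
            layers.append(t(**entry))
        return cls(layers, tap_point=doc["tap_point"], input_size=doc["input_size"],
                   in_channels=doc["in_channels"])


def default_spec(input_size: int = 128, num_classes: int = 3) -> NetworkSpec:
    """The standard v1.1-style layout: stem conv, 3 pools, 8 fire modules."""

    def fire(name, cin, s, e):
        return FireModuleSpec(name, cin, s, e, e)

    layers: list[LayerSpec] = [
        ConvLayerSpec("conv1", 3, 64, kernel_size=3, stride=2),
        MaxPoolSpec("pool1"),
        fire("fire2", 64, 16, 64),
        fire("fire3", 128, 16, 64),
        MaxPoolSpec("pool3"),
        fire("fire4", 128, 32, 128),
        fire("fire5", 256, 32, 128),
        MaxPoolSpec("pool5"),
        fire("fire6", 256, 48, 192),
        fire("fire7", 384, 48, 192),
        fire("fire8", 384, 64, 256),
        fire("fire9", 512, 64, 256),
        GlobalAvgPoolSpec("gap"),
        ClassifierSpec("classifier", 512, num_classes),
    ]
    return NetworkSpec(layers, tap_point="gap", input_size=input_size, in_channels=3)


# ---------------------------------------------------------------------------
# Shape propagation (also used by tests as the contract for spatial sizes)


def _conv_out(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def propagate_shapes(spec: NetworkSpec) -> dict[str, tuple]:
    """(channels, height, width) after every layer; the head yields (classes,)."""
    c, h, w = spec.in_channels, spec.input_size, spec.input_size
    shapes: dict[str, tuple] = {}
    for l in spec.layers:
        if isinstance(l, ConvLayerSpec):
            h, w = _conv_out(h, l.kernel_size, l.stride, l.padding), _conv_out(w, l.kernel_size, l.stride, l.padding)
            c = l.out_channels
            shapes[l.name] = (c, h, w)
        elif isinstance(l, FireModuleSpec):
            c = l.out_channels  # expand-3x3 branch uses padding 1: spatial size kept
            shapes[l.name] = (c, h, w)
        elif isinstance(l, MaxPoolSpec):
            h, w = _conv_out(h, l.kernel_size, l.stride, 0), _conv_out(w, l.kernel_size, l.stride, 0)
            shapes[l.name] = (c, h, w)
        elif isinstance(l, GlobalAvgPoolSpec):
            shapes[l.name] = (c,)
            h = w = 1
        else:
            shapes[l.name] = (l.num_classes,)
        if isinstance(l, (ConvLayerSpec, MaxPoolSpec)) and min(h, w) < 1:
            raise InputError(f"spatial size collapsed to zero at layer {l.name}")
    return shapes


# ---------------------------------------------------------------------------
# Forward implementation


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (C,H,W); W: (O,C,k,k) -> (O,H',W') via im2col."""
    O, C, k, _ = W.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    _, H, Wd = x.shape
    Ho, Wo = (H - k) // stride + 1, (Wd - k) // stride + 1
    if k == 1:
        patches = x[:, ::stride, ::stride][:, :Ho, :Wo].reshape(C, -1)
    else:
        s0, s1, s2 = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x, shape=(C, Ho, Wo, k, k), strides=(s0, s1 * stride, s2 * stride, s1, s2),
            writeable=False,
        )
        patches = windows.transpose(0, 3, 4, 1, 2).reshape(C * k * k, Ho * Wo)
    out = W.reshape(O, -1) @ patches + b[:, None]
    return out.reshape(O, Ho, Wo)


def _maxpool(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    C, H, W = x.shape
    Ho, Wo = (H - k) // stride + 1, (W - k) // stride + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(C, Ho, Wo, k, k), strides=(s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False,
    )
    return windows.max(axis=(3, 4))


class Network:
    """A built network: spec + weights; forward pass with activation taps."""

    def __init__(self, spec: NetworkSpec, weights: dict[str, np.ndarray]):
        self.spec = spec
        self.weights = weights

    def forward(self, x: np.ndarray, taps: Sequence[str] = ()) -> dict[str, np.ndarray]:
        """Run one (C,H,W) image; returns {layer name: activation} for the
        requested taps plus ``"output"`` (softmax probabilities)."""
        if x.shape != (self.spec.in_channels, self.spec.input_size, self.spec.input_size):
            raise InputError(
                f"expected input {(self.spec.in_channels, self.spec.input_size, self.spec.input_size)}, got {x.shape}"
            )
        taps = set(taps)
        out: dict[str, np.ndarray] = {}
        for l in self.spec.layers:
            if isinstance(l, ConvLayerSpec):
                x = _conv2d(x, self.weights[f"{l.name}.W"], self.weights[f"{l.name}.b"], l.stride, l.padding)
                if l.activation == "relu":
                    x = relu(x)
            elif isinstance(l, FireModuleSpec):
                s = relu(_conv2d(x, self.weights[f"{l.name}.squeeze.W"], self.weights[f"{l.name}.squeeze.b"], 1, 0))
                e1 = relu(_conv2d(s, self.weights[f"{l.name}.expand1.W"], self.weights[f"{l.name}.expand1.b"], 1, 0))
                e3 = relu(_conv2d(s, self.weights[f"{l.name}.expand3.W"], self.weights[f"{l.name}.expand3.b"], 1, 1))
                x = np.concatenate([e1, e3], axis=0)
            elif isinstance(l, MaxPoolSpec):
                x = _maxpool(x, l.kernel_size, l.stride)
            elif isinstance(l, GlobalAvgPoolSpec):
                x = x.mean(axis=(1, 2))
            else:  # classifier head
                logits = self.weights[f"{l.name}.W"] @ x.ravel() + self.weights[f"{l.name}.b"]
                z = logits - logits.max()
                e = np.exp(z)
                x = e / e.sum()
            if l.name in taps:
                out[l.name] = x.copy()
        out["output"] = x
        return out

    def parameter_count(self) -> int:
        return sum(w.size for w in self.weights.values())

    def export_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}


def _he(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> Network:
    """Deterministically initialise a network (He-normal weights, zero biases)."""
    spec = spec or default_spec()
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {}
    for l in spec.layers:
        if isinstance(l, ConvLayerSpec):
            fan = l.in_channels * l.kernel_size**2
            w[f"{l.name}.W"] = _he(rng, (l.out_channels, l.in_channels, l.kernel_size, l.kernel_size), fan)
            w[f"{l.name}.b"] = np.zeros(l.out_channels)
        elif isinstance(l, FireModuleSpec):
            w[f"{l.name}.squeeze.W"] = _he(rng, (l.squeeze_channels, l.in_channels, 1, 1), l.in_channels)
            w[f"{l.name}.squeeze.b"] = np.zeros(l.squeeze_channels)
            w[f"{l.name}.expand1.W"] = _he(rng, (l.expand1_channels, l.squeeze_channels, 1, 1), l.squeeze_channels)
            w[f"{l.name}.expand1.b"] = np.zeros(l.expand1_channels)
            w[f"{l.name}.expand3.W"] = _he(rng, (l.expand3_channels, l.squeeze_channels, 3, 3), l.squeeze_channels * 9)
            w[f"{l.name}.expand3.b"] = np.zeros(l.expand3_channels)
        elif isinstance(l, ClassifierSpec):
            w[f"{l.name}.W"] = _he(rng, (l.num_classes, l.in_features), l.in_features)
            w[f"{l.name}.b"] = np.zeros(l.num_classes)
    return Network(spec, w)


class WeightImportError(ValueError):
    """A pretrained container does not match the spec (names the layer)."""


def load_pretrained(weights_source: str | Path | Mapping[str, np.ndarray],
                    spec: NetworkSpec | None = None) -> Network:
    """Build a network from an imported weight container.

    ``weights_source`` is a mapping name -> array or a path to an ``.npz``
    with the same keys as :meth:`Network.export_weights`.  Every expected
    entry must be present with the exact shape; mismatches raise
    :class:`WeightImportError` naming the offending layer entry.
    """
    spec = spec or default_spec()
    if isinstance(weights_source, (str, Path)):
        with np.load(weights_source) as blob:
            container = {k: np.array(blob[k]) for k in blob.files}
    else:
        container = {k: np.asarray(v, dtype=float) for k, v in weights_source.items()}
    template = build_network(spec, seed=0).weights
    imported: dict[str, np.ndarray] = {}
    for key, ref in template.items():
        if key not in container:
            raise WeightImportError(f"missing weight entry {key!r}")
        arr = np.asarray(container[key], dtype=float)
        if arr.shape != ref.shape:
            raise WeightImportError(f"shape mismatch at {key!r}: expected {ref.shape}, got {arr.shape}")
        imported[key] = arr
    return Network(spec, imported)


# ---------------------------------------------------------------------------
# Feature extraction


@dataclass
class FeatureMatrix:
    """samples x features values with aligned sample identifiers."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.sample_ids):
            raise InputError("row count != number of sample ids")
        if not np.all(np.isfinite(self.values)):
            raise InputError("non-finite feature values")

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[str(i) for i in range(self.feature_dim)])
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df.drop(columns=["sample_id"]).to_numpy(float), [str(s) for s in df["sample_id"]])

    def to_cache(self, path: str | Path) -> None:
        """Compact binary cache plus a JSON shape sidecar."""
        path = Path(path)
        with open(path, "wb") as f:
            np.savez(f, values=self.values, sample_ids=np.array(self.sample_ids))
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"n_samples": self.values.shape[0], "feature_dim": self.feature_dim})
        )

    @classmethod
    def from_cache(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as blob:
            return cls(blob["values"], [str(s) for s in blob["sample_ids"]])


def _prepare_input(img: ImagePatch, size: int) -> np.ndarray:
    """Resize (bilinear) to the network input size; grayscale -> 3 channels."""
    from skimage.transform import resize

    px = img.normalized().pixels
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if min(px.shape[:2]) < 8:
        raise InputError(f"image {img.source or ''} too small to resize to {size}x{size}")
    if px.shape[:2] != (size, size):
        px = resize(px, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    return np.ascontiguousarray(px.transpose(2, 0, 1))


def extract_features(images: Sequence[ImagePatch], net: Network,
                     tap_point: str | None = None) -> FeatureMatrix:
    """Frozen-network features: one row per image from the tap activations.

    Deterministic for fixed weights; the feature dimension is the flattened
    activation size at the tap (channel count for the default GAP tap).
    """
    tap = tap_point or net.spec.tap_point
    rows, ids = [], []
    for i, img in enumerate(images):
        x = _prepare_input(img, net.spec.input_size)
        acts = net.forward(x, taps=(tap,))
        rows.append(acts[tap].ravel())
        ids.append(img.source or f"sample_{i:05d}")
    return FeatureMatrix(np.vstack(rows), ids)


def fit_head(net: Network, features: FeatureMatrix, labels: Sequence[str],
             class_names: Sequence[str], epochs: int = 50, learning_rate: float = 0.1,
             batch_size: int = 32, seed: int = 0) -> list[float]:
    """Train the softmax head on tap features by mini-batch gradient descent.

    Uses the mean cross-entropy cost; the convolutional trunk stays frozen.
    Returns the per-epoch cost trace (useful to confirm descent).
    """
    head = next(l for l in net.spec.layers if isinstance(l, ClassifierSpec))
    idx = {c: i for i, c in enumerate(class_names)}
    T = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        T[i, idx[str(lab)]] = 1.0
    X = features.values
    W = net.weights[f"{head.name}.W"]
    b = net.weights[f"{head.name}.b"]
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            sl = order[start:start + batch_size]
            logits = X[sl] @ W.T + b
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            P = e / e.sum(axis=1, keepdims=True)
            dL = (P - T[sl]) / len(sl)
            W -= learning_rate * (dL.T @ X[sl])
            b -= learning_rate * dL.sum(axis=0)
        logits = X @ W.T + b
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        P = e / e.sum(axis=1, keepdims=True)
        trace.append(cross_entropy_cost(P, T))
    net.weights[f"{head.name}.W"] = W
    net.weights[f"{head.name}.b"] = b
    return trace
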