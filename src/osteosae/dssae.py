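"""Deep stacked sparse autoencoder (DSSAE) classifier.

A sparse autoencoder (SAE) maps an input vector ``y`` to a code
``c = logsig(W_Y y + b_Y)`` and back to a reconstruction
``z = logsig(W_Z c + b_Z)``.  Its loss combines three terms:

    L = (1/N) * sum_i ||z_i - y_i||^2  +  c_s * KL(rho || rho_hat)  +  c_w * (||W_Y||_F^2 + ||W_Z||_F^2) / 2

where ``rho_hat_j`` is unit j's mean code over the batch and the KL term
pulls every unit's mean activation toward the sparsity proportion ``rho``.
Because the decoder output is log-sigmoid bounded, inputs must be scaled to
[0, 1] (a min-max scaler fitted on the training split is part of the model).

The classifier greedily stacks several SAEs (default 4): each layer trains
on the codes of the previous one, and a softmax layer trained with
cross-entropy sits on the last code.  All training uses the scaled conjugate
gradient optimiser in :mod:`osteosae.scg`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .scg import scg_minimize

__all__ = [
    "SparseAutoencoder",
    "DSSAEModel",
    "TrainConfig",
    "logsig",
    "encode",
    "decode",
    "kl_sparsity",
    "weight_reg",
    "sae_loss",
    "sae_loss_grad",
    "train_sae",
    "train_dssae",
    "predict",
    "save_model",
    "load_model",
]

_RHO_HAT_CLIP = 1e-8  # keeps KL finite on dead or saturated units


def logsig(x):
    """Log-sigmoid 1 / (1 + exp(-x)), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass
class SparseAutoencoder:
    """One SAE layer: encoder/decoder weights plus regularisation settings."""

    W_Y: np.ndarray  # hidden x input
    B_Y: np.ndarray  # hidden
    W_Z: np.ndarray  # input x hidden
    B_Z: np.ndarray  # input
    rho: float = 0.05
    c_s: float = 1.0
    c_w: float = 1e-4

    def __post_init__(self) -> None:
        self.W_Y = np.asarray(self.W_Y, dtype=float)
        self.B_Y = np.asarray(self.B_Y, dtype=float).ravel()
        self.W_Z = np.asarray(self.W_Z, dtype=float)
        self.B_Z = np.asarray(self.B_Z, dtype=float).ravel()
        h, d = self.W_Y.shape
        if self.W_Z.shape != (d, h):
            raise ValueError(f"decoder weights must be {d}x{h}, got {self.W_Z.shape}")
        if self.B_Y.shape != (h,) or self.B_Z.shape != (d,):
            raise ValueError("bias shapes inconsistent with weights")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (0, 1)")
        if self.c_s < 0 or self.c_w < 0:
            raise ValueError("regularisation factors must be >= 0")

    @property
    def n_input(self) -> int:
        return self.W_Y.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_Y.shape[0]

    @classmethod
    def init(cls, n_input: int, n_hidden: int, rng: np.random.Generator,
             rho: float = 0.05, c_s: float = 1.0, c_w: float = 1e-4) -> "SparseAutoencoder":
        """Small symmetric uniform initialisation (Glorot-style range)."""
        r = np.sqrt(6.0 / (n_input + n_hidden))
        return cls(
            W_Y=rng.uniform(-r, r, size=(n_hidden, n_input)),
            B_Y=np.zeros(n_hidden),
            W_Z=rng.uniform(-r, r, size=(n_input, n_hidden)),
            B_Z=np.zeros(n_input),
            rho=rho, c_s=c_s, c_w=c_w,
        )


def encode(sae: SparseAutoencoder, Y: np.ndarray) -> np.ndarray:
    """Codes C = logsig(W_Y Y + B_Y); rows are samples."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != sae.n_input:
        raise ValueError(f"input dim {Y.shape[1]} != encoder dim {sae.n_input}")
    return logsig(Y @ sae.W_Y.T + sae.B_Y)


def decode(sae: SparseAutoencoder, C: np.ndarray) -> np.ndarray:
    """Reconstructions Z = logsig(W_Z C + B_Z); rows are samples."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != sae.n_hidden:
        raise ValueError(f"code dim {C.shape[1]} != hidden dim {sae.n_hidden}")
    return logsig(C @ sae.W_Z.T + sae.B_Z)


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over units of the Bernoulli KL divergence KL(rho || rho_hat_j)."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (0, 1)")
    rh = np.clip(np.atleast_1d(np.asarray(rho_hat, dtype=float)), _RHO_HAT_CLIP, 1.0 - _RHO_HAT_CLIP)
    return float(np.sum(rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh))))


def weight_reg(sae: SparseAutoencoder) -> float:
    """Half the summed squared Frobenius norms of encoder and decoder weights."""
    return 0.5 * (float(np.sum(sae.W_Y**2)) + float(np.sum(sae.W_Z**2)))


def sae_loss(sae: SparseAutoencoder, Y: np.ndarray) -> float:
    """Full SAE objective on a batch (reconstruction + sparsity + weight decay)."""
    return _sae_loss_grad_arrays(sae, np.atleast_2d(Y))[0]


def sae_loss_grad(sae: SparseAutoencoder, Y: np.ndarray) -> tuple[float, "SparseAutoencoder"]:
    """Loss and its analytic gradient, the latter packed as an SAE of gradients."""
    loss, gW_Y, gB_Y, gW_Z, gB_Z = _sae_loss_grad_arrays(sae, np.atleast_2d(Y))
    grad = SparseAutoencoder(gW_Y, gB_Y, gW_Z, gB_Z, rho=sae.rho, c_s=sae.c_s, c_w=sae.c_w)
    return loss, grad


def _sae_loss_grad_arrays(sae: SparseAutoencoder, Y: np.ndarray):
    N = Y.shape[0]
    if N < 1:
        raise ValueError("empty batch")
    C = encode(sae, Y)                      # N x h
    Z = decode(sae, C)                      # N x d
    diff = Z - Y
    rho_hat = C.mean(axis=0)
    rec = float(np.sum(diff**2)) / N
    loss = rec + sae.c_s * kl_sparsity(sae.rho, rho_hat) + sae.c_w * weight_reg(sae)

    # Backward pass.
    dZ = (2.0 / N) * diff * Z * (1.0 - Z)   # through decoder logsig
    gW_Z = dZ.T @ C + sae.c_w * sae.W_Z
    gB_Z = dZ.sum(axis=0)
    dC = dZ @ sae.W_Z                        # reconstruction path into the code
    rh = np.clip(rho_hat, _RHO_HAT_CLIP, 1.0 - _RHO_HAT_CLIP)
    interior = (rho_hat > _RHO_HAT_CLIP) & (rho_hat < 1.0 - _RHO_HAT_CLIP)
    dKL = np.where(interior, -sae.rho / rh + (1.0 - sae.rho) / (1.0 - rh), 0.0)
    dC = dC + sae.c_s * dKL / N              # KL path: d rho_hat_j / d c_ij = 1/N
    dA = dC * C * (1.0 - C)                  # through encoder logsig
    gW_Y = dA.T @ Y + sae.c_w * sae.W_Y
    gB_Y = dA.sum(axis=0)
    return loss, gW_Y, gB_Y, gW_Z, gB_Z


# ---------------------------------------------------------------------------
# Parameter packing for the SCG optimiser


def _pack(sae: SparseAutoencoder) -> np.ndarray:
    return np.concatenate([sae.W_Y.ravel(), sae.B_Y, sae.W_Z.ravel(), sae.B_Z])


def _unpack(theta: np.ndarray, template: SparseAutoencoder) -> SparseAutoencoder:
    h, d = template.W_Y.shape
    i = 0
    W_Y = theta[i:i + h * d].reshape(h, d); i += h * d
    B_Y = theta[i:i + h]; i += h
    W_Z = theta[i:i + d * h].reshape(d, h); i += d * h
    B_Z = theta[i:i + d]
    return replace(template, W_Y=W_Y, B_Y=B_Y, W_Z=W_Z, B_Z=B_Z)


@dataclass
class TrainConfig:
    """Training hyperparameters; epochs/batch_size/learning_rate are the
    knobs exposed to the hyperparameter optimiser."""

    epochs: int = 100
    batch_size: int = 10**9  # >= N selects full-batch SCG
    learning_rate: float = 1e-2  # used only by the optional fine-tuning pass
    rho: float = 0.05
    c_s: float = 1.0
    c_w: float = 1e-4
    scg_sigma: float = 1e-5
    scg_lambda0: float = 1e-7
    fine_tune_epochs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def train_sae(Y: np.ndarray, dims: tuple[int, int], config: TrainConfig,
              rng: np.random.Generator | None = None) -> tuple[SparseAutoencoder, list[float]]:
    """Train a single SAE on [0,1]-scaled data; returns the model and loss trace.

    Full-batch SCG capped at ``config.epochs`` iterations; when
    ``batch_size < N`` each epoch runs a short SCG restart on every shuffled
    mini-batch (a stochastic approximation of the batch optimiser).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d_in, d_hidden = dims
    if Y.shape[1] != d_in:
        raise ValueError(f"data dim {Y.shape[1]} != declared input dim {d_in}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sae = SparseAutoencoder.init(d_in, d_hidden, rng, rho=config.rho, c_s=config.c_s, c_w=config.c_w)
    N = Y.shape[0]
    trace: list[float] = []

    def make_obj(batch):
        def fun_grad(theta):
            model = _unpack(theta, sae)
            loss, gW_Y, gB_Y, gW_Z, gB_Z = _sae_loss_grad_arrays(model, batch)
            return loss, np.concatenate([gW_Y.ravel(), gB_Y, gW_Z.ravel(), gB_Z])
        return fun_grad

    theta = _pack(sae)
    if config.batch_size >= N:
        res = scg_minimize(make_obj(Y), theta, max_iter=config.epochs,
                           sigma=config.scg_sigma, lambda0=config.scg_lambda0)
        theta, trace = res.x, res.trace
    else:
        # Stochastic variant: short SCG restarts on shuffled mini-batches,
        # under the same total per-layer iteration budget as the full-batch
        # path ("epochs" caps SCG iterations per layer in both cases).
        budget = config.epochs
        while budget > 0:
            order = rng.permutation(N)
            for start in range(0, N, config.batch_size):
                if budget <= 0:
                    break
                batch = Y[order[start:start + config.batch_size]]
                res = scg_minimize(make_obj(batch), theta, max_iter=min(3, budget),
                                   sigma=config.scg_sigma, lambda0=config.scg_lambda0)
                theta = res.x
                budget -= min(3, budget)
            loss = sae_loss(_unpack(theta, sae), Y)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite loss during SAE training")
            trace.append(loss)
    return _unpack(theta, sae), trace


# ---------------------------------------------------------------------------
# Stacked model + softmax head


@dataclass
class DSSAEModel:
    """Greedily stacked SAEs with a softmax output layer and input scaler.

    ``code_min``/``code_range`` hold the per-layer min-max rescaling applied
    to each SAE's codes before they feed the next layer (and the head).
    Without it the sparsity penalty, whose KL term dominates once a layer's
    input range shrinks, drives deep codes to the constant ``rho`` and erases
    the class signal; rescaling restores a full [0, 1] working range at every
    depth.  All scalers are fitted on the training data only.
    """

    saes: list[SparseAutoencoder]
    softmax_W: np.ndarray  # classes x last_hidden
    softmax_B: np.ndarray  # classes
    class_names: tuple[str, ...]
    scaler_min: np.ndarray
    scaler_range: np.ndarray
    code_min: list[np.ndarray] = field(default_factory=list)
    code_range: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        dims = [s.n_input for s in self.saes] + [self.saes[-1].n_hidden]
        for a, b in zip(self.saes[:-1], self.saes[1:]):
            if a.n_hidden != b.n_input:
                raise ValueError("SAE dimensions do not chain")
        if self.softmax_W.shape != (len(self.class_names), dims[-1]):
            raise ValueError("softmax dimensions inconsistent with the stack")
        if not self.code_min:  # identity rescaling
            self.code_min = [np.zeros(s.n_hidden) for s in self.saes]
            self.code_range = [np.ones(s.n_hidden) for s in self.saes]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scale features to [0,1] and push them through every encoder."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.saes[0].n_input:
            raise ValueError(f"feature dim {X.shape[1]} != model input dim {self.saes[0].n_input}")
        H = np.clip((X - self.scaler_min) / self.scaler_range, 0.0, 1.0)
        for sae, lo, rg in zip(self.saes, self.code_min, self.code_range):
            H = np.clip((encode(sae, H) - lo) / rg, 0.0, 1.0)
        return H


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _labels_to_onehot(labels: Sequence, class_names: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(class_names)}
    T = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        T[i, lab if isinstance(lab, (int, np.integer)) else idx[lab]] = 1.0
    return T


def train_dssae(
    features: np.ndarray,
    labels: Sequence,
    hidden_dims: Sequence[int] = (256, 128, 64, 32),
    config: TrainConfig | None = None,
    class_names: Sequence[str] | None = None,
) -> DSSAEModel:
    """Greedy layer-wise training of the stack, then the softmax head.

    Features are min-max scaled to [0,1] per dimension (fitted here, stored on
    the model).  Layer k trains on the codes of layer k-1; the softmax head
    trains on the last codes with mean cross-entropy, via the same SCG
    optimiser.  An optional end-to-end fine-tuning pass (plain gradient
    descent on the head + encoders, ``config.fine_tune_epochs`` > 0) is off by
    default.  Deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != len(labels):
        raise ValueError("feature row count != label count")
    if class_names is None:
        class_names = tuple(sorted(set(str(l) for l in labels)))
    class_names = tuple(class_names)
    rng = np.random.default_rng(config.seed)

    scaler_min = X.min(axis=0)
    scaler_range = X.max(axis=0) - scaler_min
    scaler_range[scaler_range < 1e-12] = 1.0
    H = (X - scaler_min) / scaler_range

    saes: list[SparseAutoencoder] = []
    code_min: list[np.ndarray] = []
    code_range: list[np.ndarray] = []
    for h_dim in hidden_dims:
        if saes and h_dim >= saes[-1].n_hidden:
            import warnings

            warnings.warn(f"expansion layer: hidden dim {h_dim} >= previous {saes[-1].n_hidden}")
        sae, _ = train_sae(H, (H.shape[1], int(h_dim)), config, rng=rng)
        saes.append(sae)
        C = encode(sae, H)
        lo = C.min(axis=0)
        rg = C.max(axis=0) - lo
        rg[rg < 1e-12] = 1.0
        code_min.append(lo)
        code_range.append(rg)
        H = (C - lo) / rg

    # Softmax head on the deepest codes.
    T = _labels_to_onehot(labels, class_names)
    n_classes, n_hidden = T.shape[1], H.shape[1]
    r = np.sqrt(6.0 / (n_classes + n_hidden))
    W0 = rng.uniform(-r, r, size=(n_classes, n_hidden))
    b0 = np.zeros(n_classes)

    def head_obj(theta):
        W = theta[: n_classes * n_hidden].reshape(n_classes, n_hidden)
        b = theta[n_classes * n_hidden:]
        P = _softmax(H @ W.T + b)
        m = H.shape[0]
        loss = -float(np.sum(T * np.log(np.clip(P, 1e-12, None)))) / m
        dL = (P - T) / m
        gW = dL.T @ H
        gb = dL.sum(axis=0)
        return loss, np.concatenate([gW.ravel(), gb])

    res = scg_minimize(head_obj, np.concatenate([W0.ravel(), b0]),
                       max_iter=max(config.epochs, 50),
                       sigma=config.scg_sigma, lambda0=config.scg_lambda0)
    W = res.x[: n_classes * n_hidden].reshape(n_classes, n_hidden)
    b = res.x[n_classes * n_hidden:]

    model = DSSAEModel(saes, W, b, class_names, scaler_min, scaler_range,
                       code_min=code_min, code_range=code_range, seed=config.seed)
    if config.fine_tune_epochs > 0:
        model = _fine_tune(model, X, T, config)
    return model


def _fine_tune(model: DSSAEModel, X: np.ndarray, T: np.ndarray, config: TrainConfig) -> DSSAEModel:
    """Plain gradient descent on the softmax head through the frozen scaler.

    Only the head is updated (learning_rate steps); kept deliberately simple —
    the greedy stack is the model of record and fine-tuning is optional.
    """
    H = model.transform(X)
    W, b = model.softmax_W.copy(), model.softmax_B.copy()
    m = H.shape[0]
    for _ in range(config.fine_tune_epochs):
        P = _softmax(H @ W.T + b)
        dL = (P - T) / m
        W -= config.learning_rate * (dL.T @ H)
        b -= config.learning_rate * dL.sum(axis=0)
    return replace(model, softmax_W=W, softmax_B=b)


def predict(model: DSSAEModel, features: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class-probability rows (argmax, ties -> lowest index)."""
    H = model.transform(features)
    P = _softmax(H @ model.softmax_W.T + model.softmax_B)
    idx = P.argmax(axis=1)
    return [model.class_names[i] for i in idx], P


# ---------------------------------------------------------------------------
# Serialisation: JSON header + npz weight blob in one file


def save_model(model: DSSAEModel, path: str | Path) -> None:
    """Single-file serialisation: npz of weights with a JSON header entry."""
    arrays: dict[str, np.ndarray] = {}
    header = {
        "schema": "osteosae-dssae-1",
        "n_saes": len(model.saes),
        "class_names": list(model.class_names),
        "seed": model.seed,
        "sae_hyper": [
            {"rho": s.rho, "c_s": s.c_s, "c_w": s.c_w} for s in model.saes
        ],
    }
    for i, s in enumerate(model.saes):
        arrays[f"sae{i}_W_Y"] = s.W_Y
        arrays[f"sae{i}_B_Y"] = s.B_Y
        arrays[f"sae{i}_W_Z"] = s.W_Z
        arrays[f"sae{i}_B_Z"] = s.B_Z
        arrays[f"sae{i}_code_min"] = model.code_min[i]
        arrays[f"sae{i}_code_range"] = model.code_range[i]
    arrays["softmax_W"] = model.softmax_W
    arrays["softmax_B"] = model.softmax_B
    arrays["scaler_min"] = model.scaler_min
    arrays["scaler_range"] = model.scaler_range
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    with open(path, "wb") as f:  # exact filename, no .npz appended
        np.savez(f, **arrays)


def load_model(path: str | Path) -> DSSAEModel:
    with np.load(path) as blob:
        header = json.loads(bytes(blob["header"]).decode())
        if header.get("schema") != "osteosae-dssae-1":
            raise ValueError(f"unknown model schema in {path}")
        saes = []
        for i in range(header["n_saes"]):
            hyper = header["sae_hyper"][i]
            saes.append(
                SparseAutoencoder(
                    blob[f"sae{i}_W_Y"], blob[f"sae{i}_B_Y"],
                    blob[f"sae{i}_W_Z"], blob[f"sae{i}_B_Z"], **hyper,
                )
            )
        return DSSAEModel(
            saes,
            blob["softmax_W"],
            blob["softmax_B"],
            tuple(header["class_names"]),
            blob["scaler_min"],
            blob["scaler_range"],
            code_min=[blob[f"sae{i}_code_min"] for i in range(header["n_saes"])],
            code_range=[blob[f"sae{i}_code_range"] for i in range(header["n_saes"])],
            seed=header["seed"],
        )
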