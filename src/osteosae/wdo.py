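"""Wind Driven Optimization (WDO) for hyperparameter search.

WDO is a population metaheuristic inspired by atmospheric motion: candidate
solutions are "air parcels" carrying position, velocity and a pressure
(fitness, lower is better).  Each iteration the parcels are ranked; the
velocity update combines gravitation toward the origin, friction, a
pressure-gradient pull toward the best parcel's position scaled by
``|1 - 1/k|`` for rank k, and a Coriolis-like term that mixes in the velocity
of a randomly chosen other dimension:

    u_new = -g * x_old + (1 - alpha) * u_old
            + |1 - 1/k| * RT * (x_max - x_old)
            - c * u_old[d'] / k

Positions advance by one unit time step and are clipped to the normalized
box [-1, 1]^D, zeroing the violating velocity component.  A ``SearchSpace``
maps the box to native hyperparameter units (log/linear continuous scales or
integer grids).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AirParcel",
    "WDOConfig",
    "Dimension",
    "SearchSpace",
    "fitness",
    "rank_parcels",
    "update_velocity",
    "update_position",
    "optimize",
    "tune_dssae",
    "default_search_space",
]

logger = logging.getLogger(__name__)

FULL_BATCH = 10**9  # sentinel batch size meaning "use the whole training set"


@dataclass
class AirParcel:
    """One WDO candidate: position/velocity in [-1,1]^D, pressure, rank."""

    x: np.ndarray
    u: np.ndarray
    pressure: float = math.inf
    k: int = 0  # rank, 1 = best; 0 = unranked
    index: int = 0


@dataclass
class WDOConfig:
    population_size: int = 20
    alpha: float = 0.4       # friction coefficient
    g: float = 0.2           # gravitation
    RT: float = 3.0          # pressure-gradient constant
    c: float = 0.4           # Coriolis constant
    max_velocity: float = 0.3
    iterations: int = 50
    boundary: str = "clip"   # or "reflect"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        # RT = 0 disables the pressure-gradient pull (used for ablations)
        if self.g < 0 or self.c < 0 or self.RT < 0 or self.max_velocity <= 0:
            raise ValueError("g, c, RT >= 0; max_velocity > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.boundary not in ("clip", "reflect"):
            raise ValueError("boundary must be 'clip' or 'reflect'")


def fitness(model_predictions: Sequence, labels: Sequence) -> float:
    """Classification error rate: 100 * misclassified / total."""
    if len(model_predictions) == 0:
        raise ValueError("empty prediction sequence")
    if len(model_predictions) != len(labels):
        raise ValueError("prediction/label length mismatch")
    wrong = sum(1 for p, t in zip(model_predictions, labels) if p != t)
    return 100.0 * wrong / len(labels)


def rank_parcels(population: list[AirParcel]) -> list[AirParcel]:
    """Assign ranks 1..N by ascending pressure; ties break by parcel index.

    Non-finite pressures sort worst (with a logged warning).  Returns the
    population in its original order with ``k`` set.
    """
    for p in population:
        if not math.isfinite(p.pressure):
            logger.warning("parcel %d has non-finite pressure; ranked worst", p.index)
    order = sorted(
        population,
        key=lambda p: (not math.isfinite(p.pressure), p.pressure, p.index),
    )
    for rank, parcel in enumerate(order, start=1):
        parcel.k = rank
    return population


def update_velocity(
    parcel: AirParcel, x_max: np.ndarray, config: WDOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Rank-scaled velocity update, clamped elementwise to +/- max_velocity."""
    if parcel.k < 1:
        raise RuntimeError("parcel must be ranked before the velocity update")
    D = parcel.x.size
    # Coriolis surrogate: for each dimension, the current velocity of one
    # uniformly chosen *other* dimension (the same dimension when D == 1).
    if D == 1:
        u_other = parcel.u.copy()
    else:
        shifts = rng.integers(1, D, size=D)
        u_other = parcel.u[(np.arange(D) + shifts) % D]
    k = parcel.k
    u_new = (
        -config.g * parcel.x
        + (1.0 - config.alpha) * parcel.u
        + abs(1.0 - 1.0 / k) * config.RT * (x_max - parcel.x)
        - config.c * u_other / k
    )
    return np.clip(u_new, -config.max_velocity, config.max_velocity)


def update_position(parcel: AirParcel, config: WDOConfig) -> tuple[np.ndarray, np.ndarray]:
    """Advance by one unit time step, then apply the boundary rule.

    ``clip``: clamp to [-1, 1] and zero the violating velocity component.
    ``reflect``: mirror inside the box and flip the component's sign.
    Returns (x_new, u_new).
    """
    x = parcel.x + parcel.u
    u = parcel.u.copy()
    lo, hi = -1.0, 1.0
    if config.boundary == "clip":
        viol = (x < lo) | (x > hi)
        x = np.clip(x, lo, hi)
        u[viol] = 0.0
    else:
        for _ in range(2):  # at most two reflections given the velocity clamp
            over, under = x > hi, x < lo
            x[over] = 2 * hi - x[over]
            x[under] = 2 * lo - x[under]
            u[over | under] *= -1.0
        x = np.clip(x, lo, hi)
    return x, u


@dataclass
class Dimension:
    """One search dimension with a decode map from [-1, 1] to native units."""

    name: str
    kind: str  # 'linear', 'log', or 'grid'
    lower: float = 0.0
    upper: float = 1.0
    grid: tuple | None = None  # native values for kind='grid'

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "log", "grid"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "grid":
            if not self.grid:
                raise ValueError("grid dimension needs values")
        else:
            if not (math.isfinite(self.lower) and math.isfinite(self.upper) and self.lower < self.upper):
                raise ValueError("bounds must be finite with lower < upper")
            if self.kind == "log" and self.lower <= 0:
                raise ValueError("log dimension needs positive bounds")

    def decode(self, t: float):
        """Map a coordinate in [-1, 1] to native units."""
        s = (float(t) + 1.0) / 2.0
        if self.kind == "linear":
            return self.lower + s * (self.upper - self.lower)
        if self.kind == "log":
            return math.exp(math.log(self.lower) + s * (math.log(self.upper) - math.log(self.lower)))
        n = len(self.grid)
        return self.grid[min(n - 1, int(s * n))]

    def encode(self, v) -> float:
        """Inverse of decode; exact for grid values (cell centre)."""
        if self.kind == "linear":
            s = (float(v) - self.lower) / (self.upper - self.lower)
        elif self.kind == "log":
            s = (math.log(float(v)) - math.log(self.lower)) / (math.log(self.upper) - math.log(self.lower))
        else:
            i = self.grid.index(v)
            s = (i + 0.5) / len(self.grid)
        return 2.0 * s - 1.0


@dataclass
class SearchSpace:
    dimensions: list[Dimension]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def decode(self, x: np.ndarray) -> dict:
        return {d.name: d.decode(t) for d, t in zip(self.dimensions, x)}

    def encode(self, values: dict) -> np.ndarray:
        return np.array([d.encode(values[d.name]) for d in self.dimensions])


def default_search_space() -> SearchSpace:
    """Epochs (log-spaced integer grid 20..200), batch size, learning rate."""
    epochs = tuple(sorted({int(round(v)) for v in np.geomspace(20, 200, 10)}))
    return SearchSpace(
        [
            Dimension("epochs", "grid", grid=epochs),
            Dimension("batch_size", "grid", grid=(8, 16, 32, 64, FULL_BATCH)),
            Dimension("learning_rate", "log", lower=1e-4, upper=1e-1),
        ]
    )


@dataclass
class OptimizeResult:
    best_x: np.ndarray
    best_fitness: float
    best_decoded: dict
    history: pd.DataFrame
    n_evaluations: int


def optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    config: WDOConfig | None = None,
) -> OptimizeResult:
    """Run the WDO loop over the search space.

    ``objective`` receives decoded native-unit parameters and returns a
    fitness to minimise (an error percentage in the tuning use).  Evaluation
    errors are logged and scored as the worst fitness (100).  The best-so-far
    fitness is non-increasing by construction; the history holds one row per
    iteration (best/mean fitness and the decoded best position).
    """
    config = config or WDOConfig()
    rng = np.random.default_rng(config.seed)
    D = space.ndim
    parcels = [
        AirParcel(
            x=rng.uniform(-1.0, 1.0, size=D),
            u=rng.uniform(-config.max_velocity, config.max_velocity, size=D),
            index=i,
        )
        for i in range(config.population_size)
    ]
    best_x, best_fit = None, math.inf
    rows = []
    n_eval = 0

    def evaluate(p: AirParcel) -> None:
        nonlocal n_eval
        n_eval += 1
        try:
            p.pressure = float(objective(space.decode(p.x)))
        except Exception as exc:  # noqa: BLE001 — parcel failure must not kill the search
            logger.warning("objective failed at %s: %s", space.decode(p.x), exc)
            p.pressure = 100.0

    for it in range(1, config.iterations + 1):
        for p in parcels:
            evaluate(p)
        rank_parcels(parcels)
        leader = min(parcels, key=lambda p: p.k)
        if leader.pressure < best_fit:
            best_fit = leader.pressure
            best_x = leader.x.copy()
        x_max = leader.x.copy()  # pull toward the current rank-1 parcel
        rows.append(
            {
                "iteration": it,
                "best_fitness": best_fit,
                "mean_fitness": float(np.mean([p.pressure for p in parcels])),
                **{f"best_{k}": v for k, v in space.decode(best_x).items()},
            }
        )
        if it == config.iterations:
            break
        for p in parcels:
            p.u = update_velocity(p, x_max, config, rng)
            p.x, p.u = update_position(p, config)
    history = pd.DataFrame(rows)
    return OptimizeResult(
        best_x=best_x,
        best_fitness=best_fit,
        best_decoded=space.decode(best_x),
        history=history,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# DSSAE hyperparameter tuning


def tune_dssae(
    features: np.ndarray,
    labels: Sequence,
    space: SearchSpace | None = None,
    config: WDOConfig | None = None,
    hidden_dims: Sequence[int] = (256, 128, 64, 32),
    base_train: "TrainConfig | None" = None,
    val_fraction: float = 0.25,
):
    """WDO-tune the DSSAE training hyperparameters, then retrain on all data.

    The objective trains a DSSAE with the decoded hyperparameters on a
    stratified 75/25 sub-split of the supplied training data and scores the
    classification error rate on the held-out quarter.  The mandatory search
    dimensions are ``epochs``, ``batch_size`` and ``learning_rate``; extra
    dimensions matching :class:`osteosae.dssae.TrainConfig` fields (e.g.
    ``c_s``, ``rho``) are passed through.  Returns
    (best_hyperparameters, model retrained on the full data, OptimizeResult).
    """
    from .dssae import TrainConfig, predict, train_dssae
    from .synthetic import stratified_split

    space = space or default_search_space()
    missing = {"epochs", "batch_size", "learning_rate"} - set(space.names)
    if missing:
        raise ValueError(f"search space missing mandatory dimensions: {sorted(missing)}")
    config = config or WDOConfig()
    base_train = base_train or TrainConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = list(labels)
    tr_idx, val_idx = stratified_split(y, 1.0 - val_fraction, seed=config.seed)

    def make_config(params: dict) -> TrainConfig:
        fields = {k: v for k, v in params.items() if hasattr(base_train, k)}
        if "epochs" in fields:
            fields["epochs"] = int(fields["epochs"])
        if "batch_size" in fields:
            fields["batch_size"] = int(fields["batch_size"])
        return replace(base_train, **fields)

    def objective(params: dict) -> float:
        cfg = make_config(params)
        model = train_dssae(X[tr_idx], [y[i] for i in tr_idx], hidden_dims, cfg)
        preds, _ = predict(model, X[val_idx])
        return fitness(preds, [y[i] for i in val_idx])

    result = optimize(objective, space, config)
    best_cfg = make_config(result.best_decoded)
    model = train_dssae(X, y, hidden_dims, best_cfg)
    return result.best_decoded, model, result
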