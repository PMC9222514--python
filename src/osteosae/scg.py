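"""Scaled conjugate gradient (SCG) minimiser, Moller's formulation.

A batch second-order-free optimiser: conjugate directions with a
Levenberg-Marquardt style scaling of the local curvature estimate, no line
search.  Used to train each sparse autoencoder layer and the softmax head.

``sigma`` controls the finite-difference step for the curvature estimate and
``lambda0`` the initial scale regulariser; the defaults (1e-5, 1e-7) are the
conventional ones and rarely need changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SCGResult", "scg_minimize"]


@dataclass
class SCGResult:
    x: np.ndarray
    fun: float
    n_iter: int
    trace: list[float] = field(default_factory=list)
    converged: bool = False


def scg_minimize(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    max_iter: int = 200,
    sigma: float = 1e-5,
    lambda0: float = 1e-7,
    grad_tol: float = 1e-8,
) -> SCGResult:
    """Minimise ``fun_grad`` (returning value and gradient) from ``x0``.

    Returns the best point seen; the trace records the objective value after
    every successful step.
    """
    w = np.asarray(x0, dtype=float).copy()
    n = w.size
    f, grad = fun_grad(w)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite objective at the starting point")
    r = -grad
    p = r.copy()
    lam, lam_bar = lambda0, 0.0
    success = True
    trace = [f]
    delta = 0.0
    k = 0
    for k in range(1, max_iter + 1):
        p_norm2 = float(p @ p)
        if p_norm2 <= 0 or np.sqrt(float(r @ r)) < grad_tol:
            break
        if success:
            # Second-order information along p via a finite difference of grads.
            sigma_k = sigma / np.sqrt(p_norm2)
            _, grad_plus = fun_grad(w + sigma_k * p)
            s = (grad_plus - grad) / sigma_k
            delta = float(p @ s)
        # Scale the curvature estimate.
        delta = delta + (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian surrogate positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, grad_new = fun_grad(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite objective during SCG step")
        comp = 2.0 * delta * (f - f_new) / (mu * mu)  # comparison parameter
        if comp >= 0:  # successful step
            w = w + alpha * p
            f = f_new
            r_new = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if k % n == 0:  # restart in the steepest-descent direction
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            trace.append(f)
            if comp >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam = lam + delta * (1.0 - comp) / p_norm2
        if lam > 1e100:  # trust region collapsed; no further progress possible
            break
    return SCGResult(x=w, fun=f, n_iter=k, trace=trace, converged=np.sqrt(float(r @ r)) < grad_tol)
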