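"""Scaled conjugate gradient minimization (Moller, 1993).

A Hessian-free batch optimizer: curvature along the search direction is
estimated by a finite difference of gradients and regularized by a
Levenberg-Marquardt style scale parameter, so no line search is needed.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..errors import TrainingError

__all__ = ["scg_minimize"]


def scg_minimize(
    f_and_g: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    max_iter: int = 500,
    sigma0: float = 1e-4,
    lambda0: float = 1e-6,
    grad_tol: float = 1e-10,
    on_iterate: Callable[[int, np.ndarray, float], bool] | None = None,
) -> tuple[np.ndarray, float, int]:
    """Minimize ``f`` starting from ``w0``.

    ``on_iterate(k, w, f)`` is called after every successful weight update;
    returning True stops the optimization (used for validation-based early
    stopping).  Returns ``(w, f, iterations)``.
    """
    w = np.asarray(w0, dtype=float).copy()
    n = w.size
    f, grad = f_and_g(w)
    if not np.isfinite(f):
        raise TrainingError("non-finite loss at the initial weights; restart with a new seed")
    r = -grad
    p = r.copy()
    lam, lam_bar = lambda0, 0.0
    success = True
    delta = 0.0
    k = 0
    for k in range(1, max_iter + 1):
        p_sq = float(p @ p)
        if p_sq <= grad_tol ** 2:
            break
        p_norm = np.sqrt(p_sq)
        if success:
            sigma = sigma0 / p_norm
            _, grad_s = f_and_g(w + sigma * p)
            s = (grad_s - grad) / sigma
            delta = float(p @ s)
        delta = delta + (lam - lam_bar) * p_sq
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, grad_new = f_and_g(w + alpha * p)
        if not np.isfinite(f_new):
            raise TrainingError("non-finite loss during training; restart with a new seed "
                                "or reduce the model size")
        comparison = 2.0 * delta * (f - f_new) / (mu * mu)
        if comparison >= 0:  # successful reduction
            w = w + alpha * p
            f = f_new
            r_old = r
            r = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if k % n == 0:  # restart the direction periodically
                p = r.copy()
            else:
                beta = (float(r @ r) - float(r @ r_old)) / mu
                p = r + beta * p
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-20)
            if on_iterate is not None and on_iterate(k, w, f):
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_sq
        if lam > 1e20 or float(r @ r) <= grad_tol ** 2:
            break
    return w, f, k
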