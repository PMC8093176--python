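"""Thin wrapper around scipy's quasi-Newton minimizer used by all fits."""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.optimize import minimize

#: Finite stand-in for +inf deviance so finite differences stay usable.
BIG = 1e12


def finite(fun: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    def wrapped(x: np.ndarray) -> float:
        v = fun(x)
        return BIG if not math.isfinite(v) else v
    return wrapped


def numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray,
                    eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; used only to scale profile searches."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = eps * (np.abs(x) + 1.0)
    hess = np.empty((n, n))
    f0 = fun(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    return hess


def numeric_gradient(fun: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = eps * (np.abs(x) + 1.0)
    grad = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h[i]
        grad[i] = (fun(x + e) - fun(x - e)) / (2.0 * h[i])
    return grad


def minimize_deviance(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_starts: int = 1,
    jitter: float = 0.1,
    seed: int = 1234,
    tol: float = 1e-8,
    maxiter: int = 3000,
    fun_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None,
) -> tuple[np.ndarray, float, bool, dict]:
    """Minimize with optional jittered restarts; returns the best optimum.

    Restarts after the first are warm-started from the incumbent optimum with
    multiplicative-plus-additive jitter (fixed seed for reproducibility).
    When ``fun_and_grad`` is given its analytic gradient is used, otherwise
    finite differences.
    """
    f = finite(fun)
    # ftol is relative to |f|; deviances are O(1e4-1e5), so 1e-13 terminates
    # on absolute changes well below the 1e-8 contract
    options = {"maxiter": maxiter, "maxfun": 10 * maxiter,
               "ftol": min(tol * 1e-5, 1e-13), "gtol": 1e-8}
    if fun_and_grad is not None:
        def f_jac(x):
            v, g = fun_and_grad(x)
            if not math.isfinite(v):
                return BIG, g
            return v, g
    else:
        options["eps"] = 1e-7
    rng = np.random.default_rng(seed)
    best_x, best_val, best_ok, nit = None, math.inf, False, 0
    start = np.asarray(x0, dtype=float)
    for k in range(max(1, n_starts)):
        if k > 0:
            base = best_x if best_x is not None else start
            scale = jitter * (np.abs(base) + 0.1)
            start = base + rng.normal(size=base.shape) * scale
        if fun_and_grad is not None:
            res = minimize(f_jac, start, method="L-BFGS-B", jac=True,
                           options=options)
        else:
            res = minimize(f, start, method="L-BFGS-B", options=options)
        nit += int(res.nit)
        if res.fun < best_val:
            best_x, best_val, best_ok = np.asarray(res.x), float(res.fun), bool(res.success)
    diagnostics = {"n_iter": nit, "n_starts": max(1, n_starts)}
    converged = best_ok and best_val < BIG
    return best_x, best_val, converged, diagnostics
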