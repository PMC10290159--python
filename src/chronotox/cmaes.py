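"""Covariance-matrix-adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES minimizer with box constraints via
coordinate-wise reflection, used by the fitting routines. The strategy
follows the standard rank-mu update with cumulative step-size adaptation;
weights, learning rates and damping use the canonical defaults for the
problem dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAESResult", "cma_es_minimize"]


@dataclass
class CMAESResult:
    """Outcome of a CMA-ES run."""

    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)  # best f per generation


def _reflect_into_box(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [lo, hi]; handles excursions of any size."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def cma_es_minimize(
    fun,
    x0,
    sigma0: float,
    bounds=None,
    max_evals: int = 5000,
    popsize: int | None = None,
    seed: int | None = None,
    ftol: float = 1e-12,
    trace_every: int = 1,
) -> CMAESResult:
    """Minimize ``fun`` starting from ``x0`` with initial step size ``sigma0``.

    Parameters
    ----------
    fun : callable
        Objective ``f(x) -> float``; must accept a 1-D ndarray.
    x0 : array-like
        Initial mean of the search distribution.
    sigma0 : float
        Initial global step size, in the units of ``x0``.
    bounds : (lo, hi) pair of array-likes, optional
        Box constraints enforced by reflection before evaluation.
    max_evals : int
        Evaluation budget. ``max_evals == 0`` returns ``x0`` and its cost.
    popsize : int, optional
        Offspring per generation; default ``4 + floor(3 ln n)``.
    seed : int, optional
        Seed for the sampling RNG; fixed seed gives a reproducible run.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if lo.shape != x0.shape or hi.shape != x0.shape:
            raise ValueError("bounds must match x0 in shape")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        x0 = np.clip(x0, lo, hi)
    else:
        lo = hi = None

    if max_evals == 0:
        return CMAESResult(x=x0.copy(), fun=float(fun(x0)), n_evals=1,
                           n_iter=0, converged=False, trace=[])

    rng = np.random.default_rng(seed)
    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    lam = max(lam, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    # canonical learning rates
    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = x0.copy()
    sigma = float(sigma0)
    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    invsqrtC = np.eye(n)
    eigen_stale = 0

    best_x = mean.copy()
    best_f = np.inf
    n_evals = 0
    it = 0
    trace: list = []
    converged = False

    while n_evals < max_evals:
        it += 1
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T  # y_k = B D z_k
        xs = mean + sigma * y
        if lo is not None:
            xs_eval = np.array([_reflect_into_box(x, lo, hi) for x in xs])
        else:
            xs_eval = xs
        fs = np.array([fun(x) for x in xs_eval])
        n_evals += lam
        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs_eval[order[0]].copy()
        if it % trace_every == 0:
            trace.append(best_f)

        # use the *evaluated* (reflected) points so the distribution tracks
        # the feasible region
        y_sel = (xs_eval[order[:mu]] - mean) / sigma
        y_w = w @ y_sel

        mean = mean + sigma * y_w
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (invsqrtC @ y_w)
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * n_evals / lam)) / chi_n
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
             + cmu * (y_sel.T * w) @ y_sel)
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1e8)

        eigen_stale += lam
        if eigen_stale > lam / ((c1 + cmu) * n * 10):
            eigen_stale = 0
            C = np.triu(C) + np.triu(C, 1).T
            eigval, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(eigval, 1e-20))
            invsqrtC = B @ np.diag(1.0 / D) @ B.T

        f_spread = float(fs[order[-1]] - fs[order[0]])
        if f_spread < ftol and it > 10:
            converged = True
            break
        if sigma * D.max() < 1e-14:
            converged = True
            break

    return CMAESResult(x=best_x, fun=best_f, n_evals=n_evals, n_iter=it,
                       converged=converged, trace=trace)
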