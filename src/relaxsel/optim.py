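"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES minimizer following the standard
recursions: weighted recombination of the best mu of lambda sampled
offspring, cumulation paths for the step size (CSA) and the rank-one
covariance update, and a rank-mu update.  Derivative-free, so it handles
the non-smooth mean-absolute-error objectives used for trajectory fitting.

Deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAESResult", "cmaes_minimize"]


@dataclass
class CMAESResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    history: list = field(default_factory=list, repr=False)


def cmaes_minimize(
    objective,
    x0,
    sigma0: float = 0.3,
    *,
    seed: int = 0,
    max_evals: int = 5000,
    tol_fun: float = 1e-10,
    tol_x: float = 1e-12,
    popsize: int | None = None,
):
    """Minimize ``objective(x)`` over R^d by CMA-ES.

    Parameters
    ----------
    objective : callable
        Maps a 1-D parameter vector to a scalar.  Non-finite values are
        treated as very bad candidates rather than errors.
    x0 : array_like
        Initial mean of the search distribution.
    sigma0 : float
        Initial global step size, in the coordinates of ``x0``.
    seed : int
        Seed for the sampling RNG.
    max_evals : int
        Evaluation budget.
    tol_fun : float
        Stop when the function-value spread within the current population
        and across the recent history falls below this.
    tol_x : float
        Stop when ``sigma * sqrt(max eigenvalue of C)`` is below this.
    popsize : int, optional
        Offspring per generation; defaults to ``4 + floor(3*ln(d))``.

    Returns
    -------
    CMAESResult
        Best-ever point, its objective value, and bookkeeping.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(x0, dtype=float).copy()
    d = mean.size
    sigma = float(sigma0)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    # strategy parameters (Hansen's defaults)
    cc = (4 + mu_eff / d) / (d + 4 + 2 * mu_eff / d)
    cs = (mu_eff + 2) / (d + mu_eff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((d + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (d + 1)) - 1) + cs
    chi_d = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

    pc = np.zeros(d)
    ps = np.zeros(d)
    C = np.eye(d)
    B = np.eye(d)
    D = np.ones(d)
    inv_sqrt_C = np.eye(d)
    eigen_stale = 0

    best_x = mean.copy()
    best_f = float(objective(mean))
    n_evals = 1
    recent_best: list[float] = []
    n_iter = 0
    converged = False

    while n_evals + lam <= max_evals:
        n_iter += 1
        z = rng.standard_normal((lam, d))
        y = z * D @ B.T  # y_i = B D z_i
        xs = mean + sigma * y
        fs = np.empty(lam)
        for i in range(lam):
            fi = objective(xs[i])
            fs[i] = fi if np.isfinite(fi) else 1e300
        n_evals += lam

        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (inv_sqrt_C @ y_w)
        h_sig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (n_iter + 1)))
            < (1.4 + 2 / (d + 1)) * chi_d
        )
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w

        delta_h = (1 - h_sig) * cc * (2 - cc)
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + delta_h * C)
            + cmu * (y_sel.T * w) @ y_sel
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))

        eigen_stale += lam
        if eigen_stale > lam / (10 * d * (c1 + cmu) + 1e-12) or eigen_stale >= 5 * lam:
            eigen_stale = 0
            C = (C + C.T) / 2
            eigvals, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(eigvals, 1e-30))
            inv_sqrt_C = (B / D) @ B.T

        recent_best.append(float(fs[order[0]]))
        hist_span = 10 + int(np.ceil(30 * d / lam))
        if len(recent_best) > hist_span:
            recent_best.pop(0)
        f_spread = fs[order[-1]] - fs[order[0]]
        hist_spread = max(recent_best) - min(recent_best)
        if len(recent_best) >= hist_span and max(f_spread, hist_spread) < tol_fun:
            converged = True
            break
        if sigma * D.max() < tol_x:
            converged = True
            break
        if sigma * D.max() > 1e8:  # divergence guard
            break

    return CMAESResult(
        x=best_x, fun=best_f, n_evals=n_evals, n_iter=n_iter, converged=converged
    )
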