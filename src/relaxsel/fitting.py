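"""CMA-ES fitting of the trajectory curves by weighted mean absolute error.

Both curve families are fitted by minimising the weighted MAE

    sum_i w_i |y_i - f(x_i)| / sum_i w_i

with box constraints handled by smooth reparameterisations (logistic for
the decay factor ``a`` in (0,1); log for the positive Weibull shape and
scale), so the CMA-ES covariance adaptation operates on an unconstrained
space.  Fits are best-of-``n_restarts`` and reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .curves import InverseParams, WeibullParams, inverse_curve, weibull_curve
from .optim import cmaes_minimize

__all__ = [
    "FitResult",
    "InverseCurveFitter",
    "WeibullCurveFitter",
    "fit_inverse_cmaes",
    "fit_weibull_cmaes",
]


@dataclass
class FitResult:
    """Outcome of one best-of-restarts CMA-ES curve fit."""

    params: InverseParams | WeibullParams
    mae: float
    n_restarts: int
    converged: bool
    seed: int

    def to_json(self) -> str:
        d = {
            "curve": "inverse" if isinstance(self.params, InverseParams) else "weibull",
            "params": asdict(self.params),
            "mae": self.mae,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


def _weighted_mae(resid: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * np.abs(resid)) / np.sum(w))


def _check_xyw(x, y, w, min_records: int, min_distinct: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float).ravel()
    if not (x.size == y.size == w.size):
        raise ValueError("x, y and weights must have equal lengths")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if x.size < min_records:
        raise ValueError(f"need at least {min_records} records; got {x.size}")
    if np.unique(x).size < min_distinct:
        raise ValueError(
            f"need at least {min_distinct} distinct x values; curve is unidentifiable"
        )
    return x, y, w


class _CurveFitterBase:
    """Shared sklearn-style plumbing for the two curve fitters."""

    _param_names: tuple[str, ...] = ()

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _restart_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s) for s in ss.generate_state(self.n_restarts) >> 1]

    def predict(self, x):
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        return self._curve(x, self.params_)

    def score(self, x, y, w=None):
        """Negative weighted MAE (higher is better, sklearn convention)."""
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        w = np.ones_like(x) if w is None else np.asarray(w, float).ravel()
        return -_weighted_mae(y - self.predict(x), w)

    @property
    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_,
            mae=self.mae_,
            n_restarts=self.n_restarts,
            converged=self.converged_,
            seed=self.seed,
        )


class InverseCurveFitter(_CurveFitterBase):
    """Fit the geometric-decay mean trajectory ``y_ini + k*a**x``.

    Parameters
    ----------
    seed : int
        Master seed; each restart draws its own child seed from it.
    n_restarts : int
        Independent CMA-ES runs; the lowest-MAE result wins.  Default 5.
    max_evals : int
        Objective-evaluation budget per restart.
    sigma0 : float
        Initial CMA-ES step size in the transformed coordinates.

    Attributes
    ----------
    params_ : InverseParams
    mae_ : float
        Weighted MAE of the returned parameters.
    converged_ : bool
    """

    _param_names = ("seed", "n_restarts", "max_evals", "sigma0")

    def __init__(self, seed: int = 0, n_restarts: int = 5,
                 max_evals: int = 5000, sigma0: float = 0.3):
        self.seed = seed
        self.n_restarts = n_restarts
        self.max_evals = max_evals
        self.sigma0 = sigma0

    @staticmethod
    def _curve(x, p):
        return inverse_curve(x, p)

    @staticmethod
    def _decode(theta) -> InverseParams:
        y_ini, k, za = theta
        a = 1.0 / (1.0 + np.exp(-za))  # logistic keeps a in (0,1)
        a = min(max(a, 1e-12), 1 - 1e-12)
        return InverseParams(float(y_ini), float(k), float(a))

    def fit(self, x, y, w=None):
        x, y, w = _check_xyw(x, y, w, min_records=4, min_distinct=2)

        def objective(theta):
            p = self._decode(theta)
            return _weighted_mae(y - inverse_curve(x, p), w)

        # data-driven start: early mean vs late mean bracket the decay
        lo, hi = np.argmin(x), np.argmax(x)
        y0_guess = float(y[lo])
        yinf_guess = float(y[hi])
        theta0 = np.array([yinf_guess, y0_guess - yinf_guess, 0.0])

        best = None
        for r, rseed in enumerate(self._restart_seeds()):
            start = theta0 if r == 0 else theta0 + np.random.default_rng(rseed).normal(0, 1.0, 3)
            res = cmaes_minimize(objective, start, self.sigma0, seed=rseed,
                                 max_evals=self.max_evals)
            if best is None or res.fun < best.fun:
                best = res
        self.params_ = self._decode(best.x)
        self.mae_ = float(best.fun)
        self.converged_ = bool(best.converged)
        return self


class WeibullCurveFitter(_CurveFitterBase):
    """Fit the baseline-plus-bump CV trajectory.

    Five parameters: baseline ``y_ini``, bump scale ``a``, shape ``k > 0``,
    scale ``lam > 0`` and onset ``t_min >= 0``.  Positivity is enforced by
    log-transforms, the onset by a softplus-style exp transform.

    Attributes mirror :class:`InverseCurveFitter`.
    """

    _param_names = ("seed", "n_restarts", "max_evals", "sigma0", "fix_t_min")

    def __init__(self, seed: int = 0, n_restarts: int = 5,
                 max_evals: int = 8000, sigma0: float = 0.3,
                 fix_t_min: float | None = None):
        self.seed = seed
        self.n_restarts = n_restarts
        self.max_evals = max_evals
        self.sigma0 = sigma0
        self.fix_t_min = fix_t_min

    @staticmethod
    def _curve(x, p):
        return weibull_curve(x, p)

    def _decode(self, theta) -> WeibullParams:
        y_ini, a, lk, llam, lt = theta
        t_min = self.fix_t_min if self.fix_t_min is not None else float(np.exp(lt) - 1.0)
        t_min = max(t_min, 0.0)
        return WeibullParams(
            y_ini=float(y_ini),
            a=float(a),
            k=float(np.exp(np.clip(lk, -20, 20))),
            lam=float(np.exp(np.clip(llam, -20, 20))),
            t_min=t_min,
        )

    def fit(self, x, y, w=None):
        x, y, w = _check_xyw(x, y, w, min_records=6, min_distinct=3)

        def objective(theta):
            p = self._decode(theta)
            return _weighted_mae(y - weibull_curve(x, p), w)

        y_base = float(np.median(y))
        bump = float(np.max(y) - y_base)
        x_peak = float(x[np.argmax(y)])
        lam0 = max(x_peak, np.ptp(x) / 4.0, 1.0)
        # a*(k/lam)*u^{k-1}e^{-u^k} peaks near a/(lam*e^{1/2}) for k=2
        a0 = max(bump, 1e-3) * lam0 * np.exp(0.5) / 2.0
        theta0 = np.array([y_base, a0, np.log(2.0), np.log(lam0), np.log(1.0)])

        best = None
        for r, rseed in enumerate(self._restart_seeds()):
            if r == 0:
                start = theta0
            else:
                jitter = np.random.default_rng(rseed).normal(0, 0.8, 5)
                start = theta0 + jitter * np.array([abs(y_base) + 0.1, a0 * 0.5 + 0.1, 1, 1, 1])
            res = cmaes_minimize(objective, start, self.sigma0, seed=rseed,
                                 max_evals=self.max_evals)
            if best is None or res.fun < best.fun:
                best = res
        self.params_ = self._decode(best.x)
        self.mae_ = float(best.fun)
        self.converged_ = bool(best.converged)
        return self


def fit_inverse_cmaes(x, y, w=None, seed: int = 0, n_restarts: int = 5) -> FitResult:
    """Functional wrapper: fit the inverse-decay curve, return a FitResult."""
    return InverseCurveFitter(seed=seed, n_restarts=n_restarts).fit(x, y, w).result_


def fit_weibull_cmaes(x, y, w=None, seed: int = 0, n_restarts: int = 5,
                      fix_t_min: float | None = None) -> FitResult:
    """Functional wrapper: fit the Weibull CV curve, return a FitResult."""
    return (
        WeibullCurveFitter(seed=seed, n_restarts=n_restarts, fix_t_min=fix_t_min)
        .fit(x, y, w)
        .result_
    )
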