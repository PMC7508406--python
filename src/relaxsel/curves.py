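"""Parametric trajectory curves for antipredator traits across generations.

Two curve families describe how traits respond to generations of human
contact under relaxed predation pressure:

* an *inverse-decay* curve ``f(x) = y_ini + k * a**x`` for the trait mean,
  which decays geometrically from ``y_ini + k`` at generation 0 toward the
  asymptote ``y_ini``;
* a *Weibull bump* curve for the coefficient of variation (CV), a baseline
  ``y_ini`` plus a scaled Weibull probability-density term that rises after
  an onset generation ``t_min`` and then declines — the signature of a
  transient inflation of between-individual variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "InverseParams",
    "WeibullParams",
    "inverse_curve",
    "weibull_curve",
    "curve_derivative",
    "generations_to_asymptote",
]


@dataclass(frozen=True)
class InverseParams:
    """Parameters of the geometric-decay mean trajectory.

    Attributes
    ----------
    y_ini : float
        Asymptotic trait value (z-score units).
    k : float
        Scaling coefficient; the trait starts at ``y_ini + k``.
    a : float
        Per-generation decay factor, strictly inside (0, 1).
    """

    y_ini: float
    k: float
    a: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"decay factor a must lie in (0, 1); got {self.a}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the baseline-plus-bump CV trajectory.

    Attributes
    ----------
    y_ini : float
        Baseline CV before the onset of change.
    a : float
        Scaling coefficient of the bump.
    k : float
        Shape exponent (> 0).
    lam : float
        Scale coefficient (> 0), controls where the bump peaks.
    t_min : float
        Generation at which the change starts (>= 0).
    """

    y_ini: float
    a: float
    k: float
    lam: float
    t_min: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"shape exponent k must be positive; got {self.k}")
        if self.lam <= 0:
            raise ValueError(f"scale lambda must be positive; got {self.lam}")
        if self.t_min < 0:
            raise ValueError(f"onset t_min must be non-negative; got {self.t_min}")

    def to_dict(self) -> dict:
        return asdict(self)


def inverse_curve(x, p: InverseParams):
    """Evaluate the inverse-decay curve ``y_ini + k * a**x``.

    Parameters
    ----------
    x : array_like
        Generation count(s), >= 0.
    p : InverseParams

    Returns
    -------
    ndarray or float
        Trait value(s) at ``x``.
    """
    x = np.asarray(x, dtype=float)
    out = p.y_ini + p.k * np.power(p.a, x)
    return out if out.ndim else float(out)


def weibull_bump(x, p: WeibullParams):
    """The bump term alone: ``a*(k/lam)*u**(k-1)*exp(-u**k)``, u=(x-t_min)/lam.

    Zero before the onset ``t_min``.  With ``a = 1`` this is a Weibull
    probability density in ``x - t_min`` and integrates to 1.
    """
    x = np.asarray(x, dtype=float)
    u = (x - p.t_min) / p.lam
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (p.k / p.lam) * np.power(u, p.k - 1.0) * np.exp(-np.power(u, p.k))
    # pre-onset (u <= 0) the bump has not started; u == 0 with k < 1 diverges,
    # with k == 1 the density is (1/lam) at the onset
    if p.k > 1.0:
        val = np.where(u <= 0.0, 0.0, val)
    elif p.k == 1.0:
        val = np.where(u < 0.0, 0.0, np.where(u == 0.0, 1.0 / p.lam, val))
    else:
        val = np.where(u <= 0.0, 0.0, val)  # left limit diverges; pre-onset is baseline
    out = p.a * val
    return out if out.ndim else float(out)


def weibull_curve(x, p: WeibullParams):
    """Evaluate the CV trajectory ``y_ini + bump(x)``.

    Before the onset generation ``t_min`` the curve equals the baseline
    ``y_ini``; afterwards the scaled Weibull-density bump rises and decays.
    """
    out = p.y_ini + np.asarray(weibull_bump(x, p))
    return out if out.ndim else float(out)


def curve_derivative(p: InverseParams, x):
    """Rate of change of the inverse curve, per generation.

    The closed form is ``k * ln(a) * a**x``; negative for ``k > 0`` since
    ``0 < a < 1``.
    """
    x = np.asarray(x, dtype=float)
    out = p.k * math.log(p.a) * np.power(p.a, x)
    return out if out.ndim else float(out)


def generations_to_asymptote(p: InverseParams, fraction: float = 0.05) -> float:
    """Generations until the trait is within ``fraction*|k|`` of its asymptote.

    Solves ``|f(x) - y_ini| = fraction * |k|`` in closed form:
    ``x = ln(fraction) / ln(a)``.

    Parameters
    ----------
    p : InverseParams
    fraction : float
        Remaining fraction of the initial offset, in (0, 1).  The default
        0.05 reads "asymptote reached" as 95% of the change completed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1); got {fraction}")
    if p.k == 0:
        raise ValueError("k must be nonzero for an asymptote time to be defined")
    return math.log(fraction) / math.log(p.a)
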