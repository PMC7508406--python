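"""Loess: locally estimated scatterplot smoothing.

Local weighted polynomial regression with the tricube kernel over
span-nearest neighbours, degrees 0, 1 or 2.  Used as the assumption-free
first look at trait trajectories before a parametric curve is committed to.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LoessSmoother", "fit_loess", "select_smoothing"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


class LoessSmoother:
    """Tricube local-polynomial smoother (scikit-learn estimator style).

    Parameters
    ----------
    span : float
        Fraction of the data used in each local fit, in (0, 1].
        Default 0.75 matches the de facto standard implementation.
    degree : int
        Local polynomial degree, one of {0, 1, 2}.  Default 2.

    Attributes
    ----------
    x_ : ndarray
        Training abscissae, sorted.
    y_ : ndarray
        Training ordinates, in the order of ``x_``.
    """

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"span": self.span, "degree": self.degree}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("span", "degree"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def _validate(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if self.degree not in (0, 1, 2):
            raise ValueError(f"degree must be 0, 1 or 2; got {self.degree}")
        if not 0.0 < self.span <= 1.0:
            raise ValueError(f"span must lie in (0, 1]; got {self.span}")
        n_distinct = np.unique(x).size
        if n_distinct < self.degree + 2:
            raise ValueError(
                f"need at least degree+2={self.degree + 2} distinct x values; "
                f"got {n_distinct}"
            )
        return x, y

    def fit(self, x, y):
        x, y = self._validate(x, y)
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        self.y_ = y[order]
        n = x.size
        # effective neighbourhood must support the local polynomial
        self.k_ = max(int(np.ceil(self.span * n)), self.degree + 1)
        return self

    def predict(self, x_new):
        if not hasattr(self, "x_"):
            raise RuntimeError("LoessSmoother is not fitted")
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        out = np.empty(x_new.size)
        for i, x0 in enumerate(x_new):
            out[i] = self._fit_at(x0)
        return out

    def fit_predict(self, x, y):
        return self.fit(x, y).predict(x)

    def _fit_at(self, x0: float) -> float:
        d = np.abs(self.x_ - x0)
        idx = np.argsort(d, kind="stable")[: self.k_]
        h = d[idx].max()
        if h == 0.0:  # all selected points coincide with x0
            return float(np.mean(self.y_[idx]))
        w = _tricube(d[idx] / h)
        if w.sum() == 0.0:
            w = np.ones_like(w)
        xs, ys = self.x_[idx], self.y_[idx]
        # weighted least squares on the local design, centred for conditioning
        t = xs - x0
        X = np.vander(t, N=self.degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
        return float(beta[0])


def fit_loess(x, y, span: float = 0.75, degree: int = 2, x_query=None) -> np.ndarray:
    """Fit a loess smoother and return fitted values.

    Evaluates at ``x_query`` if given, otherwise at the training ``x``.
    """
    sm = LoessSmoother(span=span, degree=degree).fit(x, y)
    return sm.predict(x if x_query is None else x_query)


def select_smoothing(x, y, candidate_spans, degree: int = 2) -> float:
    """Pick the span minimising in-sample MAE of the loess fit.

    Candidate spans are deduplicated; ties break toward the smallest span.
    """
    spans = sorted(set(float(s) for s in candidate_spans))
    if len(spans) < 1:
        raise ValueError("need at least one candidate span")
    y = np.asarray(y, dtype=float).ravel()
    best_span, best_mae = None, np.inf
    for s in spans:
        fitted = fit_loess(x, y, span=s, degree=degree)
        mae = float(np.mean(np.abs(y - fitted)))
        if mae < best_mae - 1e-15:
            best_span, best_mae = s, mae
    return best_span
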