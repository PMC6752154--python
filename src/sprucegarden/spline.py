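"""Weighted cubic smoothing spline with a dimensionless stiffness parameter.

The fitted curve minimizes

    sum_i w_i (y_i - f(x_i))^2  +  lambda * int f''(u)^2 du

over natural cubic splines, where the penalty weight ``lambda`` is derived
from a stiffness ``spar`` in (0, 1] by the mapping

    lambda = r * 256**(3*spar - 1),     r = tr(X' W X) / tr(Omega),

with X the cubic B-spline design matrix at the distinct predictor values
(rescaled to [0, 1]) and Omega the Gram matrix of basis second derivatives.
This is the convention used by R's ``smooth.spline`` with knots at every
distinct x, so a stiffness of 0.7 here means the same curve a dendro
analyst gets from ``smooth.spline(..., spar = 0.7)``.

The solve itself uses the Reinsch formulation: with knots at the distinct
x values, the minimizer is the natural cubic spline through fitted values

    g = (W + lambda * Q R^{-1} Q')^{-1} W ybar,

where ybar are weighted means of y at each distinct x and Q, R are the
standard second-difference / overlap matrices of the knot spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, CubicSpline


def _reinsch_matrices(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q (n x n-2) and R (n-2 x n-2) matrices for knots t (Green & Silverman)."""
    n = len(t)
    h = np.diff(t)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        k = j - 1
        Q[j - 1, k] = 1.0 / h[j - 1]
        Q[j, k] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, k] = 1.0 / h[j]
        R[k, k] = (h[j - 1] + h[j]) / 3.0
        if k + 1 <= n - 3:
            R[k, k + 1] = h[j] / 6.0
            R[k + 1, k] = h[j] / 6.0
    return Q, R


def _bspline_diagonals(u: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonals of X'WX and of Omega for a cubic B-spline basis with knots at u.

    u must be sorted, distinct, in [0, 1]; w are the weights at each u.
    Omega_jk = int B_j''(s) B_k''(s) ds over [u[0], u[-1]], computed exactly
    with two-point Gauss-Legendre per knot interval (B'' is piecewise linear).
    """
    k = 3
    knots = np.concatenate([np.repeat(u[0], k), u, np.repeat(u[-1], k)])
    nbasis = len(u) + k - 1
    X = BSpline.design_matrix(u, knots, k).toarray()
    diag_xwx = np.sum(w[:, None] * X**2, axis=0)

    # Gauss-Legendre with 2 nodes is exact for the degree-2 integrand B_j''B_k''
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    omega_diag = np.zeros(nbasis)
    coeffs = np.eye(nbasis)
    d2 = [BSpline(knots, coeffs[j], k).derivative(2) for j in range(nbasis)]
    for a, b in zip(u[:-1], u[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gl_x
        vals = np.array([f(pts) for f in d2])  # (nbasis, 2)
        omega_diag += half * np.sum(vals**2, axis=1)
    return diag_xwx, omega_diag


def stiffness_to_lambda(spar: float, u: np.ndarray, w: np.ndarray) -> float:
    """Penalty weight for stiffness ``spar`` on scaled knots u with weights w.

    The trace ratio r sums interior basis functions only (the first two and
    last three are excluded), mirroring the reference fitting routine so a
    given stiffness selects the same curve.
    """
    diag_xwx, omega_diag = _bspline_diagonals(u, w)
    r = float(np.sum(diag_xwx[2:-3]) / np.sum(omega_diag[2:-3]))
    return r * 256.0 ** (3.0 * spar - 1.0)


@dataclass
class SmoothingSpline:
    """A fitted natural cubic smoothing spline over a shared predictor axis."""

    stiffness: float
    lam: float
    knots: np.ndarray  # distinct predictor values, original scale
    fitted: np.ndarray  # fitted values at the knots
    _interp: CubicSpline = field(repr=False, default=None)

    def __post_init__(self):
        if self._interp is None:
            self._interp = CubicSpline(self.knots, self.fitted, bc_type="natural")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"predictor outside spline support [{lo:g}, {hi:g}]"
            )
        return self._interp(x)


def fit_smoothing_spline(
    x: np.ndarray,
    y: np.ndarray,
    stiffness: float = 0.7,
    weights: np.ndarray | None = None,
) -> SmoothingSpline:
    """Fit the common smoothing spline to pooled (x, y) points.

    Duplicate x values are pooled into weighted means, so every point
    contributes equally regardless of how many share a predictor value.

    Parameters
    ----------
    x, y
        Pooled predictor (e.g. calendar year) and response values.
    stiffness
        Dimensionless smoothing parameter in (0, 1]; larger is stiffer.
    weights
        Optional per-point weights (default 1 each).
    """
    if not (0.0 < stiffness <= 1.0):
        raise ValueError(f"stiffness must be in (0, 1], got {stiffness}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if weights is None:
        weights = np.ones_like(x)
    else:
        weights = np.asarray(weights, dtype=float)[mask]

    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < 4:
        raise ValueError(f"need >= 4 distinct predictor values, got {len(ux)}")
    w = np.bincount(inv, weights=weights)
    ybar = np.bincount(inv, weights=weights * y) / w

    # rescale predictor to [0, 1]; the spar -> lambda map is defined there
    span = ux[-1] - ux[0]
    u = (ux - ux[0]) / span
    lam = stiffness_to_lambda(stiffness, u, w)

    Q, R = _reinsch_matrices(u)
    K = Q @ np.linalg.solve(R, Q.T)  # penalty matrix: g'Kg = int f''^2 on u-scale
    A = np.diag(w) + lam * K
    g = np.linalg.solve(A, w * ybar)
    return SmoothingSpline(stiffness=stiffness, lam=lam, knots=ux, fitted=g)
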