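"""Cubic regression spline bases with quadratic curvature penalties.

Both bases use the value-at-knot parameterisation: the coefficient vector is
the spline's value at the knots, second derivatives at the knots are the
linear map ``gamma = B^{-1} D beta`` implied by continuity, and the curvature
penalty is exactly ``integral f''(x)^2 dx = beta' D' B^{-1} D beta``.

* cyclic basis: value, first and second derivative match at the two ends of
  the period (used for hour-of-day and day-of-year);
* natural basis: second derivative zero at the boundary knots (used for the
  aperiodic covariates: lunar fraction, chlorophyll-a).
"""

from __future__ import annotations

import numpy as np


def _interp_blocks(x: np.ndarray, knots: np.ndarray):
    """Cubic-interpolation weight matrices A (values) and C (2nd derivatives).

    For x in [x_j, x_{j+1}]:
      f(x) = a-*beta_j + a+*beta_{j+1} + c-*gamma_j + c+*gamma_{j+1}
    with the classic cubic spline interpolant weights.
    Returns (A, C) of shape (n, len(knots)).
    """
    n, k = len(x), len(knots)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    left = knots[j + 1] - x
    right = x - knots[j]
    A = np.zeros((n, k))
    C = np.zeros((n, k))
    rows = np.arange(n)
    np.add.at(A, (rows, j), left / h)
    np.add.at(A, (rows, j + 1), right / h)
    np.add.at(C, (rows, j), left**3 / (6 * h) - h * left / 6)
    np.add.at(C, (rows, j + 1), right**3 / (6 * h) - h * right / 6)
    return A, C


def cyclic_cubic_basis(x, period: float, k: int):
    """Cyclic cubic regression spline design and penalty.

    Parameters: x in [0, period] (wrapped modulo the period), k equally spaced
    knots on [0, period] whose first and last values are identified, leaving
    k - 1 free columns.  Returns (X, S, knots) with X of shape (n, k-1) and S
    the (k-1, k-1) curvature penalty.
    """
    if k < 4:
        raise ValueError("cyclic cubic basis needs k >= 4")
    x = np.mod(np.asarray(x, dtype=float), period)
    knots = np.linspace(0.0, period, k)
    m = k - 1  # free knot values (last knot == first)
    h = np.diff(knots)  # m interval widths

    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for j in range(m):
        jm = (j - 1) % m
        jp = (j + 1) % m
        B[j, j] = (h[jm] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        B[j, jm] += h[jm] / 6.0
        D[j, j] = -(1.0 / h[jm] + 1.0 / h[j])
        D[j, jp] += 1.0 / h[j]
        D[j, jm] += 1.0 / h[jm]
    F = np.linalg.solve(B, D)  # maps knot values -> knot 2nd derivatives
    S = D.T @ F
    S = (S + S.T) / 2.0

    A, C = _interp_blocks(x, knots)
    # identify last knot with first (cyclic wrap)
    A[:, 0] += A[:, -1]
    C[:, 0] += C[:, -1]
    X = A[:, :m] + C[:, :m] @ F
    return X, S, knots


def natural_cubic_basis(x, knots):
    """Natural cubic regression spline design and penalty at given knots.

    Coefficients are values at the k knots; second derivatives vanish at the
    boundary knots.  x outside the knot range is clamped to the range.
    Returns (X, S) with X of shape (n, k) and S (k, k).
    """
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 4:
        raise ValueError("natural cubic basis needs k >= 4")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    h = np.diff(knots)

    ki = k - 2  # interior knots carrying free 2nd derivatives
    B = np.zeros((ki, ki))
    D = np.zeros((ki, k))
    for i in range(ki):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i > 0:
            B[i, i - 1] = h[i] / 6.0
        if i < ki - 1:
            B[i, i + 1] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -(1.0 / h[i] + 1.0 / h[i + 1])
        D[i, i + 2] = 1.0 / h[i + 1]
    F = np.linalg.solve(B, D)  # (k-2, k): values -> interior 2nd derivatives
    S = D.T @ F
    S = (S + S.T) / 2.0

    A, C = _interp_blocks(x, knots)
    X = A + C[:, 1:-1] @ F  # boundary gammas are zero
    return X, S


def quantile_knots(values, k: int) -> np.ndarray:
    """k knots at equally spaced quantiles of the observed values."""
    values = np.asarray(values, dtype=float)
    qs = np.linspace(0.0, 1.0, k)
    knots = np.quantile(values, qs)
    knots = np.unique(knots)
    if len(knots) < k:  # ties in the data: fall back to an even grid
        knots = np.linspace(values.min(), values.max(), k)
    if knots[0] == knots[-1]:
        raise ValueError("covariate has zero range; cannot place spline knots")
    return knots
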