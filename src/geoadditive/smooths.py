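"""Bayesian P-spline building blocks.

Each continuous covariate (age, BMI, wealth index score) gets a B-spline
design on equidistant knots plus a random-walk difference penalty K = D'D,
the standard P-spline pair: the Bayesian version reads K/tau^2 as the prior
precision of the basis coefficients, i.e. a random walk of order ``order``
on adjacent coefficients with smoothing variance tau^2.  A sum-to-zero
constraint over the sample makes the smooth identifiable next to the
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["SmoothTerm", "bspline_design", "difference_penalty", "center_smooth", "make_smooth_term"]


def _knot_vector(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    if hi <= lo:
        raise ValueError("degenerate covariate range for spline knots")
    interior = np.linspace(lo, hi, n_interior + 2)
    step = interior[1] - interior[0] if n_interior >= 0 else hi - lo
    left = lo - step * np.arange(degree, 0, -1)
    right = hi + step * np.arange(1, degree + 1)
    return np.concatenate([left, interior, right])


def bspline_design(
    x, n_interior_knots: int = 20, degree: int = 3, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """B-spline design matrix on equidistant knots spanning the data range.

    Returns ``(B, knots)`` with ``B`` of shape (n, n_interior_knots + degree + 1),
    rows summing to one (partition of unity).  Evaluation outside the knot
    range is an error: grids must be clamped explicitly by the caller.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if knots is None:
        knots = _knot_vector(x.min(), x.max(), n_interior_knots, degree)
    lo, hi = knots[degree], knots[-degree - 1] if degree > 0 else knots[-1]
    if x.min() < lo - 1e-12 or x.max() > hi + 1e-12:
        raise ValueError(
            f"x outside the knot range [{lo}, {hi}]; clamp the evaluation grid explicitly"
        )
    xc = np.clip(x, lo, hi)  # guard the right-closed boundary only
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return B, knots


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """Penalty K = D'D from the order-``order`` difference operator on k coefficients.

    rank(K) = k - order; the null space holds polynomials up to degree
    order-1 in the coefficient index (constant, and the linear trend when
    order = 2).
    """
    if k <= order:
        raise ValueError(f"need k > order, got k={k}, order={order}")
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


@dataclass
class SmoothTerm:
    """One P-spline smooth: design, penalty and (optional) centering transform.

    Before centering, ``design`` is the raw n x k basis and ``transform`` is
    None.  After :func:`center_smooth`, ``design`` is n x (k-1) in the
    constrained parameterisation, ``penalty`` is transformed accordingly, and
    ``transform`` (k x (k-1)) maps constrained coefficients back to the
    original basis so curves can be evaluated anywhere in range.
    """

    name: str
    knots: np.ndarray
    degree: int
    design: np.ndarray
    penalty: np.ndarray
    order: int = 2
    transform: np.ndarray | None = None
    penalty_rank: int | None = None

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def basis_at(self, grid) -> np.ndarray:
        """Raw-basis rows at ``grid`` mapped into the current parameterisation."""
        B, _ = bspline_design(grid, degree=self.degree, knots=self.knots)
        return B @ self.transform if self.transform is not None else B


def make_smooth_term(
    name: str, x, n_interior_knots: int = 20, degree: int = 3, order: int = 2
) -> SmoothTerm:
    B, knots = bspline_design(x, n_interior_knots, degree)
    K = difference_penalty(B.shape[1], order)
    return SmoothTerm(name=name, knots=knots, degree=degree, design=B, penalty=K, order=order)


def center_smooth(term: SmoothTerm) -> SmoothTerm:
    """Reparameterise so the fitted smooth sums to zero over the sample.

    The constraint 1'B gamma = 0 is imposed by an orthonormal basis Z of its
    null space: design -> BZ, penalty -> Z'KZ, and Z is kept to map draws
    back to the unconstrained basis.  Centering an already-centered term is a
    no-op.
    """
    if term.transform is not None:
        return term
    c = term.design.sum(axis=0)[None, :]
    Z = null_space(c)
    K_c = Z.T @ term.penalty @ Z
    rank = int(np.linalg.matrix_rank(K_c))
    return replace(
        term,
        design=term.design @ Z,
        penalty=K_c,
        transform=Z,
        penalty_rank=rank,
    )
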