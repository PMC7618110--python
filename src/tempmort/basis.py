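"""Spline bases for exposure-response, lag-response and seasonality terms.

Two families are provided:

* ``natural_cubic``: cubic splines constrained to have zero second
  derivative at (and linear behaviour beyond) the boundary knots.  Used
  for the seasonality term and for the lag-response function.
* ``bspline``: unconstrained Cox-de Boor B-splines on a clamped knot
  vector.  Used for the temperature exposure-response curve, with
  interior knots placed at percentiles of the location's own
  temperature distribution.

Both are pure functions of ``(x, spec)``: identical inputs give
bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "percentile_knots",
    "natural_cubic_basis",
    "bspline_basis",
    "evaluate_basis",
    "ncs_spec_from_df",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional spline basis.

    Parameters
    ----------
    family:
        ``"natural_cubic"`` or ``"bspline"``.
    interior_knots:
        Knots strictly inside the boundary, in the units of x.
    boundary_knots:
        Pair ``(lo, hi)`` with ``lo < hi``.
    degree:
        Polynomial degree; only meaningful for ``bspline`` (natural
        cubic splines are cubic by definition).
    with_intercept:
        If False (default) the basis spans functions alongside a model
        intercept: for B-splines the first column is dropped, for
        natural cubic splines the constant direction is removed.
    clamp:
        B-splines only: clip evaluation points to the boundary knots
        instead of raising on out-of-range x.  Natural cubic splines
        always extrapolate linearly and ignore this flag.
    """

    family: str
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    degree: int = 3
    with_intercept: bool = False
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("natural_cubic", "bspline", "constant"):
            raise ValueError(f"unknown basis family {self.family!r}")
        object.__setattr__(self, "interior_knots",
                           tuple(float(k) for k in self.interior_knots))
        object.__setattr__(self, "boundary_knots",
                           (float(self.boundary_knots[0]), float(self.boundary_knots[1])))
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary_knots must satisfy lo < hi")
        for k in self.interior_knots:
            if not (lo < k < hi):
                raise ValueError(f"interior knot {k} outside open boundary interval ({lo}, {hi})")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be non-decreasing")
        if self.family == "bspline" and self.degree < 1:
            raise ValueError("bspline degree must be >= 1")

    @property
    def df(self) -> int:
        """Number of basis columns."""
        if self.family == "constant":
            return 1
        m = len(self.interior_knots)
        if self.family == "natural_cubic":
            return m + 2 if self.with_intercept else m + 1
        return m + self.degree + (1 if self.with_intercept else 0)


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: an ``(n, df)`` matrix together with its spec."""

    values: np.ndarray
    spec: BasisSpec
    x: np.ndarray = field(repr=False)


def percentile_knots(values: np.ndarray, percentiles) -> np.ndarray:
    """Empirical percentiles of `values` at the given probabilities.

    Uses the linear-interpolation quantile definition (Hyndman-Fan
    type 7, numpy's default).  Missing values are ignored.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("percentile_knots: no finite values")
    pct = np.asarray(percentiles, dtype=float)
    if pct.size == 0:
        raise ValueError("percentile_knots: empty percentile list")
    if np.any(pct <= 0) or np.any(pct >= 100):
        raise ValueError("percentiles must lie strictly in (0, 100)")
    if pct.size > 1 and np.any(np.diff(pct) <= 0):
        raise ValueError("percentiles must be strictly increasing")
    return np.percentile(values, pct, method="linear")


def _check_x(x) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    return x


def _full_knot_vector(spec: BasisSpec, degree: int) -> np.ndarray:
    lo, hi = spec.boundary_knots
    return np.concatenate([
        np.repeat(lo, degree + 1),
        np.asarray(spec.interior_knots, dtype=float),
        np.repeat(hi, degree + 1),
    ])


def _bspline_design(x: np.ndarray, t: np.ndarray, degree: int,
                    deriv: int = 0) -> np.ndarray:
    """Dense design matrix of all B-spline basis functions (or a
    derivative) at `x`; columns follow the Cox-de Boor ordering."""
    ncol = len(t) - degree - 1
    spl = BSpline(t, np.eye(ncol), degree, extrapolate=True)
    if deriv:
        spl = spl.derivative(deriv)
    return spl(x)


def _ncs_projector(spec: BasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Projection onto the natural-constraint null space.

    Returns (t, Z): the clamped knot vector of the underlying cubic
    B-spline space and a matrix Z such that B(x) @ Z has zero second
    derivative at both boundary knots.  The first B-spline column is
    dropped first when the spec carries no intercept.
    """
    t = _full_knot_vector(spec, 3)
    bknots = np.asarray(spec.boundary_knots)
    d2 = _bspline_design(bknots, t, 3, deriv=2)
    keep = slice(None) if spec.with_intercept else slice(1, None)
    d2 = d2[:, keep]
    # null space of the two second-derivative constraints via full QR
    q, _ = np.linalg.qr(d2.T, mode="complete")
    z = q[:, 2:]
    return t, z


def natural_cubic_basis(x, spec: BasisSpec) -> BasisMatrix:
    """Natural cubic spline basis (R ``ns``-style construction).

    The basis spans cubic splines on the interior knots with second
    derivative zero at the boundary knots; outside the boundaries each
    column continues linearly (first-order Taylor expansion at the
    boundary, exact for a natural spline).
    """
    if spec.family != "natural_cubic":
        raise ValueError("spec.family must be 'natural_cubic'")
    x = _check_x(x)
    t, z = _ncs_projector(spec)
    keep = slice(None) if spec.with_intercept else slice(1, None)
    lo, hi = spec.boundary_knots

    inside = np.clip(x, lo, hi)
    vals = _bspline_design(inside, t, 3)[:, keep] @ z

    below = x < lo
    above = x > hi
    if below.any() or above.any():
        bpts = np.array([lo, hi])
        b0 = _bspline_design(bpts, t, 3)[:, keep] @ z
        b1 = _bspline_design(bpts, t, 3, deriv=1)[:, keep] @ z
        if below.any():
            vals[below] = b0[0] + np.outer(x[below] - lo, b1[0])
        if above.any():
            vals[above] = b0[1] + np.outer(x[above] - hi, b1[1])

    return BasisMatrix(values=vals, spec=spec, x=x)


def bspline_basis(x, spec: BasisSpec) -> BasisMatrix:
    """Cox-de Boor B-spline basis on a clamped knot vector.

    With an intercept the columns sum to one inside the boundaries
    (partition of unity); without, the first column is dropped so the
    basis is full rank alongside a model intercept.
    """
    if spec.family != "bspline":
        raise ValueError("spec.family must be 'bspline'")
    x = _check_x(x)
    lo, hi = spec.boundary_knots
    out = (x < lo) | (x > hi)
    if out.any():
        if not spec.clamp:
            raise ValueError(
                f"{out.sum()} evaluation points outside boundary knots "
                f"[{lo}, {hi}]; enable clamp to clip them")
        x = np.clip(x, lo, hi)
    t = _full_knot_vector(spec, spec.degree)
    vals = _bspline_design(x, t, spec.degree)
    if not spec.with_intercept:
        vals = vals[:, 1:]
    return BasisMatrix(values=vals, spec=spec, x=x)


def evaluate_basis(x, spec: BasisSpec) -> BasisMatrix:
    """Dispatch on the spec's family."""
    if spec.family == "natural_cubic":
        return natural_cubic_basis(x, spec)
    if spec.family == "constant":
        x = _check_x(x)
        return BasisMatrix(values=np.ones((x.size, 1)), spec=spec, x=x)
    return bspline_basis(x, spec)


def ncs_spec_from_df(x: np.ndarray, df: int, with_intercept: bool = False) -> BasisSpec:
    """Natural-cubic spec with `df` columns and knots at equally spaced
    quantiles of `x` (boundary knots at the data range)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values")
    n_interior = df - (2 if with_intercept else 1)
    if n_interior < 0:
        raise ValueError(f"df={df} too small for a natural cubic basis")
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior:
        probs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = tuple(np.percentile(x, probs, method="linear"))
    else:
        interior = ()
    return BasisSpec(family="natural_cubic", interior_knots=interior,
                     boundary_knots=(lo, hi), with_intercept=with_intercept)
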