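"""DLNM cross-basis: the exposure x lag tensor-product design block.

The distributed-lag non-linear model represents the log relative risk
as a bi-dimensional surface s(x, l) over exposure intensity x and lag
l, parameterized as a tensor product of an exposure basis b(x) (var
dimension, ``var_df`` columns) and a lag basis c(l) evaluated at the
integer lags 0..L (``lag_df`` columns).  Cross-basis column (j, k) at
day t holds

    sum_{l=0..L} b_j(x_{t-l}) * c_k(l)

Columns are ordered var-major: all lag columns for var column 0, then
var column 1, and so on.  The first L days have incomplete exposure
history; their rows are NaN and flagged for exclusion by the fitter.

``reduce_overall`` maps the fitted (var_df*lag_df) coefficient vector
to the var_df coefficients of the overall cumulative exposure-response
(the curve summed over lags), together with its covariance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

from .basis import BasisMatrix, BasisSpec, evaluate_basis

__all__ = [
    "CrossBasisSpec",
    "CrossBasis",
    "ReducedCurve",
    "log_lag_knots",
    "default_lag_spec",
    "build_crossbasis",
    "reduce_overall",
    "predict_curve",
    "predict_lag_surface",
]


@dataclass(frozen=True)
class CrossBasisSpec:
    var_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def var_df(self) -> int:
        return self.var_spec.df

    @property
    def lag_df(self) -> int:
        return self.lag_spec.df

    @property
    def ncol(self) -> int:
        return self.var_df * self.lag_df

    def lag_basis(self) -> np.ndarray:
        """Lag basis evaluated exactly at the integer lags 0..L."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        return evaluate_basis(lags, self.lag_spec).values


@dataclass(frozen=True)
class CrossBasis:
    values: np.ndarray            # (n, var_df*lag_df); NaN rows = incomplete history
    spec: CrossBasisSpec
    exposure: np.ndarray

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of rows with a complete, fully observed history."""
        return np.all(np.isfinite(self.values), axis=1)


@dataclass(frozen=True)
class ReducedCurve:
    """Overall cumulative exposure-response: coefficients on the
    exposure basis, their covariance, and an optional centering value."""

    coef: np.ndarray
    vcov: np.ndarray
    spec: BasisSpec
    center: float | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        vcov = np.asarray(self.vcov, dtype=float)
        if vcov.shape != (coef.size, coef.size):
            raise ValueError("vcov not conformable with coef")
        if not np.allclose(vcov, vcov.T, atol=1e-8):
            raise ValueError("vcov must be symmetric")
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "vcov", 0.5 * (vcov + vcov.T))

    # -- plain-text serialization (consumed by stage2/attribution) ----
    def to_text(self) -> str:
        s = self.spec
        lines = [
            f"family\t{s.family}",
            f"degree\t{s.degree}",
            f"with_intercept\t{int(s.with_intercept)}",
            "interior_knots\t" + "\t".join(repr(float(k)) for k in s.interior_knots),
            f"boundary_knots\t{float(s.boundary_knots[0])!r}\t{float(s.boundary_knots[1])!r}",
            f"center\t{'' if self.center is None else repr(float(self.center))}",
            "coef\t" + "\t".join(repr(float(c)) for c in self.coef),
        ]
        for row in self.vcov:
            lines.append("vcov\t" + "\t".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReducedCurve":
        fields: dict[str, list[str]] = {}
        vcov_rows = []
        for line in text.strip().splitlines():
            key, *vals = line.split("\t")
            if key == "vcov":
                vcov_rows.append([float(v) for v in vals])
            else:
                fields[key] = vals
        spec = BasisSpec(
            family=fields["family"][0],
            degree=int(fields["degree"][0]),
            with_intercept=bool(int(fields["with_intercept"][0])),
            interior_knots=tuple(float(v) for v in fields.get("interior_knots", []) if v != ""),
            boundary_knots=(float(fields["boundary_knots"][0]), float(fields["boundary_knots"][1])),
        )
        center = fields["center"][0] if fields.get("center") else ""
        return cls(
            coef=np.array([float(v) for v in fields["coef"]]),
            vcov=np.array(vcov_rows),
            spec=spec,
            center=float(center) if center else None,
        )


def log_lag_knots(max_lag: int, n_knots: int) -> tuple[float, ...]:
    """Interior lag knots equally spaced on the log-lag scale in (1, L)."""
    if n_knots <= 0:
        return ()
    if max_lag < 2:
        raise ValueError("need max_lag >= 2 to place interior lag knots")
    s = np.linspace(np.log(1.0), np.log(float(max_lag)), n_knots + 2)[1:-1]
    return tuple(np.exp(s))


def default_lag_spec(max_lag: int, n_knots: int | None = None) -> BasisSpec:
    """Natural cubic lag basis with an intercept column.

    Knot-count rule: 2 interior knots for a 0-7 lag window, 3 for 0-14
    and beyond, overridable.  With L = 0 the basis degenerates to the
    single constant column.
    """
    if max_lag == 0:
        return BasisSpec(family="constant", interior_knots=(),
                         boundary_knots=(-0.5, 0.5), with_intercept=True)
    if n_knots is None:
        n_knots = 2 if max_lag <= 7 else 3
    return BasisSpec(
        family="natural_cubic",
        interior_knots=log_lag_knots(max_lag, n_knots),
        boundary_knots=(0.0, float(max_lag)),
        with_intercept=True,
    )


def build_crossbasis(x, spec: CrossBasisSpec) -> CrossBasis:
    """Tensor-product cross-basis of a daily exposure series.

    Missing exposures (NaN) propagate into every row whose lag window
    touches them, as do the first L rows of the series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    L = spec.max_lag
    if n <= L:
        raise ValueError(f"series of length {n} shorter than max_lag+1={L + 1}")

    vspec = spec.var_spec
    finite = np.isfinite(x)
    V = np.full((n, spec.var_df), np.nan)
    if finite.any():
        V[finite] = evaluate_basis(x[finite], vspec).values
    C = spec.lag_basis()                      # (L+1, lag_df)

    Q = np.zeros((n, spec.var_df, spec.lag_df))
    for l in range(L + 1):
        Vl = np.full_like(V, np.nan)
        Vl[l:] = V[:n - l] if l else V
        Q += Vl[:, :, None] * C[l][None, None, :]
    return CrossBasis(values=Q.reshape(n, spec.ncol), spec=spec, exposure=x)


def _reduction_matrix(spec: CrossBasisSpec) -> np.ndarray:
    """M with reduced = M @ coef_full: sums the lag dimension out.

    For var-major ordering, M = I_{var_df} (kron) (1' C) where C is the
    lag basis at integer lags 0..L.
    """
    ones_c = np.sum(spec.lag_basis(), axis=0)         # (lag_df,)
    return np.kron(np.eye(spec.var_df), ones_c[None, :])


def reduce_overall(coef_full, vcov_full, spec: CrossBasisSpec,
                   center: float | None = None) -> ReducedCurve:
    """Reduce full DLNM coefficients to the overall cumulative curve."""
    coef_full = np.asarray(coef_full, dtype=float)
    vcov_full = np.asarray(vcov_full, dtype=float)
    if coef_full.size != spec.ncol:
        raise ValueError(f"expected {spec.ncol} coefficients, got {coef_full.size}")
    if vcov_full.shape != (spec.ncol, spec.ncol):
        raise ValueError("vcov_full not conformable")
    M = _reduction_matrix(spec)
    return ReducedCurve(coef=M @ coef_full, vcov=M @ vcov_full @ M.T,
                        spec=spec.var_spec, center=center)


def predict_curve(curve: ReducedCurve, grid, center: float | None = None):
    """Log relative risk (and standard error) along `grid`, relative to
    `center`; logRR(center) = 0 with zero standard error by construction.
    """
    if center is None:
        center = curve.center
    if center is None:
        raise ValueError("no centering value: pass center= or set curve.center")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    B = evaluate_basis(grid, curve.spec).values
    b0 = evaluate_basis(np.array([center]), curve.spec).values[0]
    X = B - b0
    logrr = X @ curve.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, curve.vcov, X), 0.0))
    return logrr, se


def predict_lag_surface(coef_full, vcov_full, spec: CrossBasisSpec,
                        exposure_value: float, center: float):
    """Lag-specific log relative risk at a fixed exposure value.

    Returns (logrr, se), each of length L+1: the contribution of lag l
    to the cumulative association of `exposure_value` relative to
    `center`.  Summing logrr over lags reproduces the reduced overall
    prediction at that value.
    """
    coef_full = np.asarray(coef_full, dtype=float)
    vcov_full = np.asarray(vcov_full, dtype=float)
    bv = evaluate_basis(np.array([exposure_value]), spec.var_spec).values[0]
    bc = evaluate_basis(np.array([center]), spec.var_spec).values[0]
    C = spec.lag_basis()                           # (L+1, lag_df)
    # row for lag l: kron(bv - bc, C[l]) under var-major ordering
    X = np.einsum("j,lk->ljk", bv - bc, C).reshape(spec.max_lag + 1, spec.ncol)
    logrr = X @ coef_full
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, vcov_full, X), 0.0))
    return logrr, se
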