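"""Multivariate random-effects meta-regression across locations.

Each location i contributes a q-vector of reduced curve coefficients
theta_i with within-location covariance S_i.  The model is

    theta_i ~ N(X_i beta, S_i + Psi),     X_i = z_i' (kron) I_q

where z_i holds the location-level meta-predictors (plus intercept)
and Psi is the q x q between-location covariance, shared across
locations.  Fixed effects are estimated by generalized least squares
given Psi; Psi itself by restricted maximum likelihood (default) over
a Cholesky parameterization.  This mirrors the standard multivariate
meta-analysis formulation used in two-stage environmental time-series
studies.

Meta-predictors are standardized (centered and scaled) internally for
optimizer stability; reported fixed effects are back-transformed to
the original predictor scale.  Wald statistics are computed on the
standardized scale, to which they are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .crossbasis import ReducedCurve

__all__ = [
    "MetaInput",
    "MetaModel",
    "BlupSet",
    "fit_meta",
    "wald_test",
    "heterogeneity",
    "blup",
]

META_PREDICTORS = ("avg_temp", "temp_range", "pw_latitude", "pw_elevation",
                   "pop_density", "avg_rh", "mpi")


@dataclass
class MetaInput:
    """Reduced per-location estimates plus the meta-predictor table.

    `predictors` may be None (intercept-only pooling) or a DataFrame
    with one row per location, aligned with `curves`.
    """

    location_ids: list[str]
    curves: list[ReducedCurve]
    predictors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        k = len(self.curves)
        if len(self.location_ids) != k:
            raise ValueError("location_ids and curves length mismatch")
        qs = {c.coef.size for c in self.curves}
        if len(qs) != 1:
            raise ValueError("all reduced curves must share the same dimension q")
        if self.predictors is not None and len(self.predictors) != k:
            raise ValueError("predictor table must have one row per location")

    @property
    def k(self) -> int:
        return len(self.curves)

    @property
    def q(self) -> int:
        return self.curves[0].coef.size

    def theta(self) -> np.ndarray:
        return np.stack([c.coef for c in self.curves])

    def S(self) -> np.ndarray:
        S = np.stack([c.vcov for c in self.curves])
        for i, Si in enumerate(S):
            ev = np.linalg.eigvalsh(Si)
            if ev.min() < -1e-8 * max(ev.max(), 1.0):
                raise ValueError(f"location vcov {self.location_ids[i]} is not positive semi-definite")
        return S


@dataclass
class MetaModel:
    beta: np.ndarray                 # (p+1, q) on the ORIGINAL predictor scale
    vcov_beta: np.ndarray            # ((p+1)q, (p+1)q), standardized scale
    psi: np.ndarray                  # (q, q) between-location covariance
    loglik: float                    # restricted (or full) log-likelihood
    method: str
    predictor_names: list[str]       # without intercept
    Q: float
    Q_df: int
    Q_pvalue: float
    I2: float
    wald: dict[str, dict]            # per-predictor {stat, df, p}
    converged: bool
    # internals needed by blup()
    _Z_std: np.ndarray = field(repr=False, default=None)
    _beta_std: np.ndarray = field(repr=False, default=None)
    _center: np.ndarray = field(repr=False, default=None)
    _scale: np.ndarray = field(repr=False, default=None)

    @property
    def q(self) -> int:
        return self.psi.shape[0]

    def fixed_prediction(self, z_std_row: np.ndarray) -> np.ndarray:
        """Fixed-effects curve prediction for one (standardized) row."""
        return self._beta_std.T @ z_std_row


@dataclass
class BlupSet:
    location_ids: list[str]
    coefs: np.ndarray                # (k, q)
    vcovs: np.ndarray                # (k, q, q)

    def curves(self, inputs: MetaInput) -> list[ReducedCurve]:
        return [ReducedCurve(coef=self.coefs[i], vcov=self.vcovs[i],
                             spec=inputs.curves[i].spec)
                for i in range(len(self.location_ids))]


def _design(inputs: MetaInput) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Standardized design (k, p+1) with leading intercept column."""
    k = inputs.k
    if inputs.predictors is None:
        return np.ones((k, 1)), [], np.zeros(0), np.ones(0)
    Z = inputs.predictors.to_numpy(dtype=float)
    names = list(inputs.predictors.columns)
    if not np.all(np.isfinite(Z)):
        raise ValueError("meta-predictor table contains missing values")
    center = Z.mean(axis=0)
    scale = Z.std(axis=0, ddof=0)
    if np.any(scale == 0):
        bad = [names[j] for j in np.where(scale == 0)[0]]
        raise ValueError(f"constant meta-predictor(s): {bad}")
    Zs = (Z - center) / scale
    Zfull = np.hstack([np.ones((k, 1)), Zs])
    # with k <= p+1 the design is trivially deficient; let the caller's
    # sample-size check produce the clearer error
    if k > Zfull.shape[1] and np.linalg.matrix_rank(Zfull) < Zfull.shape[1]:
        raise ValueError("meta-predictor design is rank deficient (aliased predictors)")
    return Zfull, names, center, scale


def _gls(theta, S, psi, Z):
    """GLS fixed effects given Psi, with batched linear algebra.

    Returns beta_std (p1, q), vcov of vec(beta) (predictor-major
    ordering), residuals, the stacked V_i^-1, log|V| accumulated over
    locations, and X'V^-1X.
    """
    k, q = theta.shape
    p1 = Z.shape[1]
    V = S + psi[None, :, :]
    chol = np.linalg.cholesky(V)                # raises if any V_i not PD
    logdet_V = 2.0 * float(np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2))))
    Vinv = np.linalg.inv(V)
    # X_i = z_i' (kron) I_q; rows of vec(beta) ordered (predictor, coef)
    XtVX = np.einsum("ij,il,iab->jalb", Z, Z, Vinv).reshape(p1 * q, p1 * q)
    XtVy = np.einsum("ij,iab,ib->ja", Z, Vinv, theta).reshape(-1)
    beta_vec = np.linalg.solve(XtVX, XtVy)
    vcov_beta = np.linalg.inv(XtVX)
    beta = beta_vec.reshape(p1, q)
    resid = theta - Z @ beta
    return beta, vcov_beta, resid, Vinv, logdet_V, XtVX


def _neg2_loglik(par, theta, S, Z, method):
    k, q = theta.shape
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = par
    psi = L @ L.T
    try:
        beta, _, resid, Vinv, logdet_V, XtVX = _gls(theta, S, psi, Z)
    except np.linalg.LinAlgError:
        return 1e12
    quad = float(np.einsum("ij,ijk,ik->", resid, Vinv, resid))
    n2 = logdet_V + quad
    if method == "reml":
        sign, logdet_X = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        n2 += logdet_X
    return n2


def _psi_moment(theta, S, Z) -> np.ndarray:
    """Crude PSD moment estimate: cov of GLS residuals at Psi=0 minus
    the average within-location covariance, projected to PSD."""
    beta, _, resid, *_ = _gls(theta, S, np.zeros((theta.shape[1],) * 2), Z)
    emp = np.cov(resid.T, ddof=Z.shape[1]) if theta.shape[0] > Z.shape[1] else np.zeros((theta.shape[1],) * 2)
    emp = np.atleast_2d(emp)
    raw = emp - S.mean(axis=0)
    w, v = np.linalg.eigh(0.5 * (raw + raw.T))
    return (v * np.maximum(w, 0.0)) @ v.T


def fit_meta(inputs: MetaInput, method: str = "reml") -> MetaModel:
    """Fit the multivariate meta-regression.

    method: "reml" (default), "ml", or "mm" (a one-step moment
    estimator of Psi followed by GLS, no likelihood optimization).
    """
    if method not in ("reml", "ml", "mm"):
        raise ValueError(f"unknown method {method!r}")
    theta = inputs.theta()
    S = inputs.S()
    Z, names, center, scale = _design(inputs)
    k, q = theta.shape
    p1 = Z.shape[1]
    if k <= p1:
        raise ValueError(f"k={k} locations insufficient for {p1} fixed-effect terms")

    converged = True
    if method == "mm":
        psi = _psi_moment(theta, S, Z)
        loglik = -0.5 * _neg2_loglik(_chol_param(psi), theta, S, Z, "ml")
    else:
        start = 0.1 * S.mean(axis=0)
        x0 = _chol_param(start)
        res = optimize.minimize(
            _neg2_loglik, x0, args=(theta, S, Z, method),
            method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        Lm = np.zeros((q, q))
        Lm[np.tril_indices(q)] = res.x
        psi = Lm @ Lm.T
        loglik = -0.5 * res.fun
        converged = bool(res.success)
    psi = 0.5 * (psi + psi.T)

    beta_std, vcov_beta, resid, Vinv, _, _ = _gls(theta, S, psi, Z)

    # heterogeneity at the fixed-effects-only (Psi = 0) fit
    _, _, resid0, Vinv0, _, _ = _gls(theta, S, np.zeros((q, q)), Z)
    Q = float(np.einsum("ij,ijk,ik->", resid0, Vinv0, resid0))
    Q_df = (k - p1) * q
    Q_p = float(stats.chi2.sf(Q, Q_df))
    I2 = max(0.0, (Q - Q_df) / Q) * 100.0 if Q > 0 else 0.0

    wald = {}
    for j, name in enumerate(names, start=1):
        sl = slice(j * q, (j + 1) * q)
        b = beta_std.reshape(-1)[sl]
        V = vcov_beta[sl, sl]
        stat = float(b @ np.linalg.solve(V, b))
        wald[name] = {"stat": stat, "df": q, "p": float(stats.chi2.sf(stat, q))}

    beta = _back_transform(beta_std, center, scale)
    return MetaModel(beta=beta, vcov_beta=vcov_beta, psi=psi, loglik=loglik,
                     method=method, predictor_names=names, Q=Q, Q_df=Q_df,
                     Q_pvalue=Q_p, I2=I2, wald=wald, converged=converged,
                     _Z_std=Z, _beta_std=beta_std, _center=center, _scale=scale)


def _chol_param(psi: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (psi + psi.T))
    psi_psd = (v * np.maximum(w, 1e-12)) @ v.T
    return np.linalg.cholesky(psi_psd)[np.tril_indices(psi.shape[0])]


def _back_transform(beta_std: np.ndarray, center: np.ndarray,
                    scale: np.ndarray) -> np.ndarray:
    beta = beta_std.copy()
    if center.size:
        beta[1:] = beta_std[1:] / scale[:, None]
        beta[0] = beta_std[0] - (center / scale) @ beta_std[1:]
    return beta


def wald_test(model: MetaModel, predictor: str) -> dict:
    """Wald chi-square test that all q coefficients of one
    meta-predictor are zero."""
    if predictor not in model.wald:
        raise KeyError(f"unknown predictor {predictor!r}; have {list(model.wald)}")
    return model.wald[predictor]


def heterogeneity(model: MetaModel) -> dict:
    """Multivariate Cochran Q (at the fixed-effects-only fit) and I2."""
    return {"Q": model.Q, "Q_df": model.Q_df, "p": model.Q_pvalue, "I2": model.I2}


def sample_curve_ensemble(model: MetaModel, inputs: MetaInput,
                          n_sim: int, seed) -> np.ndarray:
    """Joint Monte-Carlo ensemble of per-location curve coefficients.

    Returns an array of shape (k, n_sim, q).  Each draw s shares one
    fixed-effect draw beta_s ~ N(beta_hat, vcov_beta) across all
    locations and adds an independent location disturbance through the
    BLUP shrinkage map:

        curve_{i,s} = A_i (theta_i + eps_{i,s}) + (I - A_i) X_i' beta_s,
        A_i = Psi (Psi + S_i)^-1,  eps_{i,s} ~ N(0, S_i).

    The shared beta_s term is what carries the between-location
    correlation of curve uncertainty: when Psi is small every
    location's curve collapses onto the pooled fixed-effect curve and
    their errors are nearly perfectly correlated, which matters when
    attributable numbers are summed across locations.  Independent
    per-location draws would understate any aggregate interval by up
    to sqrt(k).
    """
    theta = inputs.theta()
    S = inputs.S()
    Z = model._Z_std
    k, q = theta.shape
    rng = np.random.default_rng(seed)

    Lb = _psd_factor(model.vcov_beta)
    beta_vec = model._beta_std.reshape(-1)
    beta_s = beta_vec[None, :] + rng.standard_normal((n_sim, beta_vec.size)) @ Lb.T
    beta_mats = beta_s.reshape(n_sim, Z.shape[1], q)
    out = np.empty((k, n_sim, q))
    for i in range(k):
        A = model.psi @ np.linalg.inv(S[i] + model.psi)
        eps = rng.standard_normal((n_sim, q)) @ _psd_factor(S[i]).T
        pred_s = np.einsum("j,sjq->sq", Z[i], beta_mats)
        out[i] = (theta[i] + eps) @ A.T + pred_s @ (np.eye(q) - A).T
    return out


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semi-definite matrices."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(0.5 * (M + M.T))
        return v * np.sqrt(np.maximum(w, 0.0))


def blup(model: MetaModel, inputs: MetaInput) -> BlupSet:
    """Best linear unbiased predictions of each location's curve.

    BLUP_i = X_i beta + Psi (Psi + S_i)^-1 (theta_i - X_i beta): the
    first-stage estimate shrunk toward the meta-regression prediction
    in proportion to its relative imprecision.  The reported covariance
    is the conditional covariance Psi - Psi (Psi + S_i)^-1 Psi plus the
    propagated fixed-effect uncertainty.
    """
    theta = inputs.theta()
    S = inputs.S()
    Z = model._Z_std
    beta = model._beta_std
    k, q = theta.shape
    coefs = np.empty((k, q))
    vcovs = np.empty((k, q, q))
    for i in range(k):
        Vi = S[i] + model.psi
        try:
            A = model.psi @ np.linalg.inv(Vi)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"Psi + S_i singular for {inputs.location_ids[i]}; "
                "consider adding a small ridge to the location vcov") from e
        pred = beta.T @ Z[i]
        coefs[i] = pred + A @ (theta[i] - pred)
        Xi = np.kron(Z[i][:, None], np.eye(q))       # (p1*q, q)
        C = (np.eye(q) - A) @ Xi.T
        cond = model.psi - A @ model.psi
        vcovs[i] = cond + C @ model.vcov_beta @ C.T
        vcovs[i] = 0.5 * (vcovs[i] + vcovs[i].T)
    return BlupSet(location_ids=list(inputs.location_ids), coefs=coefs, vcovs=vcovs)
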