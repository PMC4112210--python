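"""REML and BLUP for the centred animal model with one or two GRMs.

Model: y = X beta + sum_k N a_k + e, with a_k ~ N(0, G_k sigma2_k) and
e ~ N(0, I sigma2_e).  N is the record-to-animal incidence (one 1 per row),
so animals genotyped but unphenotyped are carried in G and receive
predictions through relationships.

The restricted log-likelihood is

    lR = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1 X| + y'Py ]

with V = sum_k N G_k N' sigma2_k + I sigma2_e; the (n-p)/2 * log 2*pi
constant is included, so printed values are comparable only within a run.
Single-GRM fits use an eigendecomposition of N G N' that reduces REML to a
one-dimensional profile in the variance ratio; multi-GRM fits use L-BFGS-B
on log-variances with the analytic gradient, and the two routes agree where
they overlap (a tested invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .grm import GRM

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class DesignData:
    """Phenotype vector, fixed-effect incidence, record-to-animal map."""

    y: np.ndarray                     # (n_obs,)
    X: np.ndarray                     # (n_obs, p), full column rank
    obs_idx: np.ndarray | None = None  # record i belongs to animal obs_idx[i]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X have different numbers of records")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is not of full column rank")
        if self.obs_idx is not None:
            self.obs_idx = np.asarray(self.obs_idx, dtype=int)
            if self.obs_idx.shape != self.y.shape:
                raise ValueError("obs_idx must have one entry per record")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    def animal_indices(self, q: int) -> np.ndarray:
        if self.obs_idx is None:
            if q != self.n_obs:
                raise ValueError(
                    f"{q} animals in G but {self.n_obs} records and no obs_idx")
            return np.arange(q)
        if self.obs_idx.max() >= q:
            raise ValueError("obs_idx points beyond the animals in G")
        return self.obs_idx

    def nt_dot(self, v: np.ndarray, q: int) -> np.ndarray:
        """N' v — accumulate record-level vector onto animals."""
        idx = self.animal_indices(q)
        out = np.zeros(q)
        np.add.at(out, idx, v)
        return out


@dataclass
class VarianceComponents:
    """sigma2 for each genetic term plus the residual, all >= 0."""

    genetic: tuple[float, ...]
    sigma2_e: float

    def __post_init__(self):
        self.genetic = tuple(float(v) for v in np.atleast_1d(self.genetic))
        if any(v < 0 for v in self.genetic) or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def sigma2_a(self) -> float:
        return sum(self.genetic)

    @property
    def sigma2_a1(self) -> float:
        return self.genetic[0]

    @property
    def sigma2_a2(self) -> float:
        return self.genetic[1]

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total


@dataclass
class REMLFit:
    vc: VarianceComponents
    beta: np.ndarray
    ahat_terms: list[np.ndarray]       # one BLUP vector per GRM
    loglik: float
    converged: bool
    n_iter: int
    data: DesignData
    grms: list[GRM]
    pev: np.ndarray | None = None      # (q, q), single-GRM fits
    var_ahat: np.ndarray | None = None

    @property
    def ahat(self) -> np.ndarray:
        """Total genetic prediction per animal (sum over random terms)."""
        return np.sum(self.ahat_terms, axis=0)


# ---------------------------------------------------------------------------
# restricted likelihood machinery
# ---------------------------------------------------------------------------

def _kernels(data: DesignData, grms: list[GRM]) -> list[np.ndarray]:
    """Record-level covariance kernels N G_k N' (dense, n_obs x n_obs)."""
    out = []
    for g in grms:
        idx = data.animal_indices(g.n)
        out.append(g.G[np.ix_(idx, idx)])
    return out


def _v_chol(Ks, s_gen, s_e, n):
    V = s_e * np.eye(n)
    for K, s in zip(Ks, s_gen):
        V = V + s * K
    return linalg.cholesky(0.5 * (V + V.T), lower=True)


def reml_loglik(data: DesignData, grms: list[GRM],
                vc: VarianceComponents) -> float:
    """Restricted log-likelihood at the given variance components."""
    Ks = _kernels(data, grms)
    ll, *_ = _ll_parts(data.y, data.X, Ks, np.array(vc.genetic), vc.sigma2_e)
    return ll


def _ll_parts(y, X, Ks, s_gen, s_e):
    """Return (lR, Vinv_y, Vinv_X, XtViX_chol, Py)."""
    n, p = X.shape
    L = _v_chol(Ks, s_gen, s_e, n)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    ViX = linalg.cho_solve((L, True), X)
    Viy = linalg.cho_solve((L, True), y)
    XtViX = X.T @ ViX
    Lx = linalg.cholesky(XtViX, lower=True)
    logdetX = 2.0 * np.sum(np.log(np.diag(Lx)))
    beta = linalg.cho_solve((Lx, True), X.T @ Viy)
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetX + yPy)
    return ll, Viy, ViX, (Lx, True), Py


def _neg_ll_and_grad(theta, y, X, Ks):
    """Negative lR and gradient in theta = log variances (genetic..., e)."""
    s = np.exp(theta)
    s_gen, s_e = s[:-1], s[-1]
    n, p = X.shape
    L = _v_chol(Ks, s_gen, s_e, n)
    Vi = linalg.cho_solve((L, True), np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    Lx = linalg.cholesky(XtViX, lower=True)
    logdetX = 2.0 * np.sum(np.log(np.diag(Lx)))
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    beta = linalg.cho_solve((Lx, True), ViX.T @ y)
    Py = Vi @ y - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetX + yPy)
    # P = Vi - ViX (X'ViX)^-1 X'Vi ; dlR/ds_k = -1/2 [tr(P K_k) - y'P K_k P y]
    W = linalg.cho_solve((Lx, True), ViX.T)  # (p, n); P = Vi - ViX @ W
    grad = np.empty_like(s)
    for k, K in enumerate(list(Ks) + [np.eye(n)]):
        trPK = np.trace(Vi @ K) - np.einsum("ij,ji->", W, K @ ViX)
        quad = float(Py @ K @ Py)
        grad[k] = -0.5 * (trPK - quad)
    return -ll, -(grad * s)  # chain rule for log parametrization


# ---------------------------------------------------------------------------
# single-GRM eigendecomposition fast path
# ---------------------------------------------------------------------------

def _reml_1grm_eig(data: DesignData, grm: GRM, tol: float, max_iter: int):
    y, X = data.y, data.X
    n, p = X.shape
    K = _kernels(data, [grm])[0]
    d, U = linalg.eigh(0.5 * (K + K.T))
    d = np.clip(d, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def profiled_negll(log_gamma):
        gamma = np.exp(log_gamma)
        w = gamma * d + 1.0
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        Lx = linalg.cholesky(XtWX, lower=True)
        beta = linalg.cho_solve((Lx, True), Xw.T @ yt)
        r = yt - Xt @ beta
        q = float(r @ (r / w))
        s_e = q / (n - p)
        ll = -0.5 * ((n - p) * (_LOG2PI + np.log(s_e) + 1.0)
                     + np.sum(np.log(w))
                     + 2.0 * np.sum(np.log(np.diag(Lx))))
        return -ll, s_e, beta

    lo, hi = -25.0, 25.0
    grid = np.linspace(lo, hi, 101)
    vals = np.array([profiled_negll(g)[0] for g in grid])
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: profiled_negll(g)[0],
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": max(tol, 1e-12),
                                            "maxiter": max_iter})
    lg = float(res.x)
    _, s_e, _ = profiled_negll(lg)
    gamma = np.exp(lg)
    s_a = gamma * s_e
    boundary = lg <= lo + 1e-6
    if boundary:
        s_a = 0.0
    converged = bool(res.success) or boundary
    n_iter = int(getattr(res, "nfev", 0)) + len(grid)
    return s_a, s_e, converged, n_iter


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def reml_fit(data: DesignData, grms: list[GRM] | GRM,
             init: VarianceComponents | None = None,
             tol: float = 1e-8, max_iter: int = 200,
             method: str = "auto", compute_pev: bool = True) -> REMLFit:
    """Fit the animal model by REML.

    ``method``: 'eig' (single-GRM profile path), 'generic' (L-BFGS-B on
    log-variances, any number of GRMs), or 'auto'.  Components are clamped
    at 1e-10 * var(y); a fit stopping at that floor counts as a boundary
    estimate of zero.
    """
    if isinstance(grms, GRM):
        grms = [grms]
    grms = list(grms)
    if not 1 <= len(grms) <= 2:
        raise ValueError("reml_fit supports one or two GRMs")
    if data.n_obs < data.n_fixed + 2:
        raise ValueError("need at least p + 2 observations for REML")
    vy = float(np.var(data.y))
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-10 * vy

    if method == "auto":
        method = "eig" if len(grms) == 1 else "generic"

    if method == "eig":
        if len(grms) != 1:
            raise ValueError("eig path handles a single GRM")
        s_a, s_e, converged, n_iter = _reml_1grm_eig(data, grms[0], tol, max_iter)
        s_gen = np.array([max(s_a, 0.0)])
    elif method == "generic":
        Ks = _kernels(data, grms)
        if init is None:
            if len(grms) == 2:
                base = reml_fit(data, [_merged_grm(grms)], method="eig",
                                compute_pev=False)
                s0 = np.array([0.1 * base.vc.sigma2_a + floor,
                               0.9 * base.vc.sigma2_a + floor,
                               base.vc.sigma2_e])
            else:
                s0 = np.array([0.5 * vy, 0.5 * vy])
        else:
            s0 = np.array(list(init.genetic) + [init.sigma2_e], dtype=float)
        theta0 = np.log(np.clip(s0, floor, None))
        bounds = [(np.log(floor), np.log(1e6 * vy))] * len(theta0)
        res = optimize.minimize(
            _neg_ll_and_grad, theta0, args=(data.y, data.X, Ks),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
        s = np.exp(res.x)
        s[s <= floor * (1 + 1e-6)] = 0.0
        s_gen, s_e = s[:-1], max(s[-1], floor)
        converged, n_iter = bool(res.success), int(res.nit)
        if not converged:
            logger.warning("REML did not converge: %s", res.message)
    else:
        raise ValueError(f"unknown REML method {method!r}")

    vc = VarianceComponents(genetic=tuple(s_gen), sigma2_e=float(s_e))
    ll, beta, ahat_terms = _solve_at_optimum(data, grms, vc)
    fit = REMLFit(vc=vc, beta=beta, ahat_terms=ahat_terms, loglik=ll,
                  converged=converged, n_iter=n_iter, data=data, grms=grms)
    if compute_pev and len(grms) == 1 and vc.sigma2_a > 0:
        # projection route needs no G^-1 and is exact for singular G
        fit.var_ahat = _var_ahat_projection(fit, data, grms[0])
        fit.pev = grms[0].G * vc.sigma2_a - fit.var_ahat
    return fit


def _merged_grm(grms: list[GRM]) -> GRM:
    return GRM(G=sum(g.G for g in grms))


def _solve_at_optimum(data: DesignData, grms: list[GRM],
                      vc: VarianceComponents):
    Ks = _kernels(data, grms)
    ll, Viy, ViX, Lx, Py = _ll_parts(data.y, data.X, Ks,
                                     np.array(vc.genetic), vc.sigma2_e)
    beta = linalg.cho_solve(Lx, data.X.T @ Viy)
    ahat_terms = []
    for g, s in zip(grms, vc.genetic):
        NtPy = data.nt_dot(Py, g.n)
        ahat_terms.append(s * (g.G @ NtPy))
    return ll, beta, ahat_terms


def blup(fit: REMLFit, data: DesignData | None = None,
         grms: list[GRM] | None = None) -> np.ndarray:
    """BLUP a_hat = sigma2_k G_k N' V^-1 (y - X beta) per random term.

    Returns the single vector for one GRM, else the stacked list's sum is
    available as ``fit.ahat``; terms are recomputed from the fit's variance
    components (identical to the MME route within numerical tolerance).
    """
    data = data or fit.data
    grms = grms or fit.grms
    _, _, terms = _solve_at_optimum(data, grms, fit.vc)
    return terms[0] if len(terms) == 1 else terms


def _projection(data: DesignData, grms, vc) -> np.ndarray:
    """REML projection matrix P at the fitted components (n_obs x n_obs)."""
    Ks = _kernels(data, grms)
    n = data.n_obs
    L = _v_chol(Ks, np.array(vc.genetic), vc.sigma2_e, n)
    Vi = linalg.cho_solve((L, True), np.eye(n))
    ViX = Vi @ data.X
    return Vi - ViX @ linalg.solve(data.X.T @ ViX, ViX.T)


def _var_ahat_projection(fit: REMLFit, data: DesignData,
                         grm: GRM) -> np.ndarray:
    """Var(a_hat) = sigma2_a^2 G N'PN G via the REML projection matrix."""
    s_a = fit.vc.sigma2_a
    q = grm.n
    P = _projection(data, [grm], fit.vc)
    idx = data.animal_indices(q)
    N = np.zeros((data.n_obs, q))
    N[np.arange(data.n_obs), idx] = 1.0
    GN = grm.G @ N.T
    V = s_a**2 * GN @ P @ GN.T
    return 0.5 * (V + V.T)


def pev_ahat(fit: REMLFit, data: DesignData | None = None,
             grm: GRM | None = None, route: str = "mme") -> np.ndarray:
    """Prediction error variance of a_hat for a single-GRM fit.

    ``mme`` route: PEV = C^aa sigma2_e, with C^aa the random-effect block of
    the inverse coefficient matrix [[X'X, X'N], [N'X, N'N + G^-1 lambda]],
    lambda = sigma2_e / sigma2_a.  ``vroute``: G sigma2_a -
    sigma2_a^2 G N' P N G.  The two agree to numerical precision.
    """
    data = data or fit.data
    grm = grm or fit.grms[0]
    if len(fit.grms) != 1:
        raise ValueError("PEV is defined here for single-GRM fits")
    s_a, s_e = fit.vc.sigma2_a, fit.vc.sigma2_e
    q = grm.n
    if s_a == 0:
        raise ValueError("sigma2_a = 0: PEV of a degenerate random effect")
    idx = data.animal_indices(q)
    if route == "vroute":
        P = _projection(data, [grm], fit.vc)
        N = np.zeros((data.n_obs, q))
        N[np.arange(data.n_obs), idx] = 1.0
        NtPN = N.T @ P @ N
        return grm.G * s_a - s_a**2 * grm.G @ NtPN @ grm.G
    lam = s_e / s_a
    X = data.X
    p = X.shape[1]
    NtX = np.zeros((q, p))
    np.add.at(NtX, idx, X)
    NtN = np.zeros((q, q))
    np.add.at(NtN, (idx, idx), 1.0)
    Ginv = grm.solve(np.eye(q))
    C = np.block([[X.T @ X, NtX.T], [NtX, NtN + lam * Ginv]])
    Cinv = linalg.inv(0.5 * (C + C.T))
    Caa = Cinv[p:, p:]
    return 0.5 * (Caa + Caa.T) * s_e


def var_ahat(fit: REMLFit, grm: GRM | None = None) -> np.ndarray:
    """Var(a_hat) = G sigma2_a - PEV (PSD within numerical tolerance)."""
    grm = grm or fit.grms[0]
    pev = fit.pev if fit.pev is not None else pev_ahat(fit, grm=grm)
    V = grm.G * fit.vc.sigma2_a - pev
    V = 0.5 * (V + V.T)
    dmin = float(np.min(np.diag(V)))
    scale = max(fit.vc.sigma2_a * float(np.max(np.diag(grm.G))), 1.0)
    if dmin < -1e-6 * scale:
        raise FloatingPointError(
            f"Var(a_hat) diagonal negative beyond tolerance ({dmin:.3e})")
    return V


def restricted_loglik(fit: REMLFit) -> float:
    """The restricted log-likelihood at the optimum (2*pi constant included)."""
    return fit.loglik


def vc_standard_errors(fit: REMLFit) -> np.ndarray:
    """Asymptotic SEs of (genetic..., residual) from the average-information
    matrix AI_kl = 1/2 y'P V_k P V_l P y evaluated at the optimum."""
    data, grms, vc = fit.data, fit.grms, fit.vc
    P = _projection(data, grms, vc)
    Py = P @ data.y
    mats = _kernels(data, grms) + [np.eye(data.n_obs)]
    k = len(mats)
    AI = np.empty((k, k))
    for i in range(k):
        vi = mats[i] @ Py
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(vi @ P @ (mats[j] @ Py))
    cov = linalg.pinvh(AI)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))
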