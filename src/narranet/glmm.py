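"""Generalized linear mixed models with crossed random intercepts.

Maximum-likelihood fitting of logistic and Gaussian mixed models with one
or more crossed random-intercept factors, using the Laplace approximation
to the marginal likelihood (equivalent to lme4's ``nAGQ = 1`` deviance).
The inner loop is penalized iteratively reweighted least squares (PIRLS)
over the joint fixed-effect / random-effect vector; the outer loop
optimizes the log standard deviations of the variance components with
Nelder-Mead.

Only random intercepts are supported; random slopes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["GLMMFit", "fit_glmm"]

# log-sd bounds for variance components (wide floor so near-noiseless
# Gaussian fits can drive the residual variance toward zero)
_LOG_SD_LO = -15.0
_LOG_SD_HI = 4.0
_RIDGE = 1e-10


@dataclass
class GLMMFit:
    """Result of a Laplace-ML mixed-model fit."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    loglik: float
    sigma: dict[str, float]
    sigma_resid: float | None
    u: dict[str, np.ndarray]
    family: str
    converged: bool
    message: str = ""
    vcov_beta: np.ndarray | None = None
    n_obs: int = 0

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.names, self.beta))

    @property
    def std_errors(self) -> dict[str, float]:
        return dict(zip(self.names, self.se))


def _validate_groups(groups: dict[str, np.ndarray], n: int) -> tuple[list[str], list[np.ndarray], list[int]]:
    gnames, codes_list, sizes = [], [], []
    for name, codes in groups.items():
        codes = np.asarray(codes)
        if codes.shape != (n,):
            raise ValueError(f"group '{name}' has shape {codes.shape}, expected ({n},)")
        _, enc = np.unique(codes, return_inverse=True)
        q = int(enc.max()) + 1
        if q < 2:
            raise ValueError(f"grouping factor '{name}' needs >=2 levels, got {q}")
        gnames.append(name)
        codes_list.append(enc.astype(np.intp))
        sizes.append(q)
    return gnames, codes_list, sizes


def _assemble_hessian(X, w, codes_list, sizes, dinv):
    """Dense (p+q) x (p+q) penalized Hessian via group-index bincounts."""
    n, p = X.shape
    q = int(sum(sizes))
    H = np.zeros((p + q, p + q))
    Xw = X * w[:, None]
    H[:p, :p] = Xw.T @ X
    offs = []
    off = p
    for codes, qg in zip(codes_list, sizes):
        offs.append(off)
        for j in range(p):
            H[j, off:off + qg] = np.bincount(codes, weights=Xw[:, j], minlength=qg)
        H[off:off + qg, :p] = H[:p, off:off + qg].T
        np.fill_diagonal(H[off:off + qg, off:off + qg],
                         np.bincount(codes, weights=w, minlength=qg))
        off += qg
    for a in range(len(codes_list)):
        for b in range(a + 1, len(codes_list)):
            qa, qb = sizes[a], sizes[b]
            cross = np.bincount(codes_list[a] * qb + codes_list[b],
                                weights=w, minlength=qa * qb).reshape(qa, qb)
            H[offs[a]:offs[a] + qa, offs[b]:offs[b] + qb] = cross
            H[offs[b]:offs[b] + qb, offs[a]:offs[a] + qa] = cross.T
    off = p
    for qg, dv in zip(sizes, dinv):
        idx = np.arange(off, off + qg)
        H[idx, idx] += dv + _RIDGE
        off += qg
    return H, offs


def _pirls(y, X, codes_list, sizes, sig2, sig2_res, family, v0, max_iter=60, tol=1e-9):
    """Maximize the penalized conditional log-likelihood over [beta; u].

    Returns (v_hat, f_hat, H, converged) with H the penalized Hessian at
    the mode (u-block includes the D^-1 penalty).
    """
    n, p = X.shape
    dinv = [1.0 / s2 for s2 in sig2]
    v = v0.copy()

    def split(v):
        beta = v[:p]
        us, off = [], p
        for qg in sizes:
            us.append(v[off:off + qg])
            off += qg
        return beta, us

    def f_and_parts(v):
        beta, us = split(v)
        eta = X @ beta
        for codes, u in zip(codes_list, us):
            eta = eta + u[codes]
        if family == "binomial":
            # log p(y|eta) = y*eta - log(1+e^eta), numerically stable
            ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
            mu = expit(eta)
            w = mu * (1.0 - mu)
            r = y - mu
        else:
            resid = y - eta
            ll = float(-0.5 * np.sum(resid ** 2) / sig2_res
                       - 0.5 * n * np.log(2.0 * np.pi * sig2_res))
            w = np.full(n, 1.0 / sig2_res)
            r = resid / sig2_res
        pen = 0.5 * sum(dv * float(u @ u) for dv, u in zip(dinv, us))
        return ll - pen, w, r, us

    f, w, r, us = f_and_parts(v)
    converged = False
    H = None
    for _ in range(max_iter):
        grad = np.empty(v.shape)
        grad[:p] = X.T @ r
        off = p
        for codes, qg, dv, u in zip(codes_list, sizes, dinv, us):
            grad[off:off + qg] = np.bincount(codes, weights=r, minlength=qg) - dv * u
            off += qg
        H, _ = _assemble_hessian(X, np.maximum(w, 1e-12), codes_list, sizes, dinv)
        if np.linalg.norm(grad) < tol * (1.0 + abs(f)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return v, f, H, False
        t = 1.0
        for _ls in range(30):
            v_new = v + t * step
            f_new, w_new, r_new, us_new = f_and_parts(v_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        if abs(f_new - f) < tol * (1.0 + abs(f)):
            v, f, w, r, us = v_new, f_new, w_new, r_new, us_new
            converged = True
            H, _ = _assemble_hessian(X, np.maximum(w, 1e-12), codes_list, sizes, dinv)
            break
        v, f, w, r, us = v_new, f_new, w_new, r_new, us_new
    if H is None:
        H, _ = _assemble_hessian(X, np.maximum(w, 1e-12), codes_list, sizes, dinv)
    return v, f, H, converged


def _laplace_loglik(f_hat, H, p, sizes, sig2):
    """Laplace-approximate marginal log-likelihood at the joint mode."""
    A = H[p:, p:]
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    logdet_D = sum(qg * np.log(s2) for qg, s2 in zip(sizes, sig2))
    return f_hat - 0.5 * (logdet_A + logdet_D)


def fit_glmm(
    y,
    X,
    groups: dict[str, np.ndarray],
    family: str = "binomial",
    names: list[str] | None = None,
    maxiter: int = 200,
) -> GLMMFit:
    """Fit a mixed model with crossed random intercepts by Laplace ML.

    Parameters
    ----------
    y : array (n,)
        Outcome; binary {0,1} for ``family='binomial'``.
    X : array (n, p)
        Fixed-effect design matrix (include the intercept column yourself).
    groups : dict
        Mapping from factor name to a length-n array of group labels; one
        random intercept per factor, factors fully crossed.
    family : 'binomial' or 'gaussian'
        Conditional distribution (logit link for binomial, identity for
        gaussian).
    names : list of str, optional
        Column names for ``X`` (defaults to ``x0..x{p-1}``).

    Returns
    -------
    GLMMFit
        ML estimates; ``converged=False`` flags optimizer failure,
        non-identifiability (rank-deficient ``X``), or quasi-separation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) matching y")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family '{family}'")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires a binary 0/1 outcome")
    if not groups:
        raise ValueError("at least one grouping factor is required")
    gnames, codes_list, sizes = _validate_groups(groups, n)

    identifiable = np.linalg.matrix_rank(X) == p
    if not identifiable:
        nan = np.full(p, np.nan)
        return GLMMFit(nan, nan.copy(), list(names), np.nan, {g: np.nan for g in gnames},
                       None, {}, family, converged=False,
                       message="fixed-effect design is rank deficient (non-identifiable)",
                       n_obs=n)

    q = int(sum(sizes))
    n_theta = len(sizes) + (1 if family == "gaussian" else 0)
    state = {"v": np.zeros(p + q), "pirls_ok": True}

    def negll(theta):
        th = np.clip(theta, _LOG_SD_LO, _LOG_SD_HI)
        sig2 = [float(np.exp(2.0 * t)) for t in th[:len(sizes)]]
        sig2_res = float(np.exp(2.0 * th[-1])) if family == "gaussian" else None
        v, f_hat, H, ok = _pirls(y, X, codes_list, sizes, sig2, sig2_res,
                                 family, state["v"])
        if ok:
            state["v"] = v
        state["pirls_ok"] = ok
        ll = _laplace_loglik(f_hat, H, p, sizes, sig2)
        # soft penalty keeps the simplex near the clipped box
        pen = float(np.sum(np.square(theta - th)))
        return -ll + pen

    theta0 = np.zeros(n_theta)
    if family == "gaussian":
        theta0[-1] = 0.5 * np.log(max(np.var(y), 1e-8))
    opt = minimize(negll, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": maxiter * n_theta,
                            "maxfev": maxiter * n_theta})
    th = np.clip(opt.x, _LOG_SD_LO, _LOG_SD_HI)
    sig2 = [float(np.exp(2.0 * t)) for t in th[:len(sizes)]]
    sig2_res = float(np.exp(2.0 * th[-1])) if family == "gaussian" else None
    v, f_hat, H, pirls_ok = _pirls(y, X, codes_list, sizes, sig2, sig2_res,
                                   family, state["v"], max_iter=100)
    ll = _laplace_loglik(f_hat, H, p, sizes, sig2)

    beta = v[:p]
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
        vcov_beta = cov[:p, :p]
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        vcov_beta = None

    us, off = {}, p
    for g, qg in zip(gnames, sizes):
        us[g] = v[off:off + qg]
        off += qg

    separated = family == "binomial" and bool(np.max(np.abs(beta)) > 15.0)
    converged = bool(pirls_ok and np.isfinite(ll) and not separated)
    msg = ""
    if separated:
        msg = "possible complete/quasi separation (|beta| > 15)"
    elif not pirls_ok:
        msg = "inner PIRLS did not converge"
    elif not opt.success:
        # Nelder-Mead hitting maxiter with a stable optimum is acceptable;
        # flag only when the deviance is not finite.
        msg = f"outer optimizer: {opt.message}"

    return GLMMFit(beta=beta, se=se, names=list(names), loglik=float(ll),
                   sigma={g: float(np.sqrt(s2)) for g, s2 in zip(gnames, sig2)},
                   sigma_resid=(float(np.sqrt(sig2_res)) if sig2_res is not None else None),
                   u=us, family=family, converged=converged, message=msg,
                   vcov_beta=vcov_beta, n_obs=n)
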