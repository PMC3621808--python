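"""Three-level random-intercept regression models (children in schools in countries).

Two links are supported:

* identity: a linear mixed model, fitted by maximum likelihood through
  :class:`statsmodels.regression.mixed_linear_model.MixedLM` (country as the
  top grouping factor, schools as a variance component nested within it);
* logit: a logistic mixed model with random intercepts at both grouping
  levels, fitted in-package.  The marginal likelihood is approximated by
  the Laplace method: for candidate random-intercept SDs (sigma_country,
  sigma_school) the joint penalized log-likelihood is maximized over the
  fixed effects and the standardized random effects by Newton's method,
  and the profiled Laplace objective is optimized over the two SDs by
  L-BFGS-B.  An optional nested adaptive Gauss-Hermite quadrature
  (``method="agq"``) refines the Laplace solution; with intercept-only
  random effects the two agree to roughly the third decimal on cohorts of
  the size used here.

Both fits return a :class:`MixedModelFit` carrying the fixed-effect
estimates, their full covariance matrix (needed by the mediation delta
method), the variance components, and an odds-ratio view for logit links.

Nested grouping is encoded by composite school keys (``country:school``)
so that identically labelled schools in different countries never cross.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import linalg, optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "MixedModelFit",
    "ConvergenceError",
    "SingularDesignError",
    "WaldResult",
    "wald_test",
    "fit_three_level",
    "ThreeLevelLogisticRegression",
    "ThreeLevelLinearRegression",
]

#: two-sided 95% normal quantile, fixed project-wide
Z95 = 1.959964


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries iteration diagnostics."""


class SingularDesignError(ValueError):
    """The fixed-effect design is rank deficient; names the collinear columns."""


@dataclass
class WaldResult:
    estimate: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]


@dataclass
class MixedModelFit:
    """Fitted three-level model: everything the mediation engine consumes."""

    params: pd.Series
    cov_params: pd.DataFrame
    vc: dict[str, float]  # random-intercept variances: {"country": ..., "school": ...}
    n_obs: int
    loglik: float
    converged: bool
    link: str
    n_groups: dict[str, int]

    def __post_init__(self):
        C = self.cov_params.to_numpy()
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("fixed-effect covariance matrix is not symmetric")

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    def wald(self, name: str) -> WaldResult:
        return wald_test(self, name)

    def odds_ratios(self) -> pd.DataFrame:
        """OR view of a logit fit: exp(coef) with 95% CIs."""
        if self.link != "logit":
            raise ValueError("odds ratios are only defined for logit fits")
        se = self.se
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "cov_params": self.cov_params.to_numpy().tolist(),
                "names": list(self.params.index),
                "vc": self.vc,
                "n_obs": self.n_obs,
                "loglik": self.loglik,
                "converged": self.converged,
                "link": self.link,
                "n_groups": self.n_groups,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixedModelFit":
        d = json.loads(text)
        names = d["names"]
        return cls(
            params=pd.Series({k: d["params"][k] for k in names}),
            cov_params=pd.DataFrame(d["cov_params"], index=names, columns=names),
            vc=d["vc"],
            n_obs=d["n_obs"],
            loglik=d["loglik"],
            converged=d["converged"],
            link=d["link"],
            n_groups=d["n_groups"],
        )


def wald_test(fit: MixedModelFit, name: str) -> WaldResult:
    """Normal-theory Wald test and 95% CI for one fixed effect."""
    est = float(fit.params[name])
    se = float(fit.se[name])
    if se == 0:
        raise ZeroDivisionError(f"Wald test undefined for {name!r}: SE is zero")
    z = est / se
    p = float(2.0 * special.ndtr(-abs(z)))
    return WaldResult(est, se, z, p, (est - Z95 * se, est + Z95 * se))


# ---------------------------------------------------------------------------
# design handling


def _check_design(X: np.ndarray, names: list[str]):
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns whose removal restores full rank
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R).max()]
        raise SingularDesignError(f"collinear fixed-effect columns: {bad or names}")


def _encode_groups(country, school):
    country = np.asarray(country).astype(str)
    school = np.asarray(school).astype(str)
    composite = np.char.add(np.char.add(country, ":"), school)
    c_labels, c_idx = np.unique(country, return_inverse=True)
    s_labels, s_idx = np.unique(composite, return_inverse=True)
    # nesting integrity: each composite school key maps to one country
    s_country = np.full(len(s_labels), -1)
    s_country[s_idx] = c_idx
    return c_idx, s_idx, len(c_labels), len(s_labels), s_country


# ---------------------------------------------------------------------------
# logistic Laplace machinery


class _LogitLaplace:
    def __init__(self, X, y, c_idx, s_idx, n_c, n_s, max_iter=200, tol=1e-8):
        self.X, self.y = X, y
        self.c_idx, self.s_idx = c_idx, s_idx
        self.n_c, self.n_s = n_c, n_s
        self.p = X.shape[1]
        self.max_iter, self.tol = max_iter, tol
        self.state = np.zeros(self.p + n_c + n_s)  # warm start across sigma evals
        self.inner_converged = True

    def _eta(self, theta, sc, ss):
        beta = theta[: self.p]
        zc = theta[self.p : self.p + self.n_c]
        zs = theta[self.p + self.n_c :]
        return self.X @ beta + sc * zc[self.c_idx] + ss * zs[self.s_idx], beta, zc, zs

    def _objective(self, theta, sc, ss):
        eta, _, zc, zs = self._eta(theta, sc, ss)
        ll = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(zc @ zc + zs @ zs)

    def _newton(self, sc, ss):
        """Maximize the joint penalized log-likelihood over (beta, z)."""
        theta = self.state.copy()
        p, n_c, n_s = self.p, self.n_c, self.n_s
        g_old = self._objective(theta, sc, ss)
        self.inner_converged = False
        for it in range(self.max_iter):
            eta, beta, zc, zs = self._eta(theta, sc, ss)
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.y - mu
            grad = np.concatenate(
                [
                    self.X.T @ resid,
                    sc * np.bincount(self.c_idx, resid, minlength=n_c) - zc,
                    ss * np.bincount(self.s_idx, resid, minlength=n_s) - zs,
                ]
            )
            H = self._hessian(w, sc, ss)
            try:
                cf = linalg.cho_factor(H, check_finite=False)
            except linalg.LinAlgError as exc:  # pragma: no cover - defensive
                raise ConvergenceError(f"penalized Hessian not PD at iter {it}") from exc
            step = linalg.cho_solve(cf, grad, check_finite=False)
            # backtracking line search on the penalized objective
            t = 1.0
            for _ in range(30):
                cand = theta + t * step
                g_new = self._objective(cand, sc, ss)
                if g_new >= g_old - 1e-12:
                    break
                t *= 0.5
            theta, g_gain = cand, g_new - g_old
            g_old = g_new
            if abs(g_gain) < self.tol * (abs(g_old) + 1.0):
                self.inner_converged = True
                break
        self.state = theta
        return theta, g_old

    def _hessian(self, w, sc, ss):
        p, n_c, n_s = self.p, self.n_c, self.n_s
        X = self.X
        WX = w[:, None] * X
        H = np.zeros((p + n_c + n_s, p + n_c + n_s))
        H[:p, :p] = X.T @ WX
        Mc = np.zeros((n_c, p))
        np.add.at(Mc, self.c_idx, WX)
        Ms = np.zeros((n_s, p))
        np.add.at(Ms, self.s_idx, WX)
        H[p : p + n_c, :p] = sc * Mc
        H[:p, p : p + n_c] = sc * Mc.T
        H[p + n_c :, :p] = ss * Ms
        H[:p, p + n_c :] = ss * Ms.T
        wc = np.bincount(self.c_idx, w, minlength=n_c)
        ws = np.bincount(self.s_idx, w, minlength=n_s)
        H[p : p + n_c, p : p + n_c] = np.diag(sc**2 * wc + 1.0)
        H[p + n_c :, p + n_c :] = np.diag(ss**2 * ws + 1.0)
        # school-within-country cross block
        ws_by_pair = np.zeros((n_c, n_s))
        np.add.at(ws_by_pair, (self.c_idx, self.s_idx), w)
        H[p : p + n_c, p + n_c :] = sc * ss * ws_by_pair
        H[p + n_c :, p : p + n_c] = (sc * ss * ws_by_pair).T
        return H

    def profile_loglik(self, sigmas):
        """Laplace log-likelihood with (beta, z) jointly profiled at the SDs.

        Used only to initialize the full Laplace optimization: the joint
        penalized mode of beta is not the Laplace-ML beta (the
        log-determinant term also depends on beta through the weights).
        """
        sc, ss = float(sigmas[0]), float(sigmas[1])
        theta, g = self._newton(sc, ss)
        eta, _, _, _ = self._eta(theta, sc, ss)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        Hzz = self._hessian(w, sc, ss)[self.p :, self.p :]
        sign, logdet = np.linalg.slogdet(Hzz)
        if sign <= 0:  # pragma: no cover - defensive
            raise ConvergenceError("random-effect Hessian block not PD")
        return g - 0.5 * logdet

    # -- full Laplace objective: inner mode over z only ---------------------

    def _z_hessian(self, w, sc, ss):
        """Hessian of the penalized objective in z alone (dense q x q)."""
        n_c, n_s = self.n_c, self.n_s
        wc = np.bincount(self.c_idx, w, minlength=n_c)
        ws = np.bincount(self.s_idx, w, minlength=n_s)
        H = np.zeros((n_c + n_s, n_c + n_s))
        H[:n_c, :n_c] = np.diag(sc**2 * wc + 1.0)
        H[n_c:, n_c:] = np.diag(ss**2 * ws + 1.0)
        ws_by_pair = np.zeros((n_c, n_s))
        np.add.at(ws_by_pair, (self.c_idx, self.s_idx), w)
        H[:n_c, n_c:] = sc * ss * ws_by_pair
        H[n_c:, :n_c] = H[:n_c, n_c:].T
        return H

    def _z_mode(self, beta, sc, ss):
        """Newton maximization over z at fixed (beta, sigmas).

        Always starts from z = 0 with a tight tolerance so the profiled
        objective is a deterministic function of (beta, sigmas); a
        warm-started state would make repeated evaluations at the same
        point disagree at the finite-difference scale of the outer
        optimizer and derail its line search.
        """
        n_c, n_s = self.n_c, self.n_s
        z = np.zeros(n_c + n_s)
        eta0 = self.X @ beta

        def obj(z):
            eta = eta0 + sc * z[:n_c][self.c_idx] + ss * z[n_c:][self.s_idx]
            return float(self.y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * float(z @ z)

        g_old = obj(z)
        for _ in range(self.max_iter):
            eta = eta0 + sc * z[:n_c][self.c_idx] + ss * z[n_c:][self.s_idx]
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.y - mu
            grad = np.concatenate(
                [
                    sc * np.bincount(self.c_idx, resid, minlength=n_c) - z[:n_c],
                    ss * np.bincount(self.s_idx, resid, minlength=n_s) - z[n_c:],
                ]
            )
            H = self._z_hessian(w, sc, ss)
            step = linalg.cho_solve(linalg.cho_factor(H, check_finite=False), grad, check_finite=False)
            t = 1.0
            for _ in range(30):
                cand = z + t * step
                g_new = obj(cand)
                if g_new >= g_old - 1e-12:
                    break
                t *= 0.5
            z, gain = cand, g_new - g_old
            g_old = g_new
            if abs(gain) < 1e-11 * (abs(g_old) + 1.0):
                break
        self.state = np.concatenate([beta, z])
        eta = eta0 + sc * z[:n_c][self.c_idx] + ss * z[n_c:][self.s_idx]
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        return z, g_old, w

    def laplace_nll(self, par):
        """Negative Laplace log-likelihood as a function of (beta, sc, ss)."""
        beta = par[: self.p]
        sc, ss = abs(float(par[-2])), abs(float(par[-1]))
        _, g, w = self._z_mode(beta, sc, ss)
        sign, logdet = np.linalg.slogdet(self._z_hessian(w, sc, ss))
        if sign <= 0:  # pragma: no cover - defensive
            raise ConvergenceError("random-effect Hessian block not PD")
        return -(g - 0.5 * logdet)

    def beta_cov(self, sigmas):
        """Joint-mode beta and its covariance (used for initialization)."""
        sc, ss = float(sigmas[0]), float(sigmas[1])
        theta, _ = self._newton(sc, ss)
        eta, _, _, _ = self._eta(theta, sc, ss)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = self._hessian(w, sc, ss)
        Hinv = linalg.inv(H, check_finite=False)
        return theta[: self.p], Hinv[: self.p, : self.p]

    def cov_at(self, beta, sigmas):
        """Fixed-effect covariance at a given beta: beta block of the inverse
        full penalized Hessian evaluated at (beta, z_mode(beta))."""
        sc, ss = float(sigmas[0]), float(sigmas[1])
        _, _, w = self._z_mode(np.asarray(beta, dtype=float), sc, ss)
        H = self._hessian(w, sc, ss)
        Hinv = linalg.inv(H, check_finite=False)
        return Hinv[: self.p, : self.p]


def _agq_loglik(helper: _LogitLaplace, beta, sc, ss, n_points=7):
    """Nested adaptive Gauss-Hermite marginal log-likelihood.

    School effects are integrated out with AGH within each school
    (adaptation around the conditional mode given the country node), then
    the country effect with AGH around its Laplace mode.  Costs
    O(n_points^2) likelihood sweeps; intended for validation at modest n.
    """
    nodes, weights = hermegauss(n_points)  # weight exp(-t^2/2), sum w = sqrt(2 pi)
    log_w = np.log(weights) - 0.5 * np.log(2 * math.pi)  # fold in the N(0,1) density
    X, y = helper.X, helper.y
    eta0 = X @ beta
    # Laplace modes for adaptation
    theta, _ = helper._newton(sc, ss)
    zc_hat = theta[helper.p : helper.p + helper.n_c]

    total = 0.0
    for c in range(helper.n_c):
        in_c = helper.c_idx == c
        schools = np.unique(helper.s_idx[in_c])
        # curvature of the country integrand at its mode (from the Laplace fit)
        # approximated via the weight sums; adaptation only needs a scale
        mu_hat = special.expit(
            eta0[in_c] + sc * zc_hat[c] + ss * theta[helper.p + helper.n_c :][helper.s_idx[in_c]]
        )
        curv = 1.0 + sc**2 * float(np.clip(mu_hat * (1 - mu_hat), 1e-10, None).sum())
        scale_c = 1.0 / math.sqrt(curv)
        log_terms = np.empty(n_points)
        for i, t in enumerate(nodes):
            zc = zc_hat[c] + scale_c * t
            log_pc = -0.5 * zc**2
            for s in schools:
                rows = helper.s_idx == s
                log_pc += _school_integral(
                    eta0[rows] + sc * zc, y[rows], ss, nodes, log_w
                )
            # change of variables back to the standard normal quadrature
            log_terms[i] = log_pc + log_w[i] + 0.5 * nodes[i] ** 2 + math.log(scale_c)
        total += float(special.logsumexp(log_terms))
    return total


def _school_integral(eta_fixed, y, ss, nodes, log_w):
    """log integral over one school's standardized intercept (1-D AGH)."""
    if ss == 0.0:
        return float(y @ eta_fixed - np.logaddexp(0.0, eta_fixed).sum())
    # 1-D Newton for the conditional mode
    z = 0.0
    for _ in range(25):
        eta = eta_fixed + ss * z
        mu = special.expit(eta)
        g = ss * float((y - mu).sum()) - z
        h = ss**2 * float(np.clip(mu * (1 - mu), 1e-10, None).sum()) + 1.0
        step = g / h
        z += step
        if abs(step) < 1e-10:
            break
    scale = 1.0 / math.sqrt(h)
    vals = np.empty(len(nodes))
    for i, t in enumerate(nodes):
        zz = z + scale * t
        eta = eta_fixed + ss * zz
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        vals[i] = ll - 0.5 * zz**2 + log_w[i] + 0.5 * t**2 + math.log(scale)
    return float(special.logsumexp(vals))


# ---------------------------------------------------------------------------
# estimators


class ThreeLevelLogisticRegression(BaseEstimator):
    """Random-intercept logistic regression with school-in-country nesting.

    Parameters
    ----------
    method : {"laplace", "agq"}
        Likelihood approximation.  ``"agq"`` refines the Laplace solution
        with nested adaptive Gauss-Hermite quadrature (``n_quad`` points
        per level).
    n_quad : int
        Quadrature points per level for ``method="agq"``.
    max_iter, tol : int, float
        Inner Newton iteration cap and relative objective tolerance.
    sd_bound : float
        Upper bound for each random-intercept SD during optimization.

    Attributes (after ``fit``)
    --------------------------
    result_ : MixedModelFit
    params_, cov_params_, vc_ : convenience views of ``result_``
    """

    def __init__(self, method="laplace", n_quad=7, max_iter=200, tol=1e-8, sd_bound=5.0):
        self.method = method
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.tol = tol
        self.sd_bound = sd_bound

    def fit(self, X, y, groups):
        """Fit on a design matrix/DataFrame ``X`` (no intercept column needed).

        ``groups`` is an (n, 2) array-like of ``[country, school]`` labels.
        """
        names, Xd = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("logit link requires a binary 0/1 outcome")
        groups = np.asarray(groups)
        c_idx, s_idx, n_c, n_s, _ = _encode_groups(groups[:, 0], groups[:, 1])
        Xd = np.column_stack([np.ones(len(y)), Xd])
        names = ["Intercept"] + names
        _check_design(Xd, names)

        # standardize the non-intercept columns: optimizing on the raw scale
        # leaves a flat intercept/covariate ridge when covariates are far
        # from zero (e.g. age in years)
        ctr = Xd[:, 1:].mean(axis=0)
        scl = Xd[:, 1:].std(axis=0)
        scl[scl == 0] = 1.0
        Xs = Xd.copy()
        Xs[:, 1:] = (Xd[:, 1:] - ctr) / scl

        helper = _LogitLaplace(Xs, y, c_idx, s_idx, n_c, n_s, self.max_iter, self.tol)
        # stage 1: cheap initialization from the jointly profiled objective
        res0 = optimize.minimize(
            lambda s: -helper.profile_loglik(s),
            x0=np.array([0.3, 0.3]),
            method="L-BFGS-B",
            bounds=[(0.0, self.sd_bound)] * 2,
            options={"maxiter": self.max_iter, "ftol": 1e-8},
        )
        beta0, _ = helper.beta_cov(np.abs(res0.x))
        # stage 2: Laplace maximum likelihood over (beta, sigmas)
        x0 = np.concatenate([beta0, np.abs(res0.x)])
        bounds = [(None, None)] * len(names) + [(0.0, self.sd_bound)] * 2
        res = optimize.minimize(
            helper.laplace_nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-11},
        )
        if not res.success:
            # derivative-free polish rescues the occasional L-BFGS-B line
            # search failure near the sigma = 0 boundary
            res_nm = optimize.minimize(
                lambda p: helper.laplace_nll(np.concatenate([p[:-2], np.abs(p[-2:])])),
                res.x if np.isfinite(res.fun) else x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000},
            )
            if res_nm.fun <= res.fun or not np.isfinite(res.fun):
                res = res_nm
        beta = res.x[: len(names)]
        sigmas = np.abs(res.x[-2:])
        loglik = -res.fun
        converged = bool(res.success)

        if self.method == "agq":

            def nll(par):
                return -_agq_loglik(
                    helper, par[: len(names)], abs(par[-2]), abs(par[-1]), self.n_quad
                )

            res2 = optimize.minimize(
                nll,
                np.concatenate([beta, sigmas]),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 60, "ftol": 1e-10},
            )
            converged = converged and bool(res2.success)
            beta = res2.x[: len(names)]
            sigmas = np.abs(res2.x[-2:])
            loglik = -res2.fun

        # covariance of the fixed effects: beta block of the inverse penalized
        # Hessian at the final estimates (conditional on the fitted sigmas)
        cov = helper.cov_at(beta, sigmas)

        # back-transform from the standardized to the raw covariate scale
        J = np.eye(len(names))
        J[0, 1:] = -ctr / scl
        J[1:, 1:] = np.diag(1.0 / scl)
        beta = J @ beta
        cov = J @ cov @ J.T

        if not converged:
            raise ConvergenceError(
                f"logistic mixed model did not converge: outer status "
                f"{res.message!r} after {res.nit} iterations, sigmas={sigmas}"
            )
        cov = (cov + cov.T) / 2.0
        self.result_ = MixedModelFit(
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            vc={"country": float(sigmas[0] ** 2), "school": float(sigmas[1] ** 2)},
            n_obs=len(y),
            loglik=float(loglik),
            converged=converged,
            link="logit",
            n_groups={"country": n_c, "school": n_s},
        )
        self.params_ = self.result_.params
        self.cov_params_ = self.result_.cov_params
        self.vc_ = self.result_.vc
        return self

    def predict_proba(self, X):
        """Event probability at zero random effects (cluster-median child)."""
        names, Xd = _as_design(X)
        eta = self.params_["Intercept"] + Xd @ self.params_[names].to_numpy()
        p1 = special.expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ThreeLevelLinearRegression(BaseEstimator):
    """Random-intercept linear mixed model via statsmodels MixedLM (ML fit)."""

    def __init__(self, max_iter=200, tol=1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, groups):
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        names, Xd = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        c_idx, s_idx, n_c, n_s, _ = _encode_groups(groups[:, 0], groups[:, 1])
        Xd = np.column_stack([np.ones(len(y)), Xd])
        names = ["Intercept"] + names
        _check_design(Xd, names)

        df = pd.DataFrame(Xd, columns=names)
        df["_y"] = y
        df["_country"] = c_idx
        df["_school"] = s_idx
        vcf = {"school": "0 + C(_school)"}
        model = MixedLM.from_formula(
            "_y ~ " + " + ".join(f"Q('{n}')" for n in names[1:]) if len(names) > 1 else "_y ~ 1",
            groups="_country",
            re_formula="1",
            vc_formula=vcf,
            data=df,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            sm_res = model.fit(reml=False, maxiter=self.max_iter)
        fe = sm_res.fe_params
        rename = {"Intercept": "Intercept"}
        rename.update({f"Q('{n}')": n for n in names[1:]})
        params = pd.Series({rename.get(k, k): v for k, v in fe.items()})[names]
        cov = sm_res.cov_params().iloc[: len(names), : len(names)]
        cov = pd.DataFrame(cov.to_numpy(), index=names, columns=names)
        cov = (cov + cov.T) / 2.0
        self.result_ = MixedModelFit(
            params=params,
            cov_params=cov,
            vc={
                "country": float(sm_res.cov_re.iloc[0, 0]),
                "school": float(sm_res.vcomp[0]) if len(sm_res.vcomp) else 0.0,
            },
            n_obs=len(y),
            loglik=float(sm_res.llf),
            converged=bool(sm_res.converged),
            link="identity",
            n_groups={"country": n_c, "school": n_s},
        )
        self.result_.vc["residual"] = float(sm_res.scale)
        self.params_ = self.result_.params
        self.cov_params_ = self.result_.cov_params
        self.vc_ = self.result_.vc
        return self

    def predict(self, X):
        names, Xd = _as_design(X)
        return self.params_["Intercept"] + Xd @ self.params_[names].to_numpy()


def _as_design(X):
    if isinstance(X, pd.DataFrame):
        return list(map(str, X.columns)), X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return [f"x{i}" for i in range(X.shape[1])], X


def fit_three_level(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    link: str = "identity",
    country_col: str = "country_id",
    school_col: str = "school_id",
    **settings,
) -> MixedModelFit:
    """Functional front end: fit a three-level model on cohort-table columns.

    ``fixed`` columns must be numeric (expand categoricals beforehand).
    Requires complete data and at least two groups per level.
    """
    cols = [outcome, *fixed, country_col, school_col]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    sub = data[cols]
    if sub[[outcome, *fixed]].isna().any().any():
        raise ValueError("fit_three_level requires complete data; assemble the analytic table first")
    if data[country_col].nunique() < 2 or data[school_col].nunique() < 2:
        raise ValueError("need at least two groups per level for variance components")
    groups = sub[[country_col, school_col]].to_numpy()
    X = sub[fixed]
    y = sub[outcome].to_numpy(dtype=float)
    if link == "logit":
        est = ThreeLevelLogisticRegression(**settings)
    elif link == "identity":
        # linear fits only understand the generic optimizer settings
        est = ThreeLevelLinearRegression(
            **{k: v for k, v in settings.items() if k in ("max_iter", "tol")}
        )
    else:
        raise ValueError(f"unknown link {link!r}")
    est.fit(X, y, groups)
    return est.result_
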