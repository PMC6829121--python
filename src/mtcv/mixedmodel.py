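"""REML fitting of univariate and bivariate GBLUP mixed models.

Both models have an intercept as the only fixed effect and a single random
genetic effect with known covariance structure ``K`` (the GRM)::

    univariate:  y = mu + u + e,   u ~ N(0, g K),      e ~ N(0, r I)
    bivariate :  y = mu + u + e,   u ~ N(0, G (x) K),  e ~ N(0, R (x) I)

The workhorse is the eigendecomposition ``K = Q L Q'``: rotating the data by
``Q'`` de-correlates lines, so each REML objective evaluation costs O(n)
2x2-matrix operations after a one-time O(n^3) decomposition. The univariate
model profiles out the intercept and total variance, leaving a 1-D search
over heritability; the bivariate model optimizes the six free (co)variance
parameters on a Cholesky-log scale (which keeps G and R positive definite by
construction) with quasi-Newton iterations from a moment-based start.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg, optimize

_LOG2PI = math.log(2.0 * math.pi)
#: relative log-likelihood change declared converged
REML_TOL = 1e-8
#: heritability this close to 0 or 1 is flagged as a boundary estimate
BOUNDARY_TOL = 1e-4


class MixedModelError(ValueError):
    """Invalid input to a mixed-model fit."""


@dataclass
class UnivariateFit:
    """REML estimates of the single-trait GBLUP model on the training lines."""

    mu_hat: float
    g_hat: float
    r_hat: float
    u_hat_o: np.ndarray
    loglik_reml: float
    boundary: bool = False

    @property
    def h2_hat(self) -> float:
        return self.g_hat / (self.g_hat + self.r_hat)

    def to_record(self) -> dict:
        return {
            "mu_hat": self.mu_hat, "g_hat": self.g_hat, "r_hat": self.r_hat,
            "loglik_reml": self.loglik_reml, "boundary": self.boundary,
        }


@dataclass
class BivariateFit:
    """REML estimates of the two-trait GBLUP model on the training lines.

    ``u_hat_o`` is (n_train, 2): column 0 is the focal trait.
    """

    mu_hat: np.ndarray
    G_hat: np.ndarray
    R_hat: np.ndarray
    u_hat_o: np.ndarray
    loglik_reml: float
    converged: bool = True
    boundary: bool = False

    def to_record(self) -> dict:
        g, r = self.G_hat, self.R_hat
        return {
            "mu1": self.mu_hat[0], "mu2": self.mu_hat[1],
            "g11": g[0, 0], "g12": g[0, 1], "g22": g[1, 1],
            "r11": r[0, 0], "r12": r[0, 1], "r22": r[1, 1],
            "loglik_reml": self.loglik_reml,
            "converged": self.converged, "boundary": self.boundary,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=1))


def _eig_psd(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, Q = linalg.eigh(K)
    if lam[0] <= 1e-12:
        raise MixedModelError("K is not positive definite; jitter it first")
    return lam, Q


def fit_univariate_reml(y: np.ndarray, K: np.ndarray,
                        eig: tuple[np.ndarray, np.ndarray] | None = None) -> UnivariateFit:
    """REML fit of the univariate GBLUP model by 1-D profile search.

    ``eig`` may carry a precomputed ``eigh(K)`` (shared across traits and
    fits on the same training partition).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise MixedModelError("need at least 10 training lines")
    if not np.all(np.isfinite(y)):
        raise MixedModelError("non-finite phenotypes")
    if np.var(y) == 0:
        raise MixedModelError("phenotype has zero variance")
    lam, Q = eig if eig is not None else _eig_psd(np.asarray(K, dtype=float))
    ys = Q.T @ y
    xs = Q.T @ np.ones(n)

    def negloglik(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        w = 1.0 / d
        xx = float(np.sum(xs * xs * w))
        mu = float(np.sum(xs * ys * w)) / xx
        resid = ys - xs * mu
        rss = float(np.sum(resid * resid * w))
        s2 = rss / (n - 1)
        return 0.5 * (float(np.sum(np.log(d))) + math.log(xx) + (n - 1) * math.log(s2))

    # coarse grid then local polish; the profile is cheap and occasionally multimodal
    grid = np.linspace(1e-6, 1.0 - 1e-6, 41)
    vals = [negloglik(h) for h in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    h2 = float(res.x)
    obj = float(res.fun)
    # a boundary value at least as good as the interior optimum (e.g. a flat
    # profile when K = I) is reported as a boundary estimate
    for h2_edge in (1e-6, 1.0 - 1e-6):
        if negloglik(h2_edge) <= obj + 1e-9:
            h2, obj = h2_edge, float(negloglik(h2_edge))
            break

    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    xx = float(np.sum(xs * xs * w))
    mu = float(np.sum(xs * ys * w)) / xx
    resid = ys - xs * mu
    s2 = float(np.sum(resid * resid * w)) / (n - 1)
    g_hat = h2 * s2
    r_hat = (1.0 - h2) * s2
    u_rot = (h2 * lam * w) * resid
    u_hat = Q @ u_rot
    loglik = -obj - 0.5 * (n - 1) * (1.0 + _LOG2PI)
    boundary = h2 < BOUNDARY_TOL or h2 > 1.0 - BOUNDARY_TOL
    return UnivariateFit(mu_hat=mu, g_hat=g_hat, r_hat=r_hat, u_hat_o=u_hat,
                         loglik_reml=loglik, boundary=boundary)


# ---------------------------------------------------------------------------
# bivariate model


def _theta_to_cov(theta: np.ndarray) -> np.ndarray:
    """(a, b, c) -> L L' with L = [[e^a, 0], [b, e^c]] (always PD)."""
    la, b, lc = theta
    e_a = math.exp(la)
    e_c = math.exp(lc)
    return np.array([[e_a * e_a, e_a * b], [e_a * b, b * b + e_c * e_c]])


def _cov_to_theta(C: np.ndarray) -> np.ndarray:
    L = linalg.cholesky(C, lower=True)
    return np.array([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])


def _biv_profile(theta: np.ndarray, lam: np.ndarray, xs: np.ndarray, Ys: np.ndarray):
    """Profiled REML pieces for one (G, R); returns (obj, mu, inverse pieces)."""
    G = _theta_to_cov(theta[:3])
    R = _theta_to_cov(theta[3:])
    v11 = lam * G[0, 0] + R[0, 0]
    v12 = lam * G[0, 1] + R[0, 1]
    v22 = lam * G[1, 1] + R[1, 1]
    det = v11 * v22 - v12 * v12
    if det.min() <= 0 or v11.min() <= 0:
        return None
    iv11 = v22 / det
    iv12 = -v12 / det
    iv22 = v11 / det
    x2 = xs * xs
    C11 = float(np.sum(x2 * iv11))
    C12 = float(np.sum(x2 * iv12))
    C22 = float(np.sum(x2 * iv22))
    detC = C11 * C22 - C12 * C12
    if detC <= 0:
        return None
    y0, y1 = Ys[:, 0], Ys[:, 1]
    b0 = float(np.sum(xs * (iv11 * y0 + iv12 * y1)))
    b1 = float(np.sum(xs * (iv12 * y0 + iv22 * y1)))
    mu0 = (C22 * b0 - C12 * b1) / detC
    mu1 = (C11 * b1 - C12 * b0) / detC
    r0 = y0 - xs * mu0
    r1 = y1 - xs * mu1
    quad = float(np.sum(iv11 * r0 * r0 + 2.0 * iv12 * r0 * r1 + iv22 * r1 * r1))
    obj = 0.5 * (float(np.sum(np.log(det))) + math.log(detC) + quad)
    return obj, np.array([mu0, mu1]), (iv11, iv12, iv22, r0, r1), G, R


def _biv_objective(theta, lam, xs, Ys):
    out = _biv_profile(theta, lam, xs, Ys)
    return 1e10 if out is None else out[0]


_THETA_BOUNDS = [(-12.0, 6.0), (-60.0, 60.0), (-12.0, 6.0)] * 2


def fit_bivariate_reml(Y: np.ndarray, K: np.ndarray,
                       eig: tuple[np.ndarray, np.ndarray] | None = None,
                       maxiter: int = 500) -> BivariateFit:
    """REML fit of the two-trait GBLUP model.

    Six (co)variance parameters on the Cholesky-log scale, L-BFGS-B from a
    moment start (``G0 = R0 = 0.5 * cov(Y)``) with a diagonal-only restart
    if the first attempt fails; non-convergence is flagged, not raised.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise MixedModelError("Y must be (n, 2)")
    n = Y.shape[0]
    if n < 20:
        raise MixedModelError("need at least 20 training lines")
    if not np.all(np.isfinite(Y)):
        raise MixedModelError("non-finite phenotypes")
    lam, Q = eig if eig is not None else _eig_psd(np.asarray(K, dtype=float))
    Ys = Q.T @ Y
    xs = Q.T @ np.ones(n)

    S = np.cov(Y.T)
    S = S + 1e-8 * np.trace(S) / 2.0 * np.eye(2)  # guard collinear traits
    starts = [np.concatenate([_cov_to_theta(0.5 * S)] * 2),
              np.concatenate([_cov_to_theta(0.5 * np.diag(np.diag(S)))] * 2)]

    best = None
    for k, theta0 in enumerate(starts):
        res = optimize.minimize(
            _biv_objective, theta0, args=(lam, xs, Ys), method="L-BFGS-B",
            bounds=_THETA_BOUNDS,
            options={"maxiter": maxiter, "ftol": REML_TOL * 1e-2, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if k == 0 and res.success:
            break
    res = best

    out = _biv_profile(res.x, lam, xs, Ys)
    if out is None:  # pragma: no cover - bounds keep parameters feasible
        raise MixedModelError("bivariate REML objective undefined at optimum")
    obj, mu, (iv11, iv12, iv22, r0, r1), G, R = out
    if linalg.eigvalsh(R)[0] < 1e-12:
        raise MixedModelError("estimated residual covariance is singular")

    w0 = iv11 * r0 + iv12 * r1
    w1 = iv12 * r0 + iv22 * r1
    u0 = lam * (G[0, 0] * w0 + G[0, 1] * w1)
    u1 = lam * (G[0, 1] * w0 + G[1, 1] * w1)
    u_hat = Q @ np.column_stack([u0, u1])

    h2 = np.diag(G) / (np.diag(G) + np.diag(R))
    rho_g = G[0, 1] / math.sqrt(G[0, 0] * G[1, 1])
    rho_r = R[0, 1] / math.sqrt(R[0, 0] * R[1, 1])
    boundary = bool(
        np.any(h2 < BOUNDARY_TOL) or np.any(h2 > 1.0 - BOUNDARY_TOL)
        or abs(rho_g) > 1.0 - BOUNDARY_TOL or abs(rho_r) > 1.0 - BOUNDARY_TOL
    )
    loglik = -obj - (n - 1) * _LOG2PI - 0.0  # constants for the 2(n-1) REML contrasts
    return BivariateFit(mu_hat=mu, G_hat=G, R_hat=R, u_hat_o=u_hat,
                        loglik_reml=loglik, converged=bool(res.success),
                        boundary=boundary)


def blup_with_fixed_components(Y: np.ndarray, K: np.ndarray,
                               G: np.ndarray, R: np.ndarray,
                               eig: tuple[np.ndarray, np.ndarray] | None = None,
                               ) -> BivariateFit:
    """BLUPs and GLS intercepts at supplied (G, R) — no optimization.

    Used for oracle runs (true covariances) and for consistency checks
    against :func:`fit_bivariate_reml` at that fit's own estimates.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise MixedModelError("Y must be (n, 2)")
    n = Y.shape[0]
    lam, Q = eig if eig is not None else _eig_psd(np.asarray(K, dtype=float))
    Ys = Q.T @ Y
    xs = Q.T @ np.ones(n)
    theta = np.concatenate([_cov_to_theta(np.asarray(G, float)),
                            _cov_to_theta(np.asarray(R, float))])
    out = _biv_profile(theta, lam, xs, Ys)
    if out is None:
        raise MixedModelError("supplied G/R give an indefinite marginal covariance")
    obj, mu, (iv11, iv12, iv22, r0, r1), G_, R_ = out
    w0 = iv11 * r0 + iv12 * r1
    w1 = iv12 * r0 + iv22 * r1
    u0 = lam * (G_[0, 0] * w0 + G_[0, 1] * w1)
    u1 = lam * (G_[0, 1] * w0 + G_[1, 1] * w1)
    u_hat = Q @ np.column_stack([u0, u1])
    loglik = -obj - (n - 1) * _LOG2PI
    return BivariateFit(mu_hat=mu, G_hat=G_, R_hat=R_, u_hat_o=u_hat,
                        loglik_reml=loglik, converged=True)


def univariate_blup_with_fixed(y: np.ndarray, K: np.ndarray, g: float, r: float,
                               eig: tuple[np.ndarray, np.ndarray] | None = None,
                               ) -> UnivariateFit:
    """Univariate analogue of :func:`blup_with_fixed_components`."""
    y = np.asarray(y, dtype=float)
    n = y.size
    lam, Q = eig if eig is not None else _eig_psd(np.asarray(K, dtype=float))
    ys = Q.T @ y
    xs = Q.T @ np.ones(n)
    d = g * lam + r
    w = 1.0 / d
    mu = float(np.sum(xs * ys * w)) / float(np.sum(xs * xs * w))
    resid = ys - xs * mu
    u_hat = Q @ ((g * lam * w) * resid)
    loglik = -0.5 * (float(np.sum(np.log(d))) + math.log(float(np.sum(xs * xs * w)))
                     + float(np.sum(resid * resid * w))) - 0.5 * (n - 1) * _LOG2PI
    return UnivariateFit(mu_hat=mu, g_hat=float(g), r_hat=float(r),
                         u_hat_o=u_hat, loglik_reml=loglik)
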