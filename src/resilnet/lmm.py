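"""Gaussian linear mixed models with independent random-intercept factors.

Implements the model

    y = X beta + sum_f Z_f b_f + e,   b_f ~ N(0, sigma2_f I),  e ~ N(0, sigma2_e I)

with an arbitrary number of independent random-intercept factors (here:
subject and clinical status).  Estimation maximizes the likelihood (ML) or
restricted likelihood (REML) profiled over ``beta`` and ``sigma2_e``, leaving
only the variance ratios ``gamma_f = sigma2_f / sigma2_e`` to a bounded
derivative-free optimizer.  All per-evaluation linear algebra is reduced to
the random-effect dimension q = sum_f q_f via the Woodbury identity

    V0^-1 = I - Z A^-1 Z',     A = diag(1/gamma) + Z'Z,

so a single likelihood evaluation costs O(q^3 + q^2 p) regardless of the
number of observations, which makes parametric-bootstrap refitting at scale
practical.

Also provided: the conditional AIC (cAIC) with effective degrees of freedom
rho = trace of the hat matrix mapping observations to conditional fitted
values at the plugged-in variance estimates, the marginal R-squared
(fixed-effect variance share), and simulation from a fitted model for
parametric bootstrapping.  The boundary behaviour is exact: a variance
ratio optimized to zero drops its factor, and with all ratios zero the fit,
rho and cAIC reduce to ordinary least squares and the linear-model AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotrs

__all__ = [
    "LmmWorkspace",
    "LmmFit",
    "LmmError",
    "RankError",
    "ConvergenceError",
    "conditional_aic",
    "marginal_r2",
    "simulate_from_fit",
]

_LOG2PI = math.log(2.0 * math.pi)
_GAMMA_TINY = 1e-12  # ratios below this are treated as exactly zero


class LmmError(RuntimeError):
    """Generic mixed-model failure."""


class RankError(LmmError):
    """Design matrix (or penalized system) is rank deficient."""


class ConvergenceError(LmmError):
    """Operation requires a converged fit."""


class LmmWorkspace:
    """Precomputed cross-products for repeated fits on a fixed design.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix.
    factors : sequence of integer-coded grouping vectors, one per random
        intercept factor; codes must be 0..q_f-1.

    The workspace is reused across bootstrap replicates: only the
    y-dependent cross products are recomputed per outcome vector.
    """

    def __init__(self, X: np.ndarray, factors: Sequence[np.ndarray]):
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim != 2:
            raise LmmError("X must be 2-D")
        self.X = X
        self.n, self.p = X.shape
        self.factors = [np.asarray(f, dtype=np.intp) for f in factors]
        for f in self.factors:
            if f.shape != (self.n,):
                raise LmmError("each factor must have one code per observation")
            if f.min() < 0:
                raise LmmError("factor codes must be nonnegative")
        self.q_f = [int(f.max()) + 1 for f in self.factors]
        self.q = int(sum(self.q_f))
        offs = np.cumsum([0] + self.q_f)
        self._block = [np.arange(offs[i], offs[i + 1]) for i in range(len(self.factors))]
        # dense Z'Z, Z'X assembled by scatter-adds (Z is an indicator matrix)
        ZtZ = np.zeros((self.q, self.q))
        ZtX = np.zeros((self.q, self.p))
        cols = [f + offs[i] for i, f in enumerate(self.factors)]
        for ci in cols:
            np.add.at(ZtX, ci, X)
            for cj in cols:
                np.add.at(ZtZ, (ci, cj), 1.0)
        self.ZtZ = ZtZ
        self.ZtX = ZtX
        self.XtX = X.T @ X
        self._cols = cols
        self._pat_cache: dict = {}
        if np.linalg.matrix_rank(self.XtX) < self.p:
            raise RankError("fixed-effect design matrix is rank deficient")

    # -- y-dependent cross products ------------------------------------
    def cross_y(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        Zty = np.zeros(self.q)
        for ci in self._cols:
            np.add.at(Zty, ci, y)
        return Zty, self.X.T @ y, float(y @ y)

    # -- profiled objective --------------------------------------------
    def _active(self, gamma):
        return tuple(i for i, g in enumerate(gamma) if g > _GAMMA_TINY)

    def _pattern(self, active):
        """Cached contiguous submatrices for a subset of active factors."""
        cached = self._pat_cache.get(active)
        if cached is None:
            idx = np.concatenate([self._block[i] for i in active])
            ZtZs = np.ascontiguousarray(self.ZtZ[np.ix_(idx, idx)])
            U = np.ascontiguousarray(self.ZtX[idx])
            qa = len(idx)
            diag_flat = np.arange(qa) * (qa + 1)
            cached = (idx, ZtZs, U, diag_flat)
            self._pat_cache[active] = cached
        return cached

    def _penalized_system(self, gamma, active):
        idx, ZtZs, _, diag_flat = self._pattern(active)
        A = ZtZs.copy()
        d = np.concatenate([np.full(self.q_f[i], 1.0 / gamma[i]) for i in active])
        A.ravel()[diag_flat] += d
        L, info = dpotrf(A, lower=1, overwrite_a=1, clean=0)
        if info != 0:  # pragma: no cover
            raise RankError("penalized random-effect system not positive definite")
        logdetA = 2.0 * np.log(np.diagonal(L)).sum()
        logdetV0 = logdetA + sum(self.q_f[i] * math.log(gamma[i]) for i in active)
        return idx, L, logdetV0

    def _gls(self, gamma, cy, reml: bool):
        """Profiled -2 log-likelihood and GLS quantities at variance ratios gamma."""
        Zty, Xty, yty = cy
        active = self._active(gamma)
        if active:
            idx, L, logdetV0 = self._penalized_system(gamma, active)
            U = self._pattern(active)[2]
            rhs = np.concatenate([U, Zty[idx, None]], axis=1)
            S, info = dpotrs(L, rhs, lower=1, overwrite_b=1)
            if info != 0:  # pragma: no cover
                raise RankError("penalized solve failed")
            XtPX = self.XtX - U.T @ S[:, : self.p]
            XtPy = Xty - U.T @ S[:, self.p]
            ytPy = yty - Zty[idx] @ S[:, self.p]
        else:
            XtPX, XtPy, ytPy, logdetV0 = self.XtX, Xty, yty, 0.0
        B, info = dpotrf(XtPX, lower=1)
        if info != 0:
            raise RankError("X'V^-1 X not positive definite")
        Bf = (B, True)
        beta, info = dpotrs(B, XtPy, lower=1)
        rPr = max(ytPy - beta @ XtPy, 1e-300)
        n, p = self.n, self.p
        if reml:
            sigma2 = rPr / (n - p)
            logdetB = 2.0 * np.log(np.diag(Bf[0])).sum()
            neg2ll = (n - p) * (_LOG2PI + math.log(sigma2) + 1.0) + logdetV0 + logdetB
        else:
            sigma2 = rPr / n
            neg2ll = n * (_LOG2PI + math.log(sigma2) + 1.0) + logdetV0
        return {
            "neg2ll": float(neg2ll),
            "beta": beta,
            "sigma2_e": float(sigma2),
            "XtPX": XtPX,
            "Bf": Bf,
            "logdetV0": logdetV0,
        }

    def _start_ratios(self, cy):
        """Method-of-moments starting values from OLS residual group means."""
        Zty, Xty, yty = cy
        try:
            beta = np.linalg.solve(self.XtX, Xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(self.X, np.zeros(self.n), rcond=None)[0]
        rss = max(yty - beta @ Xty, 1e-12)
        s2 = rss / max(self.n - self.p, 1)
        start = []
        for i, f in enumerate(self.factors):
            rZ = Zty[self._block[i]] - self.ZtX[self._block[i]] @ beta
            cnt = np.bincount(f, minlength=self.q_f[i]).astype(float)
            means = rZ / np.maximum(cnt, 1.0)
            v = float(np.var(means, ddof=1)) if self.q_f[i] > 1 else 0.0
            start.append(min(max(v / s2, 0.05), 5.0))
        return np.asarray(start)

    def fit(
        self,
        y: np.ndarray,
        criterion: str = "ML",
        start: np.ndarray | None = None,
        xatol: float = 1e-6,
        fatol: float = 1e-9,
    ) -> "LmmFit":
        """Maximize the profiled (restricted) likelihood over variance ratios.

        ``start`` optionally warm-starts the optimizer with variance ratios
        (e.g. from the generating fit during bootstrapping).
        """
        criterion = criterion.upper()
        if criterion not in ("ML", "REML"):
            raise LmmError("criterion must be 'ML' or 'REML'")
        reml = criterion == "REML"
        y = np.asarray(y, dtype=float)
        cy = self.cross_y(y)
        nf = len(self.factors)
        if nf == 0:
            res_success = True
            gamma = np.zeros(0)
        else:
            theta0 = np.sqrt(start if start is not None else self._start_ratios(cy))

            def objective(theta):
                return self._gls(theta**2, cy, reml)["neg2ll"]

            res = optimize.minimize(
                objective,
                np.asarray(theta0, dtype=float),
                method="Nelder-Mead",
                bounds=[(0.0, 1e3)] * nf,
                options={"xatol": xatol, "fatol": fatol, "maxiter": 400 * nf},
            )
            gamma = res.x**2
            gamma[gamma <= _GAMMA_TINY] = 0.0
            res_success = bool(res.success)
        sol = self._gls(gamma, cy, reml)
        cov_beta = sol["sigma2_e"] * cho_solve(
            sol["Bf"], np.eye(self.p), check_finite=False
        )
        return LmmFit(
            workspace=self,
            y=y,
            criterion=criterion,
            gamma=gamma,
            beta=sol["beta"],
            cov_beta=cov_beta,
            sigma2_e=sol["sigma2_e"],
            loglik=-0.5 * sol["neg2ll"],
            converged=res_success,
        )

    def evaluate(self, gamma: np.ndarray, y: np.ndarray, criterion: str = "ML") -> "LmmFit":
        """Profile beta and sigma2_e at *fixed* variance ratios (no optimization).

        Useful for boundary identities (all ratios zero reduces to ordinary
        least squares) and for tracing cAIC effective df over a ratio grid.
        """
        reml = criterion.upper() == "REML"
        y = np.asarray(y, dtype=float)
        gamma = np.asarray(gamma, dtype=float)
        sol = self._gls(gamma, self.cross_y(y), reml)
        cov_beta = sol["sigma2_e"] * cho_solve(
            sol["Bf"], np.eye(self.p), check_finite=False
        )
        return LmmFit(
            workspace=self, y=y, criterion=criterion.upper(), gamma=gamma,
            beta=sol["beta"], cov_beta=cov_beta, sigma2_e=sol["sigma2_e"],
            loglik=-0.5 * sol["neg2ll"], converged=True,
        )

    # -- conditional quantities ----------------------------------------
    def conditional_parts(self, gamma, y, beta=None):
        """Conditional (BLUP) random effects and fitted values at fixed gamma.

        Returns ``(fitted, b_hat_blocks)``; ``beta`` defaults to the GLS
        solution for this y.  The map y -> fitted is linear at fixed gamma,
        which is what the cAIC effective degrees of freedom trace out.
        """
        cy = self.cross_y(y)
        sol = self._gls(gamma, cy, reml=False)
        if beta is None:
            beta = sol["beta"]
        active = self._active(gamma)
        fitted = self.X @ beta
        b_blocks = [np.zeros(qf) for qf in self.q_f]
        if active:
            idx, L, _ = self._penalized_system(gamma, active)
            resid_cross = cy[0][idx] - self.ZtX[idx] @ beta
            b = cho_solve((L, True), resid_cross, check_finite=False)
            off = 0
            for i in active:
                qf = self.q_f[i]
                b_blocks[i] = b[off : off + qf]
                fitted = fitted + b_blocks[i][self.factors[i]]
                off += qf
        return fitted, b_blocks

    def effective_df(self, gamma) -> float:
        """Trace of the observation->conditional-fitted hat matrix.

        rho = p + tr(A^-1 Z'Z) - tr(A^-1 U B^-1 (Z'V0^-1 X)'), computed
        entirely in the q-dimensional random-effect space.
        """
        active = self._active(gamma)
        if not active:
            return float(self.p)
        idx, L, _ = self._penalized_system(gamma, active)
        ZtZs = self.ZtZ[np.ix_(idx, idx)]
        U = self.ZtX[idx]
        M = cho_solve((L, True), U, check_finite=False)  # A^-1 U
        tr1 = np.trace(cho_solve((L, True), ZtZs, check_finite=False))
        XtPX = self.XtX - U.T @ M
        Bf = cho_factor(XtPX, lower=True, check_finite=False)
        MB = cho_solve(Bf, M.T, check_finite=False).T  # A^-1 U B^-1
        ZV0X = U - ZtZs @ M  # Z' V0^-1 X
        tr2 = float(np.sum(MB * ZV0X))
        return float(self.p + tr1 - tr2)


@dataclass
class LmmFit:
    """A fitted mixed model (coefficients, variance components, likelihood)."""

    workspace: LmmWorkspace
    y: np.ndarray
    criterion: str
    gamma: np.ndarray          # variance ratios sigma2_f / sigma2_e
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_e: float
    loglik: float
    converged: bool
    terms: tuple[str, ...] | None = None
    spec: object = None
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.workspace.n

    @property
    def p(self) -> int:
        return self.workspace.p

    @property
    def variance_components(self) -> np.ndarray:
        """Per-factor random-intercept variances sigma2_f."""
        return self.gamma * self.sigma2_e

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.workspace.X @ self.beta

    def conditional_fitted(self) -> np.ndarray:
        fitted, _ = self.workspace.conditional_parts(self.gamma, self.y, self.beta)
        return fitted


def conditional_aic(fit: LmmFit) -> float:
    """Conditional AIC: -2 * conditional log-likelihood + 2 * (rho + 1).

    The conditional likelihood evaluates the Gaussian residual density at
    the conditional (BLUP) fitted values; rho is the effective number of
    parameters (trace of the conditional hat matrix) and the +1 counts the
    residual variance.  With all variance ratios zero this is exactly the
    linear-model AIC with p + 1 parameters.
    """
    if not fit.converged:
        raise ConvergenceError("cAIC requires a converged fit")
    ws = fit.workspace
    fitted = fit.conditional_fitted()
    rss = float(np.sum((fit.y - fitted) ** 2))
    s2 = fit.sigma2_e
    cond_ll = -0.5 * (ws.n * (_LOG2PI + math.log(s2)) + rss / s2)
    rho = ws.effective_df(fit.gamma)
    return float(-2.0 * cond_ll + 2.0 * (rho + 1.0))


def marginal_r2(fit: LmmFit) -> float:
    """Fixed-effect variance share: var(X beta) / (var(X beta) + sum sigma2_f + sigma2_e)."""
    if not fit.converged:
        raise ConvergenceError("marginal R2 requires a converged fit")
    var_fixed = float(np.var(fit.fitted_fixed, ddof=1))
    total = var_fixed + float(fit.variance_components.sum()) + fit.sigma2_e
    if total <= 0:
        raise LmmError("total variance is zero")
    return var_fixed / total


def simulate_from_fit(fit: LmmFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a new outcome vector from the fitted model's parameters."""
    ws = fit.workspace
    y = ws.X @ fit.beta + rng.normal(0.0, math.sqrt(fit.sigma2_e), ws.n)
    for i, f in enumerate(ws.factors):
        sd = math.sqrt(fit.gamma[i] * fit.sigma2_e)
        if sd > 0:
            y = y + rng.normal(0.0, sd, ws.q_f[i])[f]
    return y
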