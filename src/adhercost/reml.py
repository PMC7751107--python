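"""REML estimation for a Gaussian mixed model with many identity-penalty blocks.

The model is

    y = X beta + sum_j Z_j b_j + Z_g u + e,
    b_j ~ N(0, sigma_j^2 I),  u ~ N(0, sigma_g^2 I),  e ~ N(0, sigma^2 I),

where the ``Z_j`` are whitened wiggly spline blocks (one variance per smooth)
and ``Z_g`` is the patient (group) intercept indicator.  The restricted
likelihood is profiled over ``sigma^2`` and maximized over the log variance
ratios ``rho_j = log(sigma_j^2 / sigma^2)`` with a quasi-Newton optimizer and
fixed deterministic starting values, so the fit is reproducible bit for bit.

All per-evaluation algebra runs on precomputed cross-products; the group
block of the working matrix is diagonal and is eliminated by a Schur
complement, so the cost per evaluation is O(G q_s^2) rather than O((G+q_s)^3)
for G groups and q_s total wiggly columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MixedModelREML", "REMLResult", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class REMLResult:
    beta: np.ndarray
    se_beta: np.ndarray
    gamma: np.ndarray            # variance ratios, one per block (+ group last)
    sigma2: float                # residual variance
    b_smooth: np.ndarray         # BLUPs of all wiggly coefficients
    b_group: np.ndarray          # BLUPs of group intercepts
    cov_theta: np.ndarray        # sigma2 * C^{-1} over [beta, b_smooth] coords
    edf_coef: np.ndarray         # per-coefficient edf over [beta, b_smooth]
    edf_group: float             # summed edf of the group intercepts
    deviance: float              # -2 restricted log-likelihood (profiled, no const)
    n_iter: int
    trace: list = field(default_factory=list)
    converged: bool = True


class MixedModelREML:
    """REML fit of the block-variance mixed model described in the module docstring.

    Parameters
    ----------
    X : (n, p) fixed-effects design, full column rank.
    y : (n,) response.
    group : (n,) integer codes 0..G-1 (random-intercept grouping).
    blocks : list of (n, q_j) arrays, the whitened random blocks; may be empty.
    """

    def __init__(self, X, y, group, blocks):
        X = np.asarray(X, dtype=float)
        # standardize fixed-effect columns to unit norm: the design mixes
        # dummy and euro-scale columns, and the Schur subtractions below lose
        # the small directions otherwise; estimates are unscaled on output
        self.col_scale = np.sqrt((X ** 2).sum(axis=0))
        self.col_scale[self.col_scale == 0] = 1.0
        self.X = X / self.col_scale
        self.y = np.asarray(y, dtype=float)
        self.g = np.asarray(group)
        self.blocks = [np.asarray(b, dtype=float) for b in blocks]
        self.n, self.p = self.X.shape
        self.G = int(self.g.max()) + 1 if self.n else 0
        self.block_sizes = [b.shape[1] for b in self.blocks]
        self.qs = int(sum(self.block_sizes))
        self.nb = len(self.blocks)

        Zs = np.hstack(self.blocks) if self.blocks else np.zeros((self.n, 0))
        self.Zs = Zs
        U = np.column_stack([self.X, self.y])
        self.d_g = np.bincount(self.g, minlength=self.G).astype(float)
        self.ZgU = np.zeros((self.G, self.p + 1))
        np.add.at(self.ZgU, self.g, U)
        self.ZgZs = np.zeros((self.G, self.qs))
        np.add.at(self.ZgZs, self.g, Zs)
        self.ZsZs = Zs.T @ Zs
        self.ZsU = Zs.T @ U
        self.UtU = U.T @ U
        # column index of each block inside Zs
        idx = np.concatenate([[j] * q for j, q in enumerate(self.block_sizes)]) \
            if self.qs else np.zeros(0, dtype=int)
        self.col_block = idx.astype(int)

    # ------------------------------------------------------------------ core
    def _pieces(self, gamma: np.ndarray):
        """Working quantities for variance ratios ``gamma`` (blocks + group)."""
        g_s = gamma[:-1][self.col_block] if self.qs else np.zeros(0)
        g_g = gamma[-1]
        w = np.sqrt(g_s)
        a = 1.0 + g_g * self.d_g                         # diagonal group block
        log_det = float(np.log(a).sum())

        K = self.ZgZs * w[None, :]                       # G x qs, scaled
        Bg = np.sqrt(g_g) * self.ZgU                     # G x (p+1)
        S = np.eye(self.qs) + (w[:, None] * self.ZsZs * w[None, :]) \
            - g_g * (K.T @ (K / a[:, None]))
        Bs = w[:, None] * self.ZsU
        rhs_s = Bs - np.sqrt(g_g) * (K.T @ (Bg / a[:, None]))
        if self.qs:
            cS = cho_factor(S, lower=True)
            log_det += 2.0 * float(np.log(np.diag(cS[0])).sum())
            xs = cho_solve(cS, rhs_s)
        else:
            cS, xs = None, rhs_s
        # U' V0^-1 U = U'U - B' M^-1 B  with B = [Bg; Bs] via Schur elimination
        xg = (Bg - (np.sqrt(g_g) * K @ xs if self.qs else 0.0)) / a[:, None]
        UVU = self.UtU - (Bg.T @ xg + (Bs.T @ xs if self.qs else 0.0))
        return log_det, UVU

    def deviance(self, rho: np.ndarray) -> float:
        """Profiled -2 restricted log-likelihood at log variance ratios rho."""
        gamma = np.exp(np.asarray(rho, dtype=float))
        log_det, UVU = self._pieces(gamma)
        XtViX = UVU[:-1, :-1]
        XtViy = UVU[:-1, -1]
        ytViy = UVU[-1, -1]
        cX = cho_factor(XtViX, lower=True)
        beta = cho_solve(cX, XtViy)
        r = float(ytViy - XtViy @ beta)
        log_det_x = 2.0 * float(np.log(np.diag(cX[0])).sum())
        return (self.n - self.p) * np.log(max(r, 1e-300)) + log_det + log_det_x

    # ------------------------------------------------------------------- fit
    def fit(self, rho0: float = np.log(0.1), bounds: tuple[float, float] = (-18.0, 12.0),
            fixed_zero: list[int] | None = None, max_iter: int = 200,
            tol: float = 1e-10) -> REMLResult:
        """Maximize the restricted likelihood.

        ``fixed_zero`` lists block indices (into blocks + [group]) whose
        variance is pinned at (numerically) zero — used for the linear-limit
        mode where all smoothing variances are switched off.
        """
        n_par = self.nb + 1
        fixed_zero = set(fixed_zero or [])
        free = [j for j in range(n_par) if j not in fixed_zero]
        pinned = np.full(n_par, -36.0)          # gamma ~ 2e-16: numerically zero

        trace: list[tuple[np.ndarray, float]] = []

        def unpack(rho_free: np.ndarray) -> np.ndarray:
            rho = pinned.copy()
            rho[free] = rho_free
            return rho

        def fun(rho_free: np.ndarray) -> float:
            dev = self.deviance(unpack(rho_free))
            trace.append((rho_free.copy(), dev))
            return dev

        x0 = np.full(len(free), rho0)
        if len(free) == 1:
            # single variance ratio: golden-section/Brent to high precision
            sres = optimize.minimize_scalar(
                lambda r: fun(np.array([r])), bounds=bounds, method="bounded",
                options={"xatol": 1e-10, "maxiter": max_iter})
            res = optimize.OptimizeResult(
                x=np.array([sres.x]), fun=sres.fun, nit=int(sres.nfev),
                success=bool(sres.success), message=str(sres.message))
        else:
            res = optimize.minimize(
                fun, x0, method="L-BFGS-B",
                bounds=[bounds] * len(free),
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
            )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise ConvergenceError(
                f"REML optimizer did not converge: {res.message}", trace)
        rho_hat = unpack(res.x)
        return self._finalize(np.exp(rho_hat), res, trace)

    # -------------------------------------------------------------- finalize
    def _finalize(self, gamma: np.ndarray, res, trace) -> REMLResult:
        log_det, UVU = self._pieces(gamma)
        XtViX = UVU[:-1, :-1]
        XtViy = UVU[:-1, -1]
        ytViy = UVU[-1, -1]
        cX = cho_factor(XtViX, lower=True)
        beta_v = cho_solve(cX, XtViy)
        r = float(ytViy - XtViy @ beta_v)
        sigma2 = r / (self.n - self.p)

        # mixed-model equations over [beta, b_smooth, u_group]
        p, qs, G = self.p, self.qs, self.G
        g_s = gamma[:-1][self.col_block] if qs else np.zeros(0)
        g_g = gamma[-1]
        m = p + qs + G
        C = np.zeros((m, m))
        XtX = self.UtU[:-1, :-1]
        Xty = self.UtU[:-1, -1]
        C[:p, :p] = XtX
        C[:p, p:p + qs] = self.ZsU[:, :-1].T
        C[p:p + qs, :p] = self.ZsU[:, :-1]
        C[p:p + qs, p:p + qs] = self.ZsZs + np.diag(1.0 / np.maximum(g_s, 1e-300))
        C[:p, p + qs:] = self.ZgU[:, :-1].T
        C[p + qs:, :p] = self.ZgU[:, :-1]
        C[p:p + qs, p + qs:] = self.ZgZs.T
        C[p + qs:, p:p + qs] = self.ZgZs
        C[p + qs:, p + qs:] = np.diag(self.d_g + 1.0 / max(g_g, 1e-300))
        rhs = np.concatenate([Xty, self.ZsU[:, -1], self.ZgU[:, -1]])
        cC = cho_factor(C, lower=True)
        theta = cho_solve(cC, rhs)
        Cinv = cho_solve(cC, np.eye(m))

        # per-coefficient effective degrees of freedom: diag(C^{-1} C0)
        C0 = C.copy()
        if qs:
            C0[p:p + qs, p:p + qs] = self.ZsZs
        C0[p + qs:, p + qs:] = np.diag(self.d_g)
        edf_all = np.einsum("ij,ji->i", Cinv, C0)

        # undo the internal column standardization of X
        scale = self.col_scale
        beta = theta[:p] / scale
        se_beta = np.sqrt(sigma2 * np.diag(Cinv)[:p]) / scale
        Cinv[:p, :] /= scale[:, None]
        Cinv[:, :p] /= scale[None, :]
        return REMLResult(
            beta=beta,
            se_beta=se_beta,
            gamma=gamma,
            sigma2=sigma2,
            b_smooth=theta[p:p + qs],
            b_group=theta[p + qs:],
            cov_theta=sigma2 * Cinv[:p + qs, :p + qs],
            edf_coef=edf_all[:p + qs],
            edf_group=float(edf_all[p + qs:].sum()),
            deviance=float(res.fun),
            n_iter=int(res.nit),
            trace=trace,
            converged=bool(res.success),
        )
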