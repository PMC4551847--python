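"""Low-rank Gaussian linear mixed model solver.

All models in this package share one algebraic form

    y = X beta + sum_b Z_b u_b + eps,    u_b ~ N(0, sigma_b^2 I),
    eps ~ N(0, sigma_eps^2 I),

i.e. independent variance-component blocks (penalized spline coefficients,
subject intercepts, subject slopes, group-offset splines).  Writing
gamma_b = sigma_b^2 / sigma_eps^2 the marginal covariance is
sigma_eps^2 * (I + Z D Z') with D = blockdiag(gamma_b I).  For fixed gamma,
beta and sigma_eps^2 have closed-form profiled-ML solutions, and all the
n-dimensional quantities reduce to q-dimensional ones (q = total number of
random coefficients, typically 5-40) through the identity

    (I + Zt Zt')^{-1} = I - Zt M^{-1} Zt',   M = I_q + Zt' Zt,
    log|I + Zt Zt'| = log|M|,     Zt = Z D^{1/2}.

Only cross-products (X'X, Z'X, Z'Z, X'y, Z'y, y'y) are needed, so a design
shared by thousands of molecules is factored once and each molecule's fit
costs a handful of q x q Cholesky solves inside a low-dimensional search
over log gamma.  The best linear unbiased predictions (BLUPs) of the random
coefficients fall out of the same factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

# Floor for the profiled residual variance: a perfect interpolating fit has
# unbounded Gaussian likelihood; the floor keeps log-likelihoods finite and
# comparisons between two perfect fits neutral.
_VAR_FLOOR = 1e-12

# log(gamma) box for the variance-ratio search.  exp(-30) ~ 1e-13 is an
# effective zero; exp(30) ~ 1e13 an effective infinite ratio.
_THETA_LO = -30.0
_THETA_HI = 30.0


@dataclass
class LmmResult:
    """Maximum-likelihood fit of one variance-components model."""

    beta: np.ndarray
    u: list[np.ndarray]                 # BLUPs per random block
    sigma2_eps: float
    sigma2_blocks: np.ndarray           # sigma_b^2 = gamma_b * sigma2_eps
    loglik: float                       # maximized marginal ML log-likelihood
    theta: np.ndarray                   # log variance ratios at the optimum
    converged: bool
    n_obs: int = 0
    n_fixed: int = 0

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.theta)


@dataclass
class LmmDesign:
    """Pre-factored fixed/random design shared across molecules.

    Parameters
    ----------
    X : (n, p) fixed-effect design.
    Z_blocks : list of (n, q_b) random-effect designs, one variance
        component per block.  May be empty (plain OLS).
    """

    X: np.ndarray
    Z_blocks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.X = X
        self.Z_blocks = [np.asarray(Z, dtype=float) for Z in self.Z_blocks]
        self.n, self.p = X.shape
        self.q_blocks = [Z.shape[1] for Z in self.Z_blocks]
        self.q = int(sum(self.q_blocks))
        self.n_blocks = len(self.Z_blocks)
        if self.q:
            Z = np.hstack(self.Z_blocks)
            self._Z = Z
            self._ZtZ = Z.T @ Z
            self._ZtX = Z.T @ X
            edges = np.cumsum([0] + self.q_blocks)
            self._slices = [slice(edges[b], edges[b + 1])
                            for b in range(self.n_blocks)]
            self._block_of = np.concatenate(
                [np.full(qb, b) for b, qb in enumerate(self.q_blocks)])
        else:
            self._Z = np.empty((self.n, 0))
            self._ZtZ = np.empty((0, 0))
            self._ZtX = np.empty((0, self.p))
            self._slices = []
            self._block_of = np.empty(0, dtype=int)
        self._XtX = X.T @ X

    # -- per-molecule cross products --------------------------------------

    def cross(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        y = np.asarray(y, dtype=float)
        return self.X.T @ y, self._Z.T @ y, float(y @ y)

    # -- profiled likelihood at fixed variance ratios ----------------------

    def _profiled(self, theta, Xty, Zty, yty, *, want_effects=False):
        """Profiled ML log-likelihood (and optionally beta / BLUPs)."""
        n, p = self.n, self.p
        if self.q:
            s = np.exp(0.5 * np.clip(theta, _THETA_LO, _THETA_HI))
            scale = s[self._block_of]
            M = self._ZtZ * np.outer(scale, scale)
            M[np.diag_indices_from(M)] += 1.0
            try:
                cho = linalg.cho_factor(M, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return -np.inf, None
            logdetM = 2.0 * np.sum(np.log(np.diag(cho[0])))
            A = self._ZtX * scale[:, None]          # Zt' X
            a = Zty * scale                         # Zt' y
            MiA = linalg.cho_solve(cho, A, check_finite=False)
            Mia = linalg.cho_solve(cho, a, check_finite=False)
            XtVX = self._XtX - A.T @ MiA
            XtVy = Xty - A.T @ Mia
            ytVy = yty - a @ Mia
        else:
            logdetM = 0.0
            XtVX, XtVy, ytVy = self._XtX, Xty, yty
            scale = Mia = a = None
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta, *_ = linalg.lstsq(XtVX, XtVy, check_finite=False)
        rVr = max(ytVy - beta @ XtVy, 0.0)
        sigma2 = max(rVr / n, _VAR_FLOOR)
        ll = -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetM)
        if not want_effects:
            return ll, None
        if self.q:
            resid_t = a - (self._ZtX * scale[:, None]) @ beta
            u_scaled = linalg.cho_solve(cho, resid_t, check_finite=False)
            u_full = scale * u_scaled
            u = [u_full[sl].copy() for sl in self._slices]
        else:
            u = []
        return ll, (beta, u, sigma2)

    # -- fitting -----------------------------------------------------------

    def fit(self, y: np.ndarray, theta0: np.ndarray | None = None,
            extra_starts: list[np.ndarray] | None = None) -> LmmResult:
        """Maximize the ML over the variance ratios for one response.

        ``theta0`` and ``extra_starts`` seed the search (warm starts from a
        nested fit keep nesting monotonicity: the optimum is at least as
        good as the supplied points).
        """
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(y)
        if not mask.all():
            # missing responses: refactor on the observed subset
            sub = LmmDesign(self.X[mask], [Z[mask] for Z in self.Z_blocks])
            return sub.fit(y[mask], theta0=theta0, extra_starts=extra_starts)
        Xty, Zty, yty = self.cross(y)
        B = self.n_blocks
        if B == 0:
            ll, (beta, u, sigma2) = self._profiled(
                np.empty(0), Xty, Zty, yty, want_effects=True)
            return LmmResult(beta, u, sigma2, np.empty(0), ll, np.empty(0),
                             True, self.n, self.p)

        def neg(theta):
            ll, _ = self._profiled(theta, Xty, Zty, yty)
            return -ll if np.isfinite(ll) else 1e12

        converged = True
        if B == 1:
            res = optimize.minimize_scalar(
                lambda t: neg(np.array([t])),
                bounds=(_THETA_LO, _THETA_HI), method="bounded",
                options={"xatol": 1e-5})
            best_t = np.array([res.x])
            candidates = [best_t, np.array([_THETA_LO])]
            if theta0 is not None:
                candidates.append(np.asarray(theta0, dtype=float))
            best_t = min(candidates, key=neg)
            converged = bool(res.success)
        else:
            starts = [np.zeros(B)]
            if theta0 is not None:
                starts.insert(0, np.asarray(theta0, dtype=float))
            if extra_starts:
                starts.extend(np.asarray(s, dtype=float)
                              for s in extra_starts)
            best_t, best_v = None, np.inf
            for k, t0 in enumerate(starts):
                res = optimize.minimize(
                    neg, t0, method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-9,
                             "maxiter": 200 * B})
                if res.fun < best_v:
                    best_v, best_t = res.fun, res.x
                    converged = bool(res.success)
                if k == 0 and res.success:
                    break       # warm start converged; skip cold restarts
            # boundary candidates: each block switched effectively off
            for b in range(B):
                t = best_t.copy()
                t[b] = _THETA_LO
                if neg(t) < best_v - 1e-10:
                    best_v, best_t = neg(t), t
        best_t = np.clip(best_t, _THETA_LO, _THETA_HI)
        ll, (beta, u, sigma2) = self._profiled(best_t, Xty, Zty, yty,
                                               want_effects=True)
        gamma = np.exp(best_t)
        return LmmResult(beta, u, sigma2, gamma * sigma2, ll, best_t,
                         converged, self.n, self.p)


    # -- batched fitting over many responses -------------------------------

    def _batch_eval(self, theta, XtY, ZtY, ytY) -> np.ndarray:
        """Profiled ML log-likelihood at one theta for every response."""
        n = self.n
        m = ytY.size
        if self.q:
            s = np.exp(0.5 * np.clip(theta, _THETA_LO, _THETA_HI))
            scale = s[self._block_of]
            M = self._ZtZ * np.outer(scale, scale)
            M[np.diag_indices_from(M)] += 1.0
            try:
                cho = linalg.cho_factor(M, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return np.full(m, -np.inf)
            logdetM = 2.0 * np.sum(np.log(np.diag(cho[0])))
            A = self._ZtX * scale[:, None]
            a = ZtY * scale[:, None]                    # (q, m)
            MiA = linalg.cho_solve(cho, A, check_finite=False)
            Mia = linalg.cho_solve(cho, a, check_finite=False)
            XtVX = self._XtX - A.T @ MiA                # shared (p, p)
            XtVY = XtY - A.T @ Mia                      # (p, m)
            ytVy = ytY - np.einsum("qm,qm->m", a, Mia)
        else:
            logdetM = 0.0
            XtVX, XtVY, ytVy = self._XtX, XtY, ytY
        try:
            beta = np.linalg.solve(XtVX, XtVY)          # (p, m)
        except np.linalg.LinAlgError:
            beta, *_ = linalg.lstsq(XtVX, XtVY, check_finite=False)
        rVr = np.maximum(ytVy - np.einsum("pm,pm->m", beta, XtVY), 0.0)
        sigma2 = np.maximum(rVr / n, _VAR_FLOOR)
        return -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetM)

    # shared coarse grids per number of variance components
    _COARSE = {
        1: [np.array([v]) for v in
            list(np.linspace(-12.0, 8.0, 21)) + [_THETA_LO]],
        2: None,
        3: None,
    }

    def _coarse_points(self) -> list[np.ndarray]:
        B = self.n_blocks
        if B == 1:
            return LmmDesign._COARSE[1]
        axis = (np.array([-12.0, -8.0, -5.0, -3.0, -1.5, 0.0, 1.5, 3.0, 6.0])
                if B == 2 else
                np.array([-12.0, -6.0, -3.0, -1.0, 1.0, 3.0, 6.0]))
        mesh = np.meshgrid(*([axis] * B), indexing="ij")
        pts = [np.array(p) for p in
               zip(*[mm.ravel() for mm in mesh])]
        pts.append(np.full(B, _THETA_LO))
        return pts

    _REFINE_STEPS = (1.5, 0.7, 0.3, 0.12)
    _MAX_DISTINCT = 32

    def fit_batch(self, Y: np.ndarray,
                  warm_thetas: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Maximize the profiled ML for many responses sharing this design.

        Candidate theta points are shared across responses so that the
        dominant cost (the q x q factorization per point) is paid once: a
        coarse grid per variance-ratio dimension followed by successive
        local refinements around the per-response incumbents.
        ``warm_thetas`` (one row per response; NaN rows skipped) are
        evaluated exactly per response, which keeps nested-model
        likelihood orderings intact when warm starts come from a nested
        fit.  Returns (loglik (m,), theta (m, B)).

        Responses must be complete (no NaN); use :meth:`fit` otherwise.
        """
        Y = np.asarray(Y, dtype=float)
        m = Y.shape[0]
        XtY = self.X.T @ Y.T
        ZtY = self._Z.T @ Y.T
        ytY = np.einsum("mn,mn->m", Y, Y)
        B = self.n_blocks
        if B == 0:
            ll = self._batch_eval(np.empty(0), XtY, ZtY, ytY)
            return ll, np.empty((m, 0))

        best_ll = np.full(m, -np.inf)
        best_theta = np.zeros((m, B))

        def consider(points):
            nonlocal best_ll, best_theta
            for th in points:
                ll = self._batch_eval(th, XtY, ZtY, ytY)
                upd = ll > best_ll
                if upd.any():
                    best_ll = np.where(upd, ll, best_ll)
                    best_theta[upd] = th

        consider(self._coarse_points())
        if B == 1:
            offsets = [np.array([d]) for d in (-1.0, 1.0)]
        else:
            mesh = np.meshgrid(*([np.array([-1.0, 0.0, 1.0])] * B),
                               indexing="ij")
            offsets = [np.array(p) for p in
                       zip(*[mm.ravel() for mm in mesh])
                       if any(v != 0 for v in p)]
        for step in self._REFINE_STEPS:
            centers = np.unique(np.round(best_theta / (step / 4))
                                * (step / 4), axis=0)
            if centers.shape[0] > self._MAX_DISTINCT:
                # keep the most frequent incumbents
                rounded = np.round(best_theta / (step / 4)) * (step / 4)
                uniq, counts = np.unique(rounded, axis=0,
                                         return_counts=True)
                centers = uniq[np.argsort(counts)[::-1][:self._MAX_DISTINCT]]
            pts = [c + step * off for c in centers for off in offsets]
            consider(pts)

        if warm_thetas is not None:
            warm_thetas = np.asarray(warm_thetas, dtype=float)
            for i in range(m):
                th = warm_thetas[i]
                if not np.isfinite(th).all():
                    continue
                ll, _ = self._profiled(th, XtY[:, i], ZtY[:, i], ytY[i])
                if ll > best_ll[i]:
                    best_ll[i] = ll
                    best_theta[i] = th
        return best_ll, best_theta


def ols_loglik(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS fit with its Gaussian ML log-likelihood (variance = RSS/n)."""
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    y, X = y[mask], np.asarray(X, dtype=float)[mask]
    n = y.size
    beta, *_ = linalg.lstsq(X, y, check_finite=False, lapack_driver="gelsd")
    rss = float(np.sum((y - X @ beta) ** 2))
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * max(sigma2, _VAR_FLOOR)) + 1.0)
    return beta, sigma2, ll
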