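"""Restricted maximum likelihood for Gaussian variance-component models.

The models handled here have the form

    y = X beta + sum_k Z_k u_k + e,
    u_k ~ N(0, sigma2_k I),   e ~ N(0, sigma2_e W^{-1}),

with Z_k indicator matrices of grouping factors (line, line x age, ...)
and W a diagonal matrix of row weights.  Weights arise from an exact
sufficiency reduction: rows with identical fixed- and random-effect design
are collapsed to their mean (weight = group size), and the pooled
within-group sum of squares enters the likelihood as an independent
sigma2_e * chi-square stratum.  The reported log-likelihood includes the
collapse constants, so values are comparable across models fitted to the
same underlying data with different random-term sets.

Estimation maximizes the REML log-likelihood by L-BFGS-B with analytic
gradients, followed by Fisher-scoring polish steps using the expected
information; variance components are constrained to be non-negative and
estimates pinned at the zero boundary are flagged.  The asymptotic
covariance matrix of the variance-component estimates is the inverse of
the expected REML information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RemlResult", "fit_reml"]


@dataclass
class RemlResult:
    """REML estimates of a variance-component model."""

    terms: list[str]                 # random terms, residual "e" last
    variance: dict[str, float]       # sigma^2 per term (trait units^2)
    asy_cov: np.ndarray | None       # covariance of sigma^2 estimates, term order
    beta: np.ndarray                 # GLS fixed-effect estimates
    beta_se: np.ndarray
    beta_names: list[str]
    loglik: float                    # REML log-likelihood (constant terms dropped)
    n_obs: int                       # observations before collapsing
    converged: bool
    boundary: set[str] = field(default_factory=set)
    n_iter: int = 0

    def genetic_cov_block(self, genetic_terms: list[str]) -> tuple[float, float, float]:
        """Collapse asy_cov to (Var(sG2), Var(se2), Cov(sG2, se2))."""
        if self.asy_cov is None:
            raise ValueError("no asymptotic covariance available")
        idx = [self.terms.index(t) for t in genetic_terms]
        ie = self.terms.index("e")
        C = self.asy_cov
        var_g = float(C[np.ix_(idx, idx)].sum())
        var_e = float(C[ie, ie])
        cov_ge = float(C[idx, ie].sum())
        return var_g, var_e, cov_ge


class _RemlProblem:
    def __init__(self, y, X, Z_codes, weights, ssw, dfw):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if weights is None:
            weights = np.ones(self.n)
        self.w = np.asarray(weights, dtype=float)
        self.ssw = float(ssw)
        self.dfw = float(dfw)
        self.terms = list(Z_codes)
        # membership matrices M_k (n x q_k), sparse
        self.M = []
        for t in self.terms:
            codes = np.asarray(Z_codes[t])
            _, inv = np.unique(codes, return_inverse=True)
            q = inv.max() + 1
            M = sp.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), inv)), shape=(self.n, q)
            )
            self.M.append(M)
        self.logw_const = float(np.sum(np.log(self.w)))

    # ---- likelihood pieces -------------------------------------------------

    def _build_V(self, s2):
        V = np.diag(s2[-1] / self.w)
        for k, M in enumerate(self.M):
            if s2[k] != 0.0:
                V += s2[k] * (M @ M.T).toarray()
        return V

    def minus2ll(self, s2):
        V = self._build_V(s2)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        ViX = cho_solve((c, low), self.X)
        Viy = cho_solve((c, low), self.y)
        XtViX = self.X.T @ ViX
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None
        beta = np.linalg.solve(XtViX, self.X.T @ Viy)
        r = self.y - self.X @ beta
        Vir = cho_solve((c, low), r)
        quad = float(r @ Vir)
        s2e = s2[-1]
        val = (
            logdetV
            + logdetXtViX
            + quad
            + self.dfw * np.log(s2e)
            + self.ssw / s2e
            + self.logw_const
        )
        cache = (c, low, ViX, XtViX, beta, Vir)
        return val, cache

    def _P_and_Py(self, s2, cache):
        c, low, ViX, XtViX, beta, Vir = cache
        Vi = cho_solve((c, low), np.eye(self.n))
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = Vir  # P y = V^{-1}(y - X beta) for GLS beta
        return P, Py

    def gradient(self, s2, cache):
        """Gradient of minus2ll wrt sigma^2 vector (terms..., e)."""
        P, Py = self._P_and_Py(s2, cache)
        g = np.empty(len(s2))
        for k, M in enumerate(self.M):
            PM = P @ M.toarray()
            tr = float((PM * M.toarray()).sum())
            u = M.T @ Py
            g[k] = tr - float(u @ u)
        # residual: A_e = diag(1/w) on collapsed rows plus within stratum
        s2e = s2[-1]
        g[-1] = (
            float((np.diag(P) / self.w).sum())
            - float((Py * Py / self.w).sum())
            + self.dfw / s2e
            - self.ssw / s2e**2
        )
        return g, P, Py

    def expected_info(self, s2, P):
        """Expected information of the REML loglik (not minus2ll)."""
        K = len(self.terms)
        Md = [M.toarray() for M in self.M]
        PM = [P @ M for M in Md]
        I = np.empty((K + 1, K + 1))
        for k in range(K):
            for l in range(k, K):
                B = Md[k].T @ PM[l]
                I[k, l] = I[l, k] = 0.5 * float((B * B).sum())
        iw = 1.0 / self.w
        for k in range(K):
            v = ((PM[k] * PM[k]).sum(axis=1)) * iw
            I[k, -1] = I[-1, k] = 0.5 * float(v.sum())
        Pw = P * iw[None, :]
        I[-1, -1] = 0.5 * float((Pw * Pw.T).sum()) + 0.5 * self.dfw / s2[-1] ** 2
        return I


def fit_reml(
    y,
    X,
    Z_codes: dict,
    weights=None,
    ssw: float = 0.0,
    dfw: float = 0.0,
    beta_names: list[str] | None = None,
    n_obs: int | None = None,
    compute_cov: bool = True,
    max_iter: int = 200,
    tol: float = 1e-10,
    starts=None,
) -> RemlResult:
    """Fit a Gaussian variance-component model by REML.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (collapsed rows).
    Z_codes
        Mapping random-term name -> integer/group codes per row.
    weights
        Number of original observations collapsed into each row.
    ssw, dfw
        Pooled within-group sum of squares and its degrees of freedom
        from the collapse (an independent sigma2_e stratum).
    compute_cov
        Whether to compute the asymptotic covariance matrix (skippable
        in large simulation loops).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or not np.all(np.isfinite(y)):
        raise ValueError("response must be a finite 1-d array")
    prob = _RemlProblem(y, X, Z_codes, weights, ssw, dfw)
    n_total = int(n_obs if n_obs is not None else prob.n + dfw)

    # standardize scale for optimizer conditioning
    scale = float(np.var(y)) or 1.0
    K = len(prob.terms)
    floor_e = 1e-10 * scale

    def obj(s2):
        val, cache = prob.minus2ll(s2)
        if cache is None:
            return np.inf, np.zeros(K + 1)
        g, _, _ = prob.gradient(s2, cache)
        return val, g

    if starts is None:
        starts = []
        eq = np.full(K + 1, scale / (K + 1))
        starts.append(eq)
        sm = np.full(K + 1, 0.05 * scale)
        sm[-1] = 0.9 * scale
        starts.append(sm)
    else:
        starts = [np.asarray(s, dtype=float) for s in starts]
        starts = [np.maximum(s, [0.0] * K + [floor_e]) for s in starts]

    bounds = [(0.0, None)] * K + [(floor_e, None)]
    lower = np.array([0.0] * K + [floor_e])

    def scoring(s2, val, cache, iters):
        """Fisher scoring with step halving and boundary projection."""
        converged = False
        it = 0
        for it in range(1, iters + 1):
            g, P, _ = prob.gradient(s2, cache)
            info = prob.expected_info(s2, P)
            try:
                step = np.linalg.solve(info, -0.5 * g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, -0.5 * g, rcond=None)[0]
            alpha = 1.0
            improved = False
            for _ in range(30):
                cand = np.maximum(s2 + alpha * step, lower)
                cval, ccache = prob.minus2ll(cand)
                if cval <= val + 1e-12:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                # stationary only if the projected gradient vanishes
                at_bound = (s2 <= lower + 1e-300) & (g > 0)
                gtol_abs = 1e-5 * max(prob.n, 1.0) / scale
                converged = bool(np.all(at_bound | (np.abs(g) < gtol_abs)))
                break
            delta = np.max(np.abs(cand - s2)) / max(scale, 1e-300)
            s2, val, cache = cand, cval, ccache
            if delta < tol:
                converged = True
                break
        return s2, val, cache, converged, it

    # pick the best start, try Fisher scoring directly (fast when the
    # start is a good moment estimate), fall back to L-BFGS-B otherwise
    evals = []
    for s0 in starts:
        s0 = np.maximum(np.asarray(s0, dtype=float), lower)
        v0, c0 = prob.minus2ll(s0)
        evals.append((v0, s0, c0))
    v0, s0, c0 = min(evals, key=lambda t: t[0])
    s2, val, cache, converged, it = scoring(s0, v0, c0, max_iter)
    if not converged:
        res = optimize.minimize(
            obj, s2, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        s2 = np.maximum(res.x, lower)
        val, cache = prob.minus2ll(s2)
        s2, val, cache, converged, it2 = scoring(s2, val, cache, max_iter)
        it += it2

    c, low, ViX, XtViX, beta, Vir = cache
    beta_cov = np.linalg.inv(XtViX)
    beta_se = np.sqrt(np.diag(beta_cov))

    boundary = {t for k, t in enumerate(prob.terms) if s2[k] <= 1e-8 * scale}
    if s2[-1] <= 1e-8 * scale:
        boundary.add("e")
    est = {t: (0.0 if t in boundary else float(s2[k])) for k, t in enumerate(prob.terms)}
    est["e"] = float(s2[-1])

    asy_cov = None
    if compute_cov:
        _, P, _ = prob.gradient(s2, cache)
        info = prob.expected_info(s2, P)
        try:
            asy_cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            asy_cov = np.linalg.pinv(info)

    names = beta_names or [f"b{j}" for j in range(prob.p)]
    return RemlResult(
        terms=prob.terms + ["e"],
        variance=est,
        asy_cov=asy_cov,
        beta=beta,
        beta_se=beta_se,
        beta_names=names,
        loglik=-0.5 * float(val),
        n_obs=n_total,
        converged=converged,
        boundary=boundary,
        n_iter=it,
    )
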