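"""REML animal models for the herd + cow-within-herd design.

The model for every trait is  y = mu + herd + cow + e,  with the cow effect
distributed N(0, A sigma_a^2) for the sire--MGS relationship matrix A (the
Kronecker product A x G in multivariate fits) and independent residuals
(R across traits within a cow).  Heritability is sigma_a^2 over phenotypic
variance; genetic and phenotypic correlations come from the joint (G, R).

Estimation maximizes the restricted log-likelihood directly over a
log-Cholesky parameterization of (G, R) -- which keeps both matrices
positive definite -- with a quasi-Newton optimizer.  Two exact evaluation
routes are used:

* a rotated route for records with all traits observed: with K = A_cc the
  cow block of A and K = U D U', the rotated records decouple into
  independent t x t blocks with covariance d_i G + R, so one likelihood
  evaluation is O(n) after a single eigendecomposition (which can be shared
  across fits on the same pedigree);
* a mixed-model-equations route for records with missing traits (needed
  when the three parities are modelled as distinct traits under culling),
  using the sparse pedigree inverse and a dense factorization of the MME
  coefficient matrix.

Both routes evaluate the identical restricted likelihood (including
constants), which the test suite exploits.  Standard errors of
heritabilities and correlations are delta-method values from the inverse of
the numerically evaluated observed information on the (G, R) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import PedigreeTable, build_A, build_A_inverse

LOG2PI = float(np.log(2.0 * np.pi))
BOUNDARY_REL = 1e-8  # variance below this fraction of phenotypic variance
MAX_ITER = 200


# ---------------------------------------------------------------------------
# covariance parameterization


def _n_vech(t: int) -> int:
    return t * (t + 1) // 2


def _theta_to_cov(theta: np.ndarray, t: int) -> np.ndarray:
    """Log-Cholesky: exp() on the diagonal of L, raw off-diagonals."""
    L = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T


def _cov_to_theta(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    t = M.shape[0]
    out = []
    for i in range(t):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _vech(M: np.ndarray) -> np.ndarray:
    t = M.shape[0]
    return np.array([M[i, j] for i in range(t) for j in range(i + 1)])


def _unvech(v: np.ndarray, t: int) -> np.ndarray:
    M = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i + 1):
            M[i, j] = M[j, i] = v[k]
            k += 1
    return M


# ---------------------------------------------------------------------------
# results


@dataclass
class ParameterEstimate:
    estimate: float | None
    se: float | None
    significant: bool | None = None  # |estimate| > 1.96 * SE

    def __post_init__(self):
        if self.estimate is not None and self.se is not None and self.se > 0:
            self.significant = bool(abs(self.estimate) > 1.96 * self.se)


@dataclass
class RemlFit:
    """Converged (or flagged) REML fit with derived genetic parameters."""

    traits: list[str]
    G: np.ndarray
    R: np.ndarray
    heritability: dict
    genetic_corr: dict
    phenotypic_corr: dict
    herd_solutions: pd.DataFrame
    lsm: dict
    status: str  # "converged" | "max_iter" | "boundary"
    n_iter: int
    minus2_loglik: float
    loglik_trace: list = field(default_factory=list)
    param_cov: np.ndarray | None = None
    model: str = ""
    _context: object = None
    _theta: np.ndarray | None = None
    _scale: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.status in ("converged", "boundary")


# ---------------------------------------------------------------------------
# rotated (complete-record) likelihood


class RotatedContext:
    """Shared eigen-rotation for complete multivariate records on a pedigree.

    Expensive pieces (relationship matrix, eigendecomposition of its cow
    block, rotated herd design) depend only on the pedigree, the cow list
    and the herd labels, so one context can serve many fits -- e.g. every
    replicate of a parameter-recovery study on a fixed structure.
    """

    def __init__(self, pedigree: PedigreeTable, cow_ids: Sequence, herd_labels: Sequence):
        self.pedigree = pedigree
        self.cow_ids = [str(c) for c in cow_ids]
        self.herds = sorted(set(map(str, herd_labels)))
        if len(self.herds) < 1:
            raise ValueError("at least one herd is required")
        self.A = build_A(pedigree)
        self.cow_idx = pedigree.index_of(self.cow_ids)
        K = self.A.matrix[np.ix_(self.cow_idx, self.cow_idx)]
        self.d, self.U = np.linalg.eigh(K)
        self.d = np.clip(self.d, 0.0, None)
        h_pos = {h: i for i, h in enumerate(self.herds)}
        X = np.zeros((len(self.cow_ids), len(self.herds)))
        for i, h in enumerate(map(str, herd_labels)):
            X[i, h_pos[h]] = 1.0
        self.X = X
        self.Xr = self.U.T @ X
        self.n = len(self.cow_ids)
        self.h = len(self.herds)

    # -- likelihood pieces -------------------------------------------------
    def _blocks(self, G: np.ndarray, R: np.ndarray):
        t = G.shape[0]
        Sigma = self.d[:, None, None] * G[None] + R[None]
        if t == 1:
            s = Sigma[:, 0, 0]
            if np.any(s <= 0):
                return None
            Si = (1.0 / s)[:, None, None]
            logdetV = float(np.sum(np.log(s)))
        else:
            sign, logdet = np.linalg.slogdet(Sigma)
            if np.any(sign <= 0):
                return None
            Si = np.linalg.inv(Sigma)
            logdetV = float(np.sum(logdet))
        return Si, logdetV

    def minus2_restricted_ll(self, Yr: np.ndarray, G: np.ndarray, R: np.ndarray) -> float:
        """-2 log restricted likelihood (with constants) for rotated data."""
        t = G.shape[0]
        blocks = self._blocks(G, R)
        if blocks is None:
            return np.inf
        Si, logdetV = blocks
        W = np.einsum("na,nb,nkl->akbl", self.Xr, self.Xr, Si).reshape(
            self.h * t, self.h * t
        )
        rhs = np.einsum("na,nkl,nl->ak", self.Xr, Si, Yr).reshape(self.h * t)
        signW, logdetW = np.linalg.slogdet(W)
        if signW <= 0:
            return np.inf
        b = np.linalg.solve(W, rhs)
        yVy = float(np.einsum("nk,nkl,nl->", Yr, Si, Yr))
        yPy = yVy - float(b @ rhs)
        N, p = self.n * t, self.h * t
        return logdetV + logdetW + yPy + (N - p) * LOG2PI

    def gls_solution(self, Yr: np.ndarray, G: np.ndarray, R: np.ndarray):
        """Herd-trait fixed-effect solutions and their covariance."""
        t = G.shape[0]
        Si, _ = self._blocks(G, R)
        W = np.einsum("na,nb,nkl->akbl", self.Xr, self.Xr, Si).reshape(
            self.h * t, self.h * t
        )
        rhs = np.einsum("na,nkl,nl->ak", self.Xr, Si, Yr).reshape(self.h * t)
        covb = np.linalg.inv(W)
        return covb @ rhs, covb

    def blup(self, Yr: np.ndarray, G: np.ndarray, R: np.ndarray) -> np.ndarray:
        """EBVs for every animal in the pedigree at the given components."""
        t = G.shape[0]
        Si, _ = self._blocks(G, R)
        b, _ = self.gls_solution(Yr, G, R)
        Bt = b.reshape(self.h, t)
        resid = Yr - self.Xr @ Bt
        w = np.einsum("nkl,nl->nk", Si, resid)
        Mr = self.A.matrix[:, self.cow_idx] @ self.U  # q x n
        return Mr @ (w @ G.T)  # q x t


# ---------------------------------------------------------------------------
# mixed-model-equations likelihood (missing traits allowed)


class MMEContext:
    """Dense MME evaluation of the restricted likelihood with trait masks.

    One row per cow; ``Y`` is n x t with NaN marking unobserved traits.
    Fixed effects are herd-trait cells present in the data.  The additive
    covariance uses the sparse pedigree inverse; log|A| comes from the
    Mendelian variances.
    """

    def __init__(self, pedigree: PedigreeTable, cow_ids, herd_labels, Y: np.ndarray):
        self.pedigree = pedigree
        self.q = len(pedigree)
        Ainv = build_A_inverse(pedigree)
        self.Ainv = Ainv.matrix.toarray()
        self.logdetA = Ainv.log_det
        self.cow_idx = pedigree.index_of([str(c) for c in cow_ids])
        self.herds = sorted(set(map(str, herd_labels)))
        h_pos = {h: i for i, h in enumerate(self.herds)}
        self.herd_idx = np.array([h_pos[str(h)] for h in herd_labels])
        self.Y = np.asarray(Y, dtype=float)
        self.n, self.t = self.Y.shape
        self.obs = ~np.isnan(self.Y)
        self.N = int(self.obs.sum())
        # estimable herd-trait cells
        cells = set()
        for i in range(self.n):
            for k in np.nonzero(self.obs[i])[0]:
                cells.add((self.herd_idx[i], int(k)))
        self.cells = sorted(cells)
        self.cell_col = {c: j for j, c in enumerate(self.cells)}
        self.p = len(self.cells)
        self.patterns = {}
        for i in range(self.n):
            key = tuple(np.nonzero(self.obs[i])[0])
            self.patterns.setdefault(key, []).append(i)

    def herds_per_trait(self) -> dict:
        out = {}
        for hcell, k in self.cells:
            out.setdefault(k, set()).add(hcell)
        return {k: len(v) for k, v in out.items()}

    def _assemble(self, G: np.ndarray, R: np.ndarray):
        t, q, p = self.t, self.q, self.p
        dim = p + q * t
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        yRy = 0.0
        sum_logdetR = 0.0
        for key, rows in self.patterns.items():
            if not key:
                continue
            o = np.array(key)
            rows = np.array(rows)
            Ro = R[np.ix_(o, o)]
            sign, ld = np.linalg.slogdet(Ro)
            if sign <= 0:
                return None
            Rinv = np.linalg.inv(Ro)
            sum_logdetR += ld * len(rows)
            Yo = self.Y[np.ix_(rows, o)]
            colsF = np.array(
                [[self.cell_col[(self.herd_idx[i], int(k))] for k in o] for i in rows]
            )
            colsU = p + self.cow_idx[rows][:, None] * t + o[None, :]
            yRy += float(np.einsum("mi,ij,mj->", Yo, Rinv, Yo))
            for a in range(len(o)):
                for b in range(len(o)):
                    w = Rinv[a, b]
                    np.add.at(C, (colsF[:, a], colsF[:, b]), w)
                    np.add.at(C, (colsF[:, a], colsU[:, b]), w)
                    np.add.at(C, (colsU[:, a], colsF[:, b]), w)
                    np.add.at(C, (colsU[:, a], colsU[:, b]), w)
                    np.add.at(rhs, colsF[:, a], w * Yo[:, b])
                    np.add.at(rhs, colsU[:, a], w * Yo[:, b])
        signG, logdetG = np.linalg.slogdet(G)
        if signG <= 0:
            return None
        Ginv = np.linalg.inv(G)
        C[p:, p:] += np.kron(self.Ainv, Ginv)
        return C, rhs, yRy, sum_logdetR, logdetG

    def minus2_restricted_ll(self, G: np.ndarray, R: np.ndarray) -> float:
        parts = self._assemble(G, R)
        if parts is None:
            return np.inf
        C, rhs, yRy, sum_logdetR, logdetG = parts
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        yPy = yRy - float(sol @ rhs)
        return (
            sum_logdetR
            + self.t * self.logdetA
            + self.q * logdetG
            + logdetC
            + yPy
            + (self.N - self.p) * LOG2PI
        )

    def solve(self, G: np.ndarray, R: np.ndarray):
        """MME solutions: fixed effects, EBVs, and fixed-effect covariance."""
        parts = self._assemble(G, R)
        if parts is None:
            raise linalg.LinAlgError("singular coefficient matrix")
        C, rhs, *_ = parts
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        b = sol[: self.p]
        u = sol[self.p :].reshape(self.q, self.t)
        covb = Cinv[: self.p, : self.p]
        return b, u, covb

    def value_and_score(self, G: np.ndarray, R: np.ndarray):
        """-2 logLR and its gradient with respect to G and R.

        Uses the classical restricted-likelihood score: for G,
        q G^-1 - G^-1 (U' A^-1 U + T) G^-1 with T[k,l] = tr(A^-1 C^uu_kl);
        for R, per missing-pattern sums of residual outer products plus the
        prediction-variance correction from the inverse coefficient matrix.
        One factorization serves both the value and the whole gradient.
        """
        t, q, p = self.t, self.q, self.p
        parts = self._assemble(G, R)
        if parts is None:
            return np.inf, None, None
        C, rhs, yRy, sum_logdetR, logdetG = parts
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None, None
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]), check_finite=False)
        sol = Cinv @ rhs
        yPy = yRy - float(sol @ rhs)
        f = (
            sum_logdetR
            + t * self.logdetA
            + q * logdetG
            + logdetC
            + yPy
            + (self.N - p) * LOG2PI
        )
        Ginv = np.linalg.inv(G)
        U_sol = sol[p:].reshape(q, t)
        Su = U_sol.T @ self.Ainv @ U_sol
        Cuu4 = Cinv[p:, p:].reshape(q, t, q, t)
        Tu = np.einsum("ab,bkal->kl", self.Ainv, Cuu4)
        dG = q * Ginv - Ginv @ (Su + Tu) @ Ginv

        dR = np.zeros((t, t))
        b = sol[:p]
        uflat = sol[p:]
        for key, rows in self.patterns.items():
            if not key:
                continue
            o = np.array(key)
            rows = np.array(rows)
            Rinv = np.linalg.inv(R[np.ix_(o, o)])
            Yo = self.Y[np.ix_(rows, o)]
            colsF = np.array(
                [[self.cell_col[(self.herd_idx[i], int(k))] for k in o] for i in rows]
            )
            colsU = p + self.cow_idx[rows][:, None] * t + o[None, :]
            pred = b[colsF] + uflat[colsU - p]
            e = Yo - pred
            M = e.T @ e
            for a in range(len(o)):
                for c in range(len(o)):
                    M[a, c] += (
                        Cinv[colsF[:, a], colsF[:, c]].sum()
                        + Cinv[colsF[:, a], colsU[:, c]].sum()
                        + Cinv[colsU[:, a], colsF[:, c]].sum()
                        + Cinv[colsU[:, a], colsU[:, c]].sum()
                    )
            contrib = len(rows) * Rinv - Rinv @ M @ Rinv
            dR[np.ix_(o, o)] += contrib
        return f, dG, dR


# ---------------------------------------------------------------------------
# fitting machinery


def _grad_from_cov(D: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Chain rule from a symmetric d/dCov matrix to log-Cholesky parameters."""
    t = L.shape[0]
    M = 2.0 * D @ L
    out = []
    for i in range(t):
        for j in range(i + 1):
            out.append(M[i, i] * L[i, i] if i == j else M[i, j])
    return np.array(out)


def _chol_of_theta(theta: np.ndarray, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


def _optimize_with_grad(value_and_grad, theta0: np.ndarray, bounds=None):
    """Quasi-Newton descent with the analytic restricted-likelihood score."""
    trace = []

    def record(xk):
        trace.append(float(value_and_grad(xk)[0]))

    res = optimize.minimize(
        value_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=record,
        options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-7},
    )
    status = "converged" if (res.success or res.status == 0) else "max_iter"
    return res.x, float(res.fun), status, res.nit, trace


def _optimize(nll, theta0: np.ndarray, bounds=None):
    """Quasi-Newton descent on -2 logL(restricted), polished derivative-free.

    The likelihood is evaluated to ~1e-10 relative accuracy, so the
    finite-difference gradient uses a generous step; a Nelder-Mead polish
    from the quasi-Newton solution guards against premature termination on
    gradient noise near the optimum.
    """
    trace = []

    def record(xk):
        trace.append(float(nll(xk)))

    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=record,
        options={"maxiter": MAX_ITER, "ftol": 1e-11, "gtol": 1e-7, "eps": 1e-5},
    )
    best_x, best_f = res.x, float(res.fun)
    nit = res.nit

    polish = optimize.minimize(
        nll,
        best_x,
        method="Nelder-Mead",
        options={
            "maxiter": 200 * len(theta0),
            "maxfev": max(50 * len(theta0), 300),
            "xatol": 1e-8,
            "fatol": 1e-9,
            "initial_simplex": best_x[None, :]
            + np.vstack([np.zeros_like(best_x), np.diag(0.05 * np.ones_like(best_x))]),
        },
    )
    if np.isfinite(polish.fun) and polish.fun <= best_f:
        trace.append(float(polish.fun))
        best_x, best_f = polish.x, float(polish.fun)
    nit += polish.nit
    status = "converged" if (res.success or res.status == 0 or polish.success) else "max_iter"
    return best_x, best_f, status, nit, trace


def _information_cov(nll_natural, phi_hat: np.ndarray) -> np.ndarray | None:
    """Inverse observed information by central finite differences.

    Steps are halved and the Hessian retried when a perturbed covariance
    leaves the positive-definite cone (the likelihood returns +inf there).
    """
    m = len(phi_hat)
    f0 = nll_natural(phi_hat)
    if not np.isfinite(f0):
        return None
    for scale in (1e-4, 5e-5, 2e-5):
        H = np.zeros((m, m))
        steps = scale * (np.abs(phi_hat) + 1e-2)
        ok = True
        for i in range(m):
            if not ok:
                break
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = steps[i]
                ej[j] = steps[j]
                fpp = nll_natural(phi_hat + ei + ej)
                fpm = nll_natural(phi_hat + ei - ej)
                fmp = nll_natural(phi_hat - ei + ej)
                fmm = nll_natural(phi_hat - ei - ej)
                if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                    ok = False
                    break
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        if ok:
            info = 0.5 * H  # nll is -2 logL
            try:
                return np.linalg.inv(info)
            except np.linalg.LinAlgError:
                return np.linalg.pinv(info)
    return None


def _delta_se(func, phi_hat: np.ndarray, cov: np.ndarray | None) -> float | None:
    if cov is None:
        return None
    m = len(phi_hat)
    grad = np.zeros(m)
    steps = 1e-5 * (np.abs(phi_hat) + 1e-3)
    for i in range(m):
        e = np.zeros(m)
        e[i] = steps[i]
        fp, fm = func(phi_hat + e), func(phi_hat - e)
        if fp is None or fm is None:
            return None
        grad[i] = (fp - fm) / (2 * steps[i])
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else None


def _derive_parameters(traits, G, R, phi_hat, cov, boundary_tol):
    t = len(traits)
    nv = _n_vech(t)

    def gr_of(phi):
        return _unvech(phi[:nv], t), _unvech(phi[nv:], t)

    def h2_func(k):
        def f(phi):
            Gp, Rp = gr_of(phi)
            denom = Gp[k, k] + Rp[k, k]
            return Gp[k, k] / denom if denom > 0 else None

        return f

    def rg_func(k, l):
        def f(phi):
            Gp, _ = gr_of(phi)
            denom = Gp[k, k] * Gp[l, l]
            return Gp[k, l] / np.sqrt(denom) if denom > 0 else None

        return f

    def rp_func(k, l):
        def f(phi):
            Gp, Rp = gr_of(phi)
            denom = (Gp[k, k] + Rp[k, k]) * (Gp[l, l] + Rp[l, l])
            return (Gp[k, l] + Rp[k, l]) / np.sqrt(denom) if denom > 0 else None

        return f

    herit, rg, rp = {}, {}, {}
    for k, tr in enumerate(traits):
        phen = G[k, k] + R[k, k]
        if phen <= 0 or G[k, k] < boundary_tol * phen:
            herit[tr] = ParameterEstimate(0.0, None, None)
        else:
            herit[tr] = ParameterEstimate(
                G[k, k] / phen, _delta_se(h2_func(k), phi_hat, cov)
            )
    for k in range(t):
        for l in range(k + 1, t):
            pair = (traits[k], traits[l])
            phen_k = G[k, k] + R[k, k]
            phen_l = G[l, l] + R[l, l]
            if (
                G[k, k] < boundary_tol * max(phen_k, 1e-300)
                or G[l, l] < boundary_tol * max(phen_l, 1e-300)
            ):
                rg[pair] = ParameterEstimate(None, None, None)  # not estimable
            else:
                rg[pair] = ParameterEstimate(
                    G[k, l] / np.sqrt(G[k, k] * G[l, l]),
                    _delta_se(rg_func(k, l), phi_hat, cov),
                )
            rp[pair] = ParameterEstimate(
                (G[k, l] + R[k, l]) / np.sqrt(phen_k * phen_l),
                _delta_se(rp_func(k, l), phi_hat, cov),
            )
    return herit, rg, rp


def _degenerate_fit(traits, context, model):
    t = len(traits)
    Z = np.zeros((t, t))
    herds = context.herds if context is not None else []
    return RemlFit(
        traits=list(traits),
        G=Z.copy(),
        R=Z.copy(),
        heritability={tr: ParameterEstimate(0.0, None, None) for tr in traits},
        genetic_corr={},
        phenotypic_corr={},
        herd_solutions=pd.DataFrame(index=herds, columns=traits, dtype=float),
        lsm={tr: ParameterEstimate(None, None, None) for tr in traits},
        status="boundary",
        n_iter=0,
        minus2_loglik=np.nan,
        model=model,
        _context=context,
    )


def _fit_rotated(
    context: RotatedContext,
    Y: np.ndarray,
    traits: list[str],
    model: str,
    compute_se: bool = True,
) -> RemlFit:
    t = Y.shape[1]
    scale = Y.std(axis=0, ddof=1)
    if np.any(scale < 1e-12):
        return _degenerate_fit(traits, context, model)
    Ys = Y / scale
    Yr = context.U.T @ Ys
    nv = _n_vech(t)

    def nll(theta):
        G = _theta_to_cov(theta[:nv], t)
        R = _theta_to_cov(theta[nv:], t)
        return context.minus2_restricted_ll(Yr, G, R)

    G0 = 0.4 * np.eye(t)
    R0 = 0.6 * np.eye(t)
    theta0 = np.concatenate([_cov_to_theta(G0), _cov_to_theta(R0)])
    bounds = []
    for _ in range(2):
        k = 0
        for i in range(t):
            for j in range(i + 1):
                bounds.append((-12.0, 6.0) if i == j else (-30.0, 30.0))
                k += 1
    theta_hat, m2ll, status, n_iter, trace = _optimize(nll, theta0, bounds)
    Gs = _theta_to_cov(theta_hat[:nv], t)
    Rs = _theta_to_cov(theta_hat[nv:], t)
    # the fit ran on per-trait standardized responses; put the likelihood
    # back on the natural scale (constant Jacobian offset per trait)
    jac = float((context.n - context.h) * np.sum(np.log(scale**2)))
    m2ll += jac
    trace = [v + jac for v in trace]

    phi_hat = np.concatenate([_vech(Gs), _vech(Rs)])

    def nll_natural(phi):
        G = _unvech(phi[:nv], t)
        R = _unvech(phi[nv:], t)
        return context.minus2_restricted_ll(Yr, G, R)

    cov = _information_cov(nll_natural, phi_hat) if compute_se else None
    herit, rg, rp = _derive_parameters(traits, Gs, Rs, phi_hat, cov, BOUNDARY_REL)
    if any(h.estimate == 0.0 and h.se is None for h in herit.values()):
        status = "boundary"

    # fixed effects, LSMs on the original scale
    b, covb = context.gls_solution(Yr, Gs, Rs)
    B = b.reshape(context.h, t) * scale[None, :]
    herd_solutions = pd.DataFrame(B, index=context.herds, columns=traits)
    lsm = {}
    for k, tr in enumerate(traits):
        c = np.zeros(context.h * t)
        for a in range(context.h):
            c[a * t + k] = 1.0 / context.h
        est = float(c @ b) * scale[k]
        sem = float(np.sqrt(max(c @ covb @ c, 0.0))) * scale[k]
        lsm[tr] = ParameterEstimate(est, sem)

    # back-transform components
    S = np.outer(scale, scale)
    fit = RemlFit(
        traits=list(traits),
        G=Gs * S,
        R=Rs * S,
        heritability=herit,
        genetic_corr=rg,
        phenotypic_corr=rp,
        herd_solutions=herd_solutions,
        lsm=lsm,
        status=status,
        n_iter=n_iter,
        minus2_loglik=m2ll,
        loglik_trace=trace,
        param_cov=cov,
        model=model,
        _context=context,
        _theta=theta_hat,
        _scale=scale,
    )
    fit._Yr = Yr
    return fit


def _shrink_to_pd(M: np.ndarray) -> np.ndarray:
    """Halve off-diagonals until the matrix is safely positive definite."""
    D = np.diag(np.diag(M))
    O = M - D
    for _ in range(30):
        cand = D + O
        if np.linalg.eigvalsh(cand).min() > 1e-6 * max(np.trace(cand), 1e-12):
            return cand
        O *= 0.5
    return D + np.eye(len(M)) * 1e-6


def _mme_warm_start(ctx: MMEContext) -> tuple[np.ndarray, np.ndarray]:
    """Cheap starting values for the multitrait MME fit.

    Per-trait variances come from fast univariate rotated fits on each
    trait's observed subset; covariances from herd-centered phenotypic
    covariances on pairwise-complete subsets, split between G and R by the
    geometric mean of the initial heritabilities.
    """
    t = ctx.t
    G0 = np.eye(t) * 0.4
    R0 = np.eye(t) * 0.6
    ids = np.array(ctx.pedigree.ids, dtype=object)
    for k in range(t):
        mask = ctx.obs[:, k]
        if mask.sum() < 30:
            continue
        try:
            rctx = RotatedContext(
                ctx.pedigree,
                ids[ctx.cow_idx[mask]],
                [ctx.herds[j] for j in ctx.herd_idx[mask]],
            )
            fitk = _fit_rotated(
                rctx, ctx.Y[mask][:, [k]].copy(), ["y"], "warm-start",
                compute_se=False,
            )
            vk = float(fitk.G[0, 0] + fitk.R[0, 0])
            hk = fitk.heritability["y"].estimate or 0.2
        except Exception:
            continue
        hk = float(np.clip(hk, 0.02, 0.9))
        if vk > 0:
            G0[k, k] = hk * vk
            R0[k, k] = (1.0 - hk) * vk
    Yc = ctx.Y.copy()
    for j in range(len(ctx.herds)):
        sel = ctx.herd_idx == j
        for k in range(t):
            m = sel & ctx.obs[:, k]
            if m.sum():
                Yc[m, k] -= np.nanmean(ctx.Y[m, k])
    for k in range(t):
        for l in range(k):
            both = ctx.obs[:, k] & ctx.obs[:, l]
            if both.sum() < 30:
                continue
            c = float(np.cov(Yc[both, k], Yc[both, l])[0, 1])
            hk = G0[k, k] / (G0[k, k] + R0[k, k])
            hl = G0[l, l] / (G0[l, l] + R0[l, l])
            g = c * np.sqrt(hk * hl)
            G0[k, l] = G0[l, k] = g
            R0[k, l] = R0[l, k] = c - g
    return _shrink_to_pd(G0), _shrink_to_pd(R0)


def _fit_mme(
    context: MMEContext,
    traits: list[str],
    model: str,
    compute_se: bool = True,
) -> RemlFit:
    t = context.t
    scale = np.array([np.nanstd(context.Y[:, k], ddof=1) for k in range(t)])
    if np.any(~np.isfinite(scale)) or np.any(scale < 1e-12):
        return _degenerate_fit(traits, None, model)
    ctx = MMEContext.__new__(MMEContext)
    ctx.__dict__.update(context.__dict__)
    ctx.Y = context.Y / scale[None, :]
    nv = _n_vech(t)

    def value_and_grad(theta):
        Lg = _chol_of_theta(theta[:nv], t)
        Lr = _chol_of_theta(theta[nv:], t)
        f, dG, dR = ctx.value_and_score(Lg @ Lg.T, Lr @ Lr.T)
        if dG is None:
            return np.inf, np.zeros_like(theta)
        return f, np.concatenate([_grad_from_cov(dG, Lg), _grad_from_cov(dR, Lr)])

    if t > 1:
        G0, R0 = _mme_warm_start(ctx)
    else:
        G0, R0 = 0.4 * np.eye(t), 0.6 * np.eye(t)
    theta0 = np.concatenate([_cov_to_theta(G0), _cov_to_theta(R0)])
    bounds = [(-12.0, 6.0) if i == j else (-30.0, 30.0) for _ in range(2) for i in range(t) for j in range(i + 1)]
    theta_hat, m2ll, status, n_iter, trace = _optimize_with_grad(
        value_and_grad, theta0, bounds
    )
    Gs = _theta_to_cov(theta_hat[:nv], t)
    Rs = _theta_to_cov(theta_hat[nv:], t)
    # Jacobian offset back to the natural scale, per trait and observation
    cells_per_trait = np.zeros(t)
    for _, k in ctx.cells:
        cells_per_trait[k] += 1
    n_obs_per_trait = ctx.obs.sum(axis=0)
    jac = float(np.sum((n_obs_per_trait - cells_per_trait) * np.log(scale**2)))
    m2ll += jac
    trace = [v + jac for v in trace]
    phi_hat = np.concatenate([_vech(Gs), _vech(Rs)])

    def nll_natural(phi):
        return ctx.minus2_restricted_ll(_unvech(phi[:nv], t), _unvech(phi[nv:], t))

    cov = _information_cov(nll_natural, phi_hat) if compute_se else None
    herit, rg, rp = _derive_parameters(traits, Gs, Rs, phi_hat, cov, BOUNDARY_REL)

    b, u, covb = ctx.solve(Gs, Rs)
    lsm = {}
    sol_rows = {}
    for j, (hcell, k) in enumerate(ctx.cells):
        sol_rows[(ctx.herds[hcell], traits[k])] = b[j] * scale[k]
    herd_solutions = (
        pd.Series(sol_rows).unstack().reindex(index=ctx.herds, columns=traits)
        if sol_rows
        else pd.DataFrame(index=ctx.herds, columns=traits, dtype=float)
    )
    for k, tr in enumerate(traits):
        cols = [j for j, (hc, kk) in enumerate(ctx.cells) if kk == k]
        if not cols:
            lsm[tr] = ParameterEstimate(None, None, None)
            continue
        c = np.zeros(ctx.p)
        c[cols] = 1.0 / len(cols)
        est = float(c @ b) * scale[k]
        sem = float(np.sqrt(max(c @ covb @ c, 0.0))) * scale[k]
        lsm[tr] = ParameterEstimate(est, sem)

    S = np.outer(scale, scale)
    fit = RemlFit(
        traits=list(traits),
        G=Gs * S,
        R=Rs * S,
        heritability=herit,
        genetic_corr=rg,
        phenotypic_corr=rp,
        herd_solutions=herd_solutions,
        lsm=lsm,
        status=status,
        n_iter=n_iter,
        minus2_loglik=m2ll,
        loglik_trace=trace,
        param_cov=cov,
        model=model,
        _context=ctx,
        _theta=theta_hat,
        _scale=scale,
    )
    fit._u = u * scale[None, :]
    return fit


# ---------------------------------------------------------------------------
# public fitting API


def _prepare(phenotypes: pd.DataFrame, traits, parity):
    df = phenotypes
    if parity is not None and "parity" in df.columns:
        df = df[df["parity"] == parity]
    df = df.dropna(subset=["cow_id", "herd_id"])
    return df.reset_index(drop=True)


def fit_univariate(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: PedigreeTable,
    parity: int | None = 1,
    context: RotatedContext | None = None,
    compute_se: bool = True,
) -> RemlFit:
    """Univariate animal model: herd fixed, cow random with covariance A."""
    df = _prepare(phenotypes, [trait], parity)
    df = df.dropna(subset=[trait])
    if len(df) < 3:
        raise ValueError("too few records for a univariate fit")
    if context is None:
        context = RotatedContext(pedigree, df["cow_id"], df["herd_id"])
    Y = df[[trait]].to_numpy(dtype=float)
    return _fit_rotated(
        context, Y, [trait], model=f"univariate:{trait}", compute_se=compute_se
    )


def fit_bivariate(
    phenotypes: pd.DataFrame,
    traits: tuple,
    pedigree: PedigreeTable,
    parity: int | None = 1,
    context: RotatedContext | None = None,
    compute_se: bool = True,
) -> RemlFit:
    """Bivariate animal model for pairwise genetic/phenotypic correlations.

    Records missing one of the two traits are allowed; complete data uses
    the rotated route, incomplete data the MME route.
    """
    t1, t2 = traits
    df = _prepare(phenotypes, [t1, t2], parity)
    df = df.dropna(subset=[t1, t2], how="all")
    Y = df[[t1, t2]].to_numpy(dtype=float)
    if not np.isnan(Y).any():
        if context is None:
            context = RotatedContext(pedigree, df["cow_id"], df["herd_id"])
        return _fit_rotated(
            context, Y, [t1, t2], model=f"bivariate:{t1},{t2}", compute_se=compute_se
        )
    ctx = MMEContext(pedigree, df["cow_id"], df["herd_id"], Y)
    return _fit_mme(ctx, [t1, t2], model=f"bivariate:{t1},{t2}", compute_se=compute_se)


def fit_multitrait_parity(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: PedigreeTable,
    parities=(1, 2, 3),
    compute_se: bool = True,
) -> RemlFit:
    """Across-parity model with each parity of one trait as a distinct trait.

    Cows missing later parities (culling/censoring) contribute through
    trait-specific designs.  Each parity must be represented in at least two
    herds.
    """
    df = phenotypes[phenotypes["parity"].isin(parities)].dropna(subset=[trait])
    wide = df.pivot_table(index="cow_id", columns="parity", values=trait, aggfunc="first")
    herd_of = df.drop_duplicates("cow_id").set_index("cow_id")["herd_id"]
    wide = wide.reindex(columns=list(parities))
    cow_ids = wide.index.tolist()
    herds = herd_of.reindex(cow_ids)
    Y = wide.to_numpy(dtype=float)
    traits = [f"{trait}_p{p}" for p in parities]
    ctx = MMEContext(pedigree, cow_ids, herds, Y)
    per_trait = ctx.herds_per_trait()
    for k, p in enumerate(parities):
        if per_trait.get(k, 0) < 2:
            raise ValueError(f"parity {p} is represented in fewer than 2 herds")
    return _fit_mme(
        ctx, traits, model=f"multitrait_parity:{trait}", compute_se=compute_se
    )


def lsmeans(fit: RemlFit) -> pd.DataFrame:
    """Per-trait least squares means (unweighted over herds) with SEM."""
    rows = [
        {"trait": tr, "lsm": pe.estimate, "sem": pe.se}
        for tr, pe in fit.lsm.items()
    ]
    return pd.DataFrame(rows)


def ebv(fit: RemlFit) -> pd.DataFrame:
    """BLUP breeding values for every animal in the pedigree."""
    ctx = fit._context
    if ctx is None:
        raise ValueError("fit has no attached data context")
    if isinstance(ctx, RotatedContext):
        scale = fit._scale
        S = np.outer(scale, scale)
        u = ctx.blup(fit._Yr, fit.G / S, fit.R / S) * scale[None, :]
        ids = ctx.pedigree.ids
    else:
        u = fit._u
        ids = ctx.pedigree.ids
    return pd.DataFrame(u, index=pd.Index(ids, name="animal_id"), columns=fit.traits)
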