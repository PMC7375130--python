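"""Bifactor construction of a general cognitive ability (GCA) factor.

A 10-test cognitive battery is summarized by one general factor plus four
group factors.  The pipeline mirrors the classical exploratory route:

1. maximum-likelihood exploratory factor analysis (EFA) with ``n_group``
   factors on the train correlation matrix,
2. oblimin (quartimin) rotation of the first-order loadings,
3. a one-factor ML EFA of the first-order factor correlation matrix,
4. the Schmid-Leiman transformation, which distributes each test's common
   variance into a general loading and orthogonalized group loadings.

Held-out subjects are scored with regression (Thurstone) weights derived
from the train solution, after standardizing their raw test scores with the
*train* means and standard deviations, so no test-set statistic leaks into
the factor model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FactorModel",
    "FactorConvergenceError",
    "fit_bifactor",
    "score_subjects",
    "icc_2_1",
    "srmr",
    "model_implied_corr",
]

_PSI_LOWER = 0.005


class FactorConvergenceError(RuntimeError):
    """Raised when the ML factor extraction fails to converge."""


@dataclass
class FactorModel:
    """Fitted bifactor (Schmid-Leiman) solution for a test battery.

    Loadings are on the correlation metric; ``weights`` maps standardized
    test scores to the general-factor (GCA) score.
    """

    test_names: list[str]
    general_loadings: np.ndarray      # (p,)
    group_loadings: np.ndarray        # (p, n_group)
    uniquenesses: np.ndarray          # (p,)
    weights: np.ndarray               # (p,) regression scoring weights
    means: np.ndarray                 # (p,) train means
    sds: np.ndarray                   # (p,) train SDs
    omega_hierarchical: float
    srmr: float
    factor_corr: np.ndarray = field(repr=False, default=None)  # (q, q) oblique Phi
    pattern: np.ndarray = field(repr=False, default=None)      # (p, q) oblimin pattern
    second_order_loadings: np.ndarray = field(repr=False, default=None)  # (q,)
    heywood: bool = False

    @property
    def communalities(self) -> np.ndarray:
        return self.general_loadings**2 + (self.group_loadings**2).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "test_names": list(self.test_names),
            "general_loadings": self.general_loadings.tolist(),
            "group_loadings": self.group_loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "omega_hierarchical": float(self.omega_hierarchical),
            "srmr": float(self.srmr),
            "second_order_loadings": self.second_order_loadings.tolist(),
            "heywood": bool(self.heywood),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        return cls(
            test_names=list(d["test_names"]),
            general_loadings=np.asarray(d["general_loadings"], dtype=float),
            group_loadings=np.asarray(d["group_loadings"], dtype=float),
            uniquenesses=np.asarray(d["uniquenesses"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            omega_hierarchical=float(d["omega_hierarchical"]),
            srmr=float(d["srmr"]),
            second_order_loadings=np.asarray(d["second_order_loadings"], dtype=float),
            heywood=bool(d["heywood"]),
        )


# ---------------------------------------------------------------------------
# ML exploratory factor analysis (profile likelihood over uniquenesses)
# ---------------------------------------------------------------------------

def _efa_obj_grad(psi: np.ndarray, R: np.ndarray, q: int):
    """Negative profile log-likelihood and its gradient w.r.t. psi.

    Lawley-Maxwell parameterization: with S* = Psi^{-1/2} R Psi^{-1/2} and
    eigenvalues e_1 >= ... >= e_p, the objective is sum_{j>q}(e_j - log e_j - 1)
    and the optimal loadings are recoverable from the top-q eigenpairs.
    """
    sc = 1.0 / np.sqrt(psi)
    Rs = R * (sc[:, None] * sc)
    vals, vecs = np.linalg.eigh(Rs)
    vals = vals[::-1]
    e = vals[q:]
    f = float(np.sum(e - np.log(e)) - (len(psi) - q))
    lam = np.sqrt(np.maximum(vals[:q] - 1.0, 0.0))
    load = (vecs[:, ::-1][:, :q] * lam) * np.sqrt(psi)[:, None]
    g = (np.einsum("ij,ij->i", load, load) + psi - np.diag(R)) / psi**2
    return f, g, load


def _box_bfgs(fun_grad, x0, lower, upper, gtol=1e-5, ftol=1e-10, maxiter=120,
              H0=None):
    """Dense BFGS with gradient projection onto box bounds.

    Lean replacement for a generic bounded quasi-Newton solver, tuned for
    the small (p <= 10) smooth problems solved thousands of times inside
    cross-validation and permutation loops.  Returns (x, f, g, converged, H).
    """
    x = np.clip(x0, lower, upper)
    f, g = fun_grad(x)
    p = len(x)
    H = np.eye(p) if H0 is None else H0
    converged = False
    for _ in range(maxiter):
        # Projected gradient: zero where pressing against an active bound.
        pg = g.copy()
        pg[(x <= lower + 1e-12) & (g > 0)] = 0.0
        pg[(x >= upper - 1e-12) & (g < 0)] = 0.0
        if np.max(np.abs(pg)) < gtol:
            converged = True
            break
        d = -H @ g
        d[(x <= lower + 1e-12) & (d < 0)] = 0.0
        d[(x >= upper - 1e-12) & (d > 0)] = 0.0
        if d @ g > -1e-14:  # not a descent direction: reset to steepest
            H = np.eye(p)
            d = -pg
        t = 1.0
        fn, gn, xn = f, g, x
        ok = False
        for _ in range(25):
            xn = np.clip(x + t * d, lower, upper)
            fn, gn = fun_grad(xn)
            if fn <= f + 1e-4 * (g @ (xn - x)) or fn < f - 1e-14:
                ok = True
                break
            t *= 0.4
        if not ok or abs(f - fn) < ftol * max(1.0, abs(f)):
            x, f, g = xn, fn, gn
            converged = abs(f - fn) < max(ftol, 1e-9)
            break
        s = xn - x
        y = gn - g
        sy = s @ y
        if sy > 1e-12:
            rho = 1.0 / sy
            Hy = H @ y
            H = H - rho * (np.outer(s, Hy) + np.outer(Hy, s)) \
                + rho * (1.0 + rho * (y @ Hy)) * np.outer(s, s)
        else:
            H = np.eye(p)
        x, f, g = xn, fn, gn
    return x, f, g, converged, H


def ml_efa(R: np.ndarray, n_factors: int, psi0: np.ndarray | None = None,
           maxiter: int = 200, state: dict | None = None
           ) -> tuple[np.ndarray, np.ndarray]:
    """ML exploratory factor analysis of a correlation matrix.

    Returns (unrotated loadings (p, q), uniquenesses (p,)).  ``state`` may
    carry ``psi``/``H`` from a previous closely related problem to
    warm-start the quasi-Newton search (updated in place).  Raises
    :class:`FactorConvergenceError` when neither the in-module bounded
    BFGS nor the scipy L-BFGS-B fallback converges.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    q = int(n_factors)
    if R.shape != (p, p):
        raise ValueError("correlation matrix must be square")
    H0 = None
    if state is not None and psi0 is None:
        psi0 = state.get("psi")
        H0 = state.get("H")
    if psi0 is None:
        # Standard start: psi_j = (1 - q/(2p)) / diag(R^-1)_j
        psi0 = (1.0 - 0.5 * q / p) / np.diag(np.linalg.inv(R))
    psi0 = np.clip(psi0, _PSI_LOWER, 1.0)

    fg = lambda ps: _efa_obj_grad(ps, R, q)[:2]
    lo = np.full(p, _PSI_LOWER)
    hi = np.ones(p)
    psi, f, grad, converged, H = _box_bfgs(fg, psi0, lo, hi, H0=H0)
    if state is not None:
        state["psi"] = psi.copy()
        state["H"] = H
    if not converged:
        res = optimize.minimize(
            fg, psi, jac=True, method="L-BFGS-B",
            bounds=[(_PSI_LOWER, 1.0)] * p,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if res.fun <= f:
            psi = res.x
        _, grad, _ = _efa_obj_grad(psi, R, q)
        interior = (psi > _PSI_LOWER + 1e-9) & (psi < 1.0 - 1e-9)
        if not res.success and np.any(np.abs(grad[interior]) > 1e-3):
            raise FactorConvergenceError(
                f"ML factor extraction did not converge: {res.message}"
            )
    load = _efa_obj_grad(psi, R, q)[2]
    return load, psi


# ---------------------------------------------------------------------------
# Oblimin (quartimin) rotation via oblique gradient projection
# ---------------------------------------------------------------------------

def _quartimin_fg(L: np.ndarray):
    L2 = L * L
    M = L2 @ (1.0 - np.eye(L.shape[1]))
    return float(np.sum(L2 * M)) / 4.0, L * M


def quartimin(A: np.ndarray, T0: np.ndarray | None = None,
              max_iter: int = 500, tol: float = 1e-5, al0: float = 1.0,
              n_starts: int = 6):
    """Oblique quartimin rotation (oblimin with gamma = 0).

    Gradient-projection algorithm of Jennrich; returns (pattern, Phi, T, al).
    Without a supplied start the rotation is run from the identity plus
    ``n_starts`` deterministic random oblique starts and the lowest
    criterion value wins - the quartimin surface has local minima for
    highly symmetric loading patterns.
    """
    A = np.asarray(A, dtype=float)
    q = A.shape[1]
    if T0 is None:
        rng = np.random.default_rng(12345)
        best = None
        for s in range(n_starts + 1):
            if s == 0:
                T_init = np.eye(q)
            else:
                X = rng.standard_normal((q, q))
                T_init = X / np.sqrt(np.sum(X * X, axis=0))
            cand = _quartimin_gpa(A, T_init, max_iter, tol, al0)
            fval = _quartimin_fg(cand[0])[0]
            if best is None or fval < best[0] - 1e-12:
                best = (fval, cand)
        return best[1]
    return _quartimin_gpa(A, T0.copy(), max_iter, tol, al0)


def _quartimin_gpa(A: np.ndarray, T: np.ndarray, max_iter: int = 500,
                   tol: float = 1e-5, al0: float = 1.0):
    q = A.shape[1]
    al = al0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_fg(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)
        s = np.sqrt(np.sum(Gp * Gp))
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            Tt = X / np.sqrt(np.sum(X * X, axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin_fg(L)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, T, al


# ---------------------------------------------------------------------------
# Batched variants
#
# The permutation test refits the factor model in every fold of every
# permutation iteration: tens of thousands of 10-variable problems.  The
# batched routines below solve stacks of such problems with vectorized
# eigendecompositions (np.linalg.eigh on (M, p, p) arrays), a projected
# Barzilai-Borwein descent for the ML uniquenesses and a vectorized
# gradient-projection quartimin.  Problems the batched optimizers fail to
# polish are re-solved with the sequential path, so results match
# :func:`bifactor_from_corr` up to optimizer tolerance.
# ---------------------------------------------------------------------------

def _efa_batch_fg(psi, Rs, q):
    """Batched profile objective/gradient.  psi (M,p), Rs (M,p,p)."""
    M, p = psi.shape
    sc = 1.0 / np.sqrt(psi)
    A = Rs * (sc[:, :, None] * sc[:, None, :])
    vals, vecs = np.linalg.eigh(A)          # ascending
    e = vals[:, : p - q]
    f = np.sum(e - np.log(e), axis=1) - (p - q)
    top = vals[:, p - q:][:, ::-1]
    lam = np.sqrt(np.maximum(top - 1.0, 0.0))           # (M, q)
    load = vecs[:, :, p - q:][:, :, ::-1] * lam[:, None, :]
    load = load * np.sqrt(psi)[:, :, None]
    diag = np.einsum("mii->mi", Rs)
    g = (np.einsum("mjk,mjk->mj", load, load) + psi - diag) / psi**2
    return f, g, load


def _efa_batch(Rs: np.ndarray, q: int, gtol: float = 1e-5,
               maxiter: int = 500) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched ML EFA.  Returns (loadings (M,p,q), psi (M,p), converged (M,))."""
    Rs = np.asarray(Rs, dtype=float)
    M, p, _ = Rs.shape
    diag = np.einsum("mii->mi", Rs)
    psi = np.clip((1.0 - 0.5 * q / p) / np.einsum("mii->mi", np.linalg.inv(Rs)),
                  _PSI_LOWER, 1.0)
    lo, hi = _PSI_LOWER, 1.0
    f, g, _ = _efa_batch_fg(psi, Rs, q)
    t = np.full(M, 0.1)
    psi_out = psi.copy()
    conv = np.zeros(M, dtype=bool)
    idx = np.arange(M)                       # active problem ids
    s_prev = None
    for _ in range(maxiter):
        pg = g.copy()
        pg[(psi <= lo + 1e-12) & (g > 0)] = 0.0
        pg[(psi >= hi - 1e-12) & (g < 0)] = 0.0
        done = np.max(np.abs(pg), axis=1) < gtol
        if np.any(done):
            psi_out[idx[done]] = psi[done]
            conv[idx[done]] = True
            keep = ~done
            idx, psi, f, g, t = idx[keep], psi[keep], f[keep], g[keep], t[keep]
            Rs_a = Rs[idx]
            diag_a = diag[idx]
            if s_prev is not None:
                s_prev, y_prev = s_prev[keep], y_prev[keep]
            if idx.size == 0:
                break
        else:
            Rs_a, diag_a = Rs[idx], diag[idx]
        if s_prev is not None:
            sy = np.einsum("mj,mj->m", s_prev, y_prev)
            ss = np.einsum("mj,mj->m", s_prev, s_prev)
            good = sy > 1e-14
            t = np.where(good, np.clip(ss / np.where(good, sy, 1.0), 1e-5, 50.0), t)
        # Backtracking along the projection arc
        rem = np.arange(idx.size)
        x_new = psi.copy()
        f_new = f.copy()
        for _ in range(25):
            cand = np.clip(psi[rem] - t[rem, None] * g[rem], lo, hi)
            fc = _efa_batch_fg(cand, Rs_a[rem], q)[0]
            dec = np.einsum("mj,mj->m", g[rem], psi[rem] - cand)
            ok = fc <= f[rem] - 1e-4 * dec + 1e-14
            x_new[rem[ok]] = cand[ok]
            f_new[rem[ok]] = fc[ok]
            rem = rem[~ok]
            if rem.size == 0:
                break
            t[rem] *= 0.3
        if rem.size:                      # no progress possible: accept as-is
            x_new[rem] = psi[rem]
            f_new[rem] = f[rem]
        g_new = _efa_batch_fg(x_new, Rs_a, q)[1]
        s_prev = x_new - psi
        y_prev = g_new - g
        psi, f, g = x_new, f_new, g_new
    if idx.size:
        psi_out[idx] = psi
    load = _efa_batch_fg(psi_out, Rs, q)[2]
    return load, psi_out, conv


def _quartimin_batch_fg(L):
    q = L.shape[2]
    L2 = L * L
    Msum = L2 @ (1.0 - np.eye(q))
    f = np.einsum("mjk,mjk->m", L2, Msum) / 4.0
    return f, L * Msum


def _quartimin_batch(A: np.ndarray, tol: float = 1e-5, maxiter: int = 500):
    """Batched oblique quartimin.  Returns (pattern, Phi, converged)."""
    A = np.asarray(A, dtype=float)
    M, p, q = A.shape
    T = np.broadcast_to(np.eye(q), (M, q, q)).copy()
    al = np.ones(M)
    L = A.copy()
    Ti = np.broadcast_to(np.eye(q), (M, q, q)).copy()
    f, Gq = _quartimin_batch_fg(L)
    G = -np.matmul(np.matmul(L.transpose(0, 2, 1), Gq), Ti).transpose(0, 2, 1)
    T_out = T.copy()
    conv = np.zeros(M, dtype=bool)
    idx = np.arange(M)
    A_a = A
    for _ in range(maxiter):
        Gp = G - T * np.sum(T * G, axis=1, keepdims=True)
        s = np.sqrt(np.einsum("mjk,mjk->m", Gp, Gp))
        done = s < tol
        if np.any(done):
            T_out[idx[done]] = T[done]
            conv[idx[done]] = True
            keep = ~done
            idx, T, al, f, G, Gp, s = (idx[keep], T[keep], al[keep], f[keep],
                                       G[keep], Gp[keep], s[keep])
            A_a = A[idx]
            if idx.size == 0:
                break
        al = al * 2.0
        rem = np.arange(idx.size)
        T_new, f_new = T.copy(), f.copy()
        L_new = np.empty((idx.size, p, q))
        Gq_new = np.empty_like(L_new)
        Ti_new = np.empty_like(T)
        for _ in range(30):
            X = T[rem] - al[rem, None, None] * Gp[rem]
            Tt = X / np.sqrt(np.sum(X * X, axis=1, keepdims=True))
            Tti = np.linalg.inv(Tt)
            Lt = np.matmul(A_a[rem], Tti.transpose(0, 2, 1))
            ft, Gqt = _quartimin_batch_fg(Lt)
            ok = ft < f[rem] - 0.5 * s[rem] ** 2 * al[rem]
            sel = rem[ok]
            T_new[sel], f_new[sel] = Tt[ok], ft[ok]
            L_new[sel], Gq_new[sel], Ti_new[sel] = Lt[ok], Gqt[ok], Tti[ok]
            rem = rem[~ok]
            if rem.size == 0:
                break
            al[rem] *= 0.5
        if rem.size:                 # stalled line search: keep current T
            Tti = np.linalg.inv(T[rem])
            Lt = np.matmul(A_a[rem], Tti.transpose(0, 2, 1))
            ft, Gqt = _quartimin_batch_fg(Lt)
            L_new[rem], Gq_new[rem], Ti_new[rem], f_new[rem] = Lt, Gqt, Tti, ft
        T, f = T_new, f_new
        G = -np.matmul(np.matmul(L_new.transpose(0, 2, 1), Gq_new),
                       Ti_new).transpose(0, 2, 1)
    if idx.size:
        T_out[idx] = T
    Ti = np.linalg.inv(T_out)
    P = np.matmul(A, Ti.transpose(0, 2, 1))
    Phi = np.matmul(T_out.transpose(0, 2, 1), T_out)
    return P, Phi, conv


def bifactor_batch(Rs: np.ndarray, n_group: int = 4) -> dict:
    """Schmid-Leiman bifactor solutions for a stack of correlation matrices.

    Returns arrays: general (M,p), group (M,p,q), weights (M,p),
    uniquenesses (M,p).  Problems where a batched optimizer did not reach
    tolerance are re-solved with the sequential path.
    """
    Rs = np.asarray(Rs, dtype=float)
    M, p, _ = Rs.shape
    q = n_group
    A, psi1, c1 = _efa_batch(Rs, q)
    P, Phi, c2 = _quartimin_batch(A)
    flip = np.where(P.sum(axis=1) < 0, -1.0, 1.0)        # (M, q)
    P = P * flip[:, None, :]
    Phi = Phi * flip[:, :, None] * flip[:, None, :]
    gamma, _, c3 = _efa_batch(Phi, 1)
    gamma = gamma[:, :, 0]
    gsign = np.where(gamma.sum(axis=1) < 0, -1.0, 1.0)
    gamma = np.clip(gamma * gsign[:, None], -0.99999, 0.99999)
    Lg = np.einsum("mjk,mk->mj", P, gamma)
    lsign = np.where(Lg.sum(axis=1) < 0, -1.0, 1.0)
    Lg = Lg * lsign[:, None]
    Lf = P * np.sqrt(1.0 - gamma**2)[:, None, :]
    ok = c1 & c2 & c3
    for m in np.flatnonzero(~ok):
        sol = bifactor_from_corr(Rs[m], n_group=q)
        Lg[m], Lf[m] = sol["general"], sol["group"]
    W = np.linalg.solve(Rs, Lg[:, :, None])[:, :, 0]
    uniq = 1.0 - Lg**2 - (Lf**2).sum(axis=2)
    return {"general": Lg, "group": Lf, "weights": W, "uniquenesses": uniq,
            "converged": ok}


# ---------------------------------------------------------------------------
# Bifactor pipeline
# ---------------------------------------------------------------------------

def _as_matrix(scores) -> tuple[np.ndarray, list[str]]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), [str(c) for c in scores.columns]
    X = np.asarray(scores, dtype=float)
    return X, [f"test_{j + 1}" for j in range(X.shape[1])]


def bifactor_from_corr(R: np.ndarray, n_group: int = 4,
                       warm: dict | None = None) -> dict:
    """Schmid-Leiman bifactor solution from a correlation matrix.

    ``warm`` may carry ``psi1``/``T``/``psi2`` from a previous closely
    related fit to warm-start the optimizers (the solution itself does not
    depend on the start for well-conditioned problems; this is purely a
    speed device for repeated refits inside cross-validation/permutation).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    warm = warm if warm is not None else {}
    s1 = warm.setdefault("s1", {})
    s2 = warm.setdefault("s2", {})
    A, psi1 = ml_efa(R, n_group, state=s1)
    P, Phi, T, al = quartimin(A, T0=warm.get("T"), al0=warm.get("al", 1.0))
    warm["al"] = al
    # Sign-align group factors (positive manifold) so the second-order
    # factor loads positively on each.
    flip = np.where(P.sum(axis=0) < 0, -1.0, 1.0)
    P = P * flip
    T = T * flip
    Phi = T.T @ T
    gamma, psi2 = ml_efa(Phi, 1, state=s2)
    gamma = gamma[:, 0]
    if gamma.sum() < 0:
        gamma = -gamma
    gamma = np.clip(gamma, -0.99999, 0.99999)
    Lg = P @ gamma
    if Lg.sum() < 0:  # overall orientation: general ability scored positively
        Lg = -Lg
    Lf = P * np.sqrt(1.0 - gamma**2)
    h2 = Lg**2 + (Lf**2).sum(axis=1)
    uniq = 1.0 - h2
    heywood = bool(np.any(psi1 <= _PSI_LOWER + 1e-9) or np.any(uniq < -1e-6))
    warm["T"] = T.copy()
    return {
        "pattern": P, "phi": Phi, "general": Lg, "group": Lf,
        "uniquenesses": uniq, "gamma": gamma, "heywood": heywood,
        "unrotated": A, "psi1": psi1,
    }


def omega_hierarchical(general: np.ndarray, group: np.ndarray,
                       uniquenesses: np.ndarray) -> float:
    """Proportion of total score variance carried by the general factor.

    omega_h = (sum lambda_g)^2 / [(sum lambda_g)^2 + sum_f (sum_j lambda_fj)^2
    + sum psi].
    """
    num = general.sum() ** 2
    tot = num + float(np.sum(group.sum(axis=0) ** 2)) + float(uniquenesses.sum())
    return float(num / tot)


def model_implied_corr(model: FactorModel) -> np.ndarray:
    """Correlation matrix implied by the Schmid-Leiman solution."""
    Lg = model.general_loadings[:, None]
    S = Lg @ Lg.T + model.group_loadings @ model.group_loadings.T
    S[np.diag_indices_from(S)] = 1.0
    return S


def srmr(observed_corr: np.ndarray, model_implied_corr: np.ndarray) -> float:
    """Standardized root-mean-square residual over the off-diagonal
    lower triangle of two correlation matrices."""
    O = np.asarray(observed_corr, dtype=float)
    M = np.asarray(model_implied_corr, dtype=float)
    if O.shape != M.shape or O.shape[0] != O.shape[1]:
        raise ValueError("inputs must be square matrices of equal shape")
    iu = np.tril_indices(O.shape[0], k=-1)
    resid = (O - M)[iu]
    return float(np.sqrt(np.mean(resid**2)))


def fit_bifactor(scores, n_group: int = 4, warm: dict | None = None) -> FactorModel:
    """Fit the bifactor GCA model to an n x p battery of raw test scores.

    Scores are standardized internally; the stored means/SDs are the train
    statistics later reused by :func:`score_subjects`.
    """
    X, names = _as_matrix(scores)
    n, p = X.shape
    if n < 10 * n_group:
        raise ValueError(f"need at least {10 * n_group} subjects, got {n}")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite test scores")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [names[j] for j in np.flatnonzero(sds <= 0)]
        raise ValueError(f"zero train SD for tests: {bad}")
    R = np.corrcoef(X, rowvar=False)
    sol = bifactor_from_corr(R, n_group=n_group, warm=warm)
    if sol["heywood"]:
        warnings.warn("Heywood case: uniqueness at boundary", RuntimeWarning,
                      stacklevel=2)
    W = np.linalg.solve(R, sol["general"])
    om = omega_hierarchical(sol["general"], sol["group"], sol["uniquenesses"])
    model = FactorModel(
        test_names=names,
        general_loadings=sol["general"],
        group_loadings=sol["group"],
        uniquenesses=sol["uniquenesses"],
        weights=W,
        means=means,
        sds=sds,
        omega_hierarchical=om,
        srmr=np.nan,
        factor_corr=sol["phi"],
        pattern=sol["pattern"],
        second_order_loadings=sol["gamma"],
        heywood=sol["heywood"],
    )
    model.srmr = srmr(R, model_implied_corr(model))
    return model


def score_subjects(model: FactorModel, scores, use_train_stats: bool = True) -> np.ndarray:
    """Apply train-estimated GCA scoring weights to a (held-out) battery.

    With ``use_train_stats`` (the default, and the only train/test-clean
    choice inside cross-validation) raw scores are standardized with the
    model's stored train means/SDs before the weights are applied.
    """
    X, names = _as_matrix(scores)
    if isinstance(scores, pd.DataFrame) and names != model.test_names:
        raise ValueError("test-score columns do not match the fitted model")
    if X.shape[1] != len(model.test_names):
        raise ValueError("wrong number of test columns")
    if use_train_stats:
        mu, sd = model.means, model.sds
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("zero SD in scoring sample")
    return (X - mu) / sd @ model.weights


# ---------------------------------------------------------------------------
# Test-retest reliability
# ---------------------------------------------------------------------------

def icc_2_1(session1, session2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    For k = 2 sessions the ANOVA form is
    (MS_R - MS_E) / (MS_R + MS_E + (2/n) (MS_C - MS_E)).
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sessions must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("degenerate data: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + ms_e + (k / n) * (ms_c - ms_e)))
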