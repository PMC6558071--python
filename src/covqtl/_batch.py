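"""Batched Nelder-Mead engine for permutation scans and power studies.

Permutation thresholds need tens of thousands of independent marker fits
(one per permutation x marker).  Each fit is the same small simplex search,
so they are run in lockstep: one vectorised objective evaluates every
active problem per step, and the simplex update is applied with boolean
masks mirroring the classic Nelder-Mead branch structure exactly.

The objective uses per-class sufficient statistics.  The negative
log-likelihood under the Markov ("decay") covariance touches the data only
through class sums of y_d, y_d^2 and adjacent products y_d * y_{d+1}
(because the precision matrix is tridiagonal), so an evaluation is O(T) per
problem regardless of sample size.

This module is internal: results are numerically interchangeable with the
scipy path in covqtl.likelihood (tested), which remains the reference
implementation for single fits.
"""

from __future__ import annotations

import math

import numpy as np

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------


def pair_features(Y: np.ndarray) -> np.ndarray:
    """Per-individual features whose class sums are sufficient for the
    tridiagonal-precision likelihood: (y_d, y_d^2, y_d * y_{d+1})."""
    return np.concatenate([Y, Y * Y, Y[:, :-1] * Y[:, 1:]], axis=1)


def class_stats(Y: np.ndarray, G01: np.ndarray):
    """Class-wise sufficient statistics for binary markers.

    Y (n, d): stacked phenotypes; G01 (n, M): genotype codes in {0, 1}.
    Returns (n_cls (M, 2), S (M, 2, d), Cd (M, 2, d), Co (M, 2, d-1)) with
    class axis ordered by genotype code.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G01, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, d = Y.shape
    W = pair_features(Y)  # (n, 3d-1)
    tot = W.sum(axis=0)
    S1 = G.T @ W  # (M, 3d-1)
    S0 = tot - S1
    n1 = G.sum(axis=0)
    n0 = n - n1
    M = G.shape[1]
    out = np.stack([S0, S1], axis=1)  # (M, 2, 3d-1)
    n_cls = np.stack([n0, n1], axis=1)
    return n_cls, out[..., :d], out[..., d : 2 * d], out[..., 2 * d :]


def pooled_stats(Y: np.ndarray):
    """Single-class statistics (for the no-QTL model), shaped (1, 1, .)."""
    W = pair_features(np.asarray(Y, dtype=float)).sum(axis=0)
    d = Y.shape[1]
    return (
        np.array([[Y.shape[0]]], dtype=float),
        W[:d][None, None, :],
        W[d : 2 * d][None, None, :],
        W[2 * d :][None, None, :],
    )


# ---------------------------------------------------------------------------
# batched negative log-likelihood (full model, J classes, decay covariance)
# ---------------------------------------------------------------------------


def make_nll(n_cls, S, Cd, Co, times, include_static: bool,
             var_floor: tuple[float, float] = (0.0, 0.0)):
    """Build the batched objective f(theta (P, k)) -> (P,) for problems with
    per-class stats (B, J, .).  theta layout matches the scipy path: J
    blocks of (a, b, r[, mu_z]) then (log s2y, atanh rho[, atanh phi,
    log s2z])."""
    n_cls = np.asarray(n_cls, dtype=float)
    B, J = n_cls.shape
    T = times.size
    d = T + 1 if include_static else T
    if S.shape[-1] != d:
        raise ValueError("stats dimension does not match include_static")
    blk = 4 if include_static else 3
    n_tot = n_cls.sum(axis=1)
    fy, fz = var_floor

    def nll(theta: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        """idx selects the problem subset the parameter rows belong to."""
        th = np.atleast_2d(theta)
        sl = slice(None) if idx is None else idx
        nc = n_cls[sl]
        Ss, Cds, Cos = S[sl], Cd[sl], Co[sl]
        nt = n_tot[sl]

        P = th.shape[0]
        mean = th[:, : blk * J].reshape(P, J, blk)
        a = mean[..., 0]
        b = mean[..., 1]
        r = mean[..., 2]
        cov = th[:, blk * J :]
        with np.errstate(over="ignore", invalid="ignore"):
            s2y = fy + np.exp(np.clip(cov[:, 0], -700, 50))
            rho = np.tanh(cov[:, 1])
            bad = (cov[:, 0] > 50) | (a <= 0).any(axis=1)
            if include_static:
                mu_z = mean[..., 3]
                phi = np.tanh(cov[:, 2])
                s2z = fz + np.exp(np.clip(cov[:, 3], -700, 50))
                bad |= cov[:, 3] > 50

            ert = np.exp(-r[..., None] * times)  # (P, J, T)
            denom = 1.0 + b[..., None] * ert
            bad |= (denom <= 0).any(axis=(1, 2))
            denom = np.where(denom <= 0, 1.0, denom)
            g = a[..., None] / denom
            if include_static:
                mu = np.concatenate([g, mu_z[..., None]], axis=2)  # (P, J, d)
            else:
                mu = g

            # Q-statistics: class sums of e_d^2 and e_d e_{d+1}
            Qd = Cds - 2.0 * mu * Ss + nc[..., None] * mu * mu
            Qo = (
                Cos
                - mu[..., :-1] * Ss[..., 1:]
                - mu[..., 1:] * Ss[..., :-1]
                + nc[..., None] * mu[..., :-1] * mu[..., 1:]
            )

            one_m_rho2 = 1.0 - rho * rho
            w = 1.0 / (s2y * one_m_rho2)
            quad = Qd[..., 0] / s2y[:, None] + w[:, None] * (
                Qd[..., 1:T].sum(axis=2)
                - 2.0 * rho[:, None] * Qo[..., : T - 1].sum(axis=2)
                + (rho * rho)[:, None] * Qd[..., : T - 1].sum(axis=2)
            )  # (P, J)
            log_det = np.log(s2y) + (T - 1) * np.log(s2y * one_m_rho2)
            if include_static:
                cz = phi * np.sqrt(s2z / s2y)
                vz = s2z * (1.0 - phi * phi)
                quad = quad + (
                    Qd[..., T]
                    - 2.0 * cz[:, None] * Qo[..., T - 1]
                    + (cz * cz)[:, None] * Qd[..., T - 1]
                ) / vz[:, None]
                log_det = log_det + np.log(vz)

            out = 0.5 * (nt * (d * _LOG2PI + log_det) + quad.sum(axis=1))
        return np.where(bad | ~np.isfinite(out), np.inf, out)

    return nll


# ---------------------------------------------------------------------------
# lockstep Nelder-Mead
# ---------------------------------------------------------------------------


def nelder_mead_batch(
    fun,
    X0: np.ndarray,
    fatol: float = 1e-5,
    xatol: float = 5e-4,
    max_iter: int = 4000,
    adaptive: bool | None = None,
):
    """Minimize B independent k-dimensional problems in lockstep.

    ``fun(theta, idx)`` evaluates parameter rows ``theta`` belonging to the
    problem indices ``idx``.  Branching (reflect / expand / contract /
    shrink) mirrors the classic simplex update per problem via masks;
    converged problems are frozen and dropped from further evaluations.
    Returns (x_best (B, k), f_best (B,), n_iter, converged (B,)).
    """
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    B, k = X0.shape
    if adaptive is None:
        adaptive = k > 6
    if adaptive:
        chi = 1.0 + 2.0 / k
        psi = 0.75 - 1.0 / (2.0 * k)
        sigma = 1.0 - 1.0 / k
    else:
        chi, psi, sigma = 2.0, 0.5, 0.5
    rho = 1.0

    # initial simplex as in the classic implementation: +5% per coordinate
    X = np.repeat(X0[:, None, :], k + 1, axis=1)
    for j in range(k):
        step = np.where(X0[:, j] != 0.0, 0.05 * X0[:, j], 0.00025)
        X[:, j + 1, j] += step
    F = fun(X.reshape(-1, k), np.repeat(np.arange(B), k + 1)).reshape(B, k + 1)

    active = np.arange(B)
    converged = np.zeros(B, dtype=bool)
    it = 0
    while it < max_iter and active.size:
        it += 1
        Xa = X[active]
        Fa = F[active]
        order = np.argsort(Fa, axis=1)
        Fa = np.take_along_axis(Fa, order, axis=1)
        Xa = np.take_along_axis(Xa, order[:, :, None], axis=1)

        fspread = Fa[:, -1] - Fa[:, 0]
        xspread = np.abs(Xa - Xa[:, :1, :]).max(axis=(1, 2))
        done = (fspread <= fatol) & (xspread <= xatol)
        if done.any():
            ids = active[done]
            X[ids] = Xa[done]
            F[ids] = Fa[done]
            converged[ids] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            Xa, Fa = Xa[keep], Fa[keep]

        xbar = Xa[:, :-1, :].mean(axis=1)
        xw = Xa[:, -1, :]
        fw = Fa[:, -1]
        fb = Fa[:, 0]
        fsw = Fa[:, -2]

        xr = (1.0 + rho) * xbar - rho * xw
        fr = fun(xr, active)

        # second candidate per problem (evaluated in one batch)
        expand = fr < fb
        simple = (~expand) & (fr < fsw)
        out_c = (~expand) & (~simple) & (fr < fw)
        in_c = (~expand) & (~simple) & (~out_c)
        x2 = np.where(
            expand[:, None],
            (1.0 + rho * chi) * xbar - rho * chi * xw,
            np.where(
                out_c[:, None],
                (1.0 + psi * rho) * xbar - psi * rho * xw,
                (1.0 - psi) * xbar + psi * xw,
            ),
        )
        need2 = ~simple
        f2 = np.full(active.size, np.inf)
        if need2.any():
            f2[need2] = fun(x2[need2], active[need2])

        take_r = simple | (expand & (f2 >= fr))
        take_2 = (expand & (f2 < fr)) | (out_c & (f2 <= fr)) | (in_c & (f2 < fw))
        shrink = ~(take_r | take_2)

        Xa[take_r, -1, :] = xr[take_r]
        Fa[take_r, -1] = fr[take_r]
        Xa[take_2, -1, :] = x2[take_2]
        Fa[take_2, -1] = f2[take_2]

        if shrink.any():
            idx = np.flatnonzero(shrink)
            Xs = Xa[idx]
            Xs[:, 1:, :] = Xs[:, :1, :] + sigma * (Xs[:, 1:, :] - Xs[:, :1, :])
            fs = fun(
                Xs[:, 1:, :].reshape(-1, k), np.repeat(active[idx], k)
            ).reshape(idx.size, k)
            Xa[idx] = Xs
            Fa[idx, 1:] = fs

        X[active] = Xa
        F[active] = Fa

    best = np.argmin(F, axis=1)
    xb = X[np.arange(B), best]
    fb = F[np.arange(B), best]
    return xb, fb, it, converged


# ---------------------------------------------------------------------------
# high-level batched fits
# ---------------------------------------------------------------------------


def batch_fit(
    n_cls,
    S,
    Cd,
    Co,
    times: np.ndarray,
    X0: np.ndarray,
    include_static: bool = True,
    fatol: float = 1e-5,
    xatol: float = 5e-4,
    max_iter: int = 4000,
    var_floor: tuple[float, float] = (0.0, 0.0),
):
    """Fit the genotype-mean model to every problem's statistics; returns
    (log_lik (B,), theta (B, k), converged (B,))."""
    f = make_nll(n_cls, S, Cd, Co, times, include_static, var_floor)
    xb, fb, _, conv = nelder_mead_batch(f, X0, fatol, xatol, max_iter)
    return -fb, xb, conv
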