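"""Genotype-partitioned joint likelihood of the dynamic + static phenotype.

For one marker with J observed genotype classes the likelihood is

    L = prod_j prod_{i in class j} N( Y_i | mu_j, Sigma )

where Y_i = (y_i(t_1), ..., y_i(t_T), z_i), the class mean mu_j is a
logistic curve (a_j, b_j, r_j) on the grid with the static mean mu_zj
appended, and Sigma is the shared AR(1)-plus-cross-correlation covariance
(sigma2_y, rho_y, phi, sigma2_z) — one Sigma for all classes.

Model variants (all maximized by Nelder-Mead simplex from deterministic
data-driven warm starts):

    full          per-class (a_j, b_j, r_j, mu_zj)
    null          one shared (a, b, r, mu_z)        — no QTL anywhere
    growth_null   shared (a, b, r), per-class mu_zj — no curve effect
    biomass_null  per-class curve, shared mu_z      — no static effect

Setting ``include_static=False`` drops the z coordinate and the (phi,
sigma2_z) parameters, giving classical univariate functional mapping on the
longitudinal trait alone.

Packed parameter order (documented contract): per-class mean blocks in
class order — (a_j, b_j, r_j, mu_zj) for the full model; shared components
appear once in place of their per-class blocks — followed by the covariance
block (log sigma2_y, atanh rho_y, atanh phi, log sigma2_z).  Variances are
searched on the log scale and correlations through atanh, so the simplex
moves in an unconstrained space; parameter combinations that break the
model (non-positive logistic denominator, non-PD covariance) evaluate to
+inf rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from .covariance import (
    CovParams,
    JointCovariance,
    PDViolationError,
    ar1_logdet,
    build_joint_cov,
    markov_logdet,
)
from .data import LongitudinalDataset, MarkerPartition
from .growth import LogisticParams, fit_logistic_ls

__all__ = [
    "JointModelFit",
    "OptimOptions",
    "joint_log_density",
    "neg_log_lik",
    "fit_marker",
    "fit_null",
    "warm_start",
]

_LOG2PI = math.log(2.0 * math.pi)

MODELS = ("full", "null", "growth_null", "biomass_null")


@dataclass(frozen=True)
class OptimOptions:
    """Nelder-Mead settings for likelihood maximization.

    fatol/xatol are the simplex convergence tolerances on the negative
    log-likelihood and the (transformed) parameters; maxfev_mult caps
    function evaluations at maxfev_mult * dim.  Scans over permuted data
    may use a smaller cap (see covqtl.scan) since those fits start at a
    near-optimal warm start.
    """

    fatol: float = 1e-6
    xatol: float = 1e-4
    maxfev_mult: int = 2000

    def scipy_options(self, dim: int) -> dict:
        return {
            "fatol": self.fatol,
            "xatol": self.xatol,
            "maxiter": self.maxfev_mult * dim,
            "maxfev": self.maxfev_mult * dim,
            "adaptive": dim > 6,
        }


@dataclass
class JointModelFit:
    """Maximized likelihood for one marker under one model variant."""

    per_genotype: list[tuple[LogisticParams, float | None]]
    cov: CovParams | None
    sigma2_y: float
    rho_y: float
    log_lik: float
    n_params: int
    converged: bool
    model: str
    include_static: bool
    nfev: int = 0
    theta: np.ndarray | None = None

    @property
    def J(self) -> int:
        return len(self.per_genotype)


def joint_log_density(Y_i: np.ndarray, mu: np.ndarray, S: JointCovariance) -> float:
    """Exact multivariate normal log density of one stacked observation."""
    Y_i = np.asarray(Y_i, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if Y_i.shape != mu.shape or Y_i.size != S.dim:
        raise ValueError("dimension mismatch between observation, mean and covariance")
    if not S.cholesky_ok:
        raise PDViolationError("covariance not positive definite", S.params)
    e = Y_i - mu
    w = sla.solve_triangular(S.cholesky, e, lower=True)
    return -0.5 * (S.dim * _LOG2PI + S.log_det + float(w @ w))


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


def variance_floors(Y: np.ndarray, include_static: bool = True) -> tuple[float, float]:
    """Tiny data-scale lower bounds added to the variance parameters
    (sigma2 = floor + exp(theta)).  They bound the likelihood when a
    phenotype coordinate is degenerate (zero sample variance would
    otherwise send the simplex down an unbounded cliff) and perturb
    regular fits only at ~1e-9 relative."""
    T = Y.shape[1] - 1 if include_static else Y.shape[1]
    fy = 1e-9 * (float(np.mean(Y[:, :T] ** 2)) + 1.0)
    fz = 1e-9 * (float(np.mean(Y[:, T:] ** 2)) + 1.0) if include_static else 0.0
    return fy, fz


def n_mean_params(model: str, J: int, include_static: bool = True) -> int:
    if model == "full":
        return (3 + include_static) * J
    if model == "null":
        return 3 + include_static
    if model == "growth_null":
        return 3 + J  # static-trait means stay per class
    if model == "biomass_null":
        return 3 * J + 1
    raise ValueError(f"unknown model {model!r}")


def n_model_params(model: str, J: int, include_static: bool = True) -> int:
    return n_mean_params(model, J, include_static) + (4 if include_static else 2)


def pack_theta(
    curves: list[LogisticParams],
    mu_z: list[float] | None,
    cov: tuple[float, float, float, float] | tuple[float, float],
    model: str,
    include_static: bool = True,
) -> np.ndarray:
    """Pack natural-scale parameters into the optimizer vector."""
    parts: list[float] = []
    if model in ("full", "biomass_null"):
        for j, p in enumerate(curves):
            parts.extend([p.a, p.b, p.r])
            if include_static and model == "full":
                parts.append(mu_z[j])
        if model == "biomass_null":
            parts.append(mu_z[0])
    elif model in ("null", "growth_null"):
        p = curves[0]
        parts.extend([p.a, p.b, p.r])
        if include_static:
            parts.extend(mu_z if model == "growth_null" else [mu_z[0]])
    else:
        raise ValueError(f"unknown model {model!r}")
    if include_static:
        s2y, rho, phi, s2z = cov
        parts.extend(
            [math.log(s2y), math.atanh(rho), math.atanh(phi), math.log(s2z)]
        )
    else:
        s2y, rho = cov[0], cov[1]
        parts.extend([math.log(s2y), math.atanh(rho)])
    return np.asarray(parts, dtype=float)


def _unpack(
    theta: np.ndarray,
    model: str,
    J: int,
    include_static: bool,
    var_floor: tuple[float, float] = (0.0, 0.0),
):
    """Split the packed vector into curve triples, static means and
    covariance naturals.  Returns None when the covariance transform
    overflows (treated as an invalid point)."""
    k = n_mean_params(model, J, include_static)
    mean, cov = theta[:k], theta[k:]
    if np.any((cov[[0, -1]] if include_static else cov[[0]]) > 50):
        return None
    fy, fz = var_floor
    if include_static:
        s2y = fy + math.exp(max(cov[0], -700.0))
        rho = math.tanh(cov[1])
        phi = math.tanh(cov[2])
        s2z = fz + math.exp(max(cov[3], -700.0))
        covnat = (s2y, rho, phi, s2z)
    else:
        covnat = (fy + math.exp(max(cov[0], -700.0)), math.tanh(cov[1]))

    if model == "full":
        blk = 3 + include_static
        M = mean.reshape(J, blk)
        curves = M[:, :3]
        mus = M[:, 3] if include_static else None
    elif model == "null":
        curves = np.tile(mean[:3], (J, 1))
        mus = np.full(J, mean[3]) if include_static else None
    elif model == "growth_null":
        curves = np.tile(mean[:3], (J, 1))
        mus = mean[3 : 3 + J]
    elif model == "biomass_null":
        curves = mean[: 3 * J].reshape(J, 3)
        mus = np.full(J, mean[3 * J])
    else:
        raise ValueError(f"unknown model {model!r}")
    return curves, mus, covnat


# ---------------------------------------------------------------------------
# negative log-likelihood
# ---------------------------------------------------------------------------


def _nll_core(
    theta: np.ndarray,
    class_Y: list[np.ndarray],
    times: np.ndarray,
    model: str,
    include_static: bool,
    cross_structure: str,
    var_floor: tuple[float, float] = (0.0, 0.0),
) -> float:
    J = len(class_Y)
    T = times.size
    unpacked = _unpack(
        np.asarray(theta, dtype=float), model, J, include_static, var_floor
    )
    if unpacked is None:
        return math.inf
    curves, mus, covnat = unpacked

    if include_static:
        s2y, rho, phi, s2z = covnat
        if s2y <= 0 or s2z <= 0 or abs(rho) >= 1 or abs(phi) >= 1:
            return math.inf
    else:
        s2y, rho = covnat
        if s2y <= 0 or abs(rho) >= 1:
            return math.inf

    d = T + 1 if include_static else T
    n_total = sum(Y.shape[0] for Y in class_Y)

    if include_static and cross_structure == "constant":
        try:
            S = build_joint_cov(CovParams(s2y, rho, phi, s2z), T, "constant")
        except (PDViolationError, ValueError):
            return math.inf
        quad = 0.0
        for j in range(J):
            a, b, r = curves[j]
            if a <= 0 or not np.isfinite(a):
                return math.inf
            denom = 1.0 + b * np.exp(-r * times)
            if np.any(denom <= 0):
                return math.inf
            E = class_Y[j] - np.append(a / denom, mus[j])
            W = sla.solve_triangular(S.cholesky, E.T, lower=True)
            quad += float(np.sum(W * W))
        return 0.5 * (n_total * (d * _LOG2PI + S.log_det) + quad)

    # fast Markov closed forms (decay convention / univariate AR(1))
    one_m_rho2 = 1.0 - rho * rho
    inv_s2y = 1.0 / s2y
    if include_static:
        log_det = markov_logdet(CovParams(s2y, rho, phi, s2z), T)
        cz = phi * math.sqrt(s2z / s2y)
        inv_condz = 1.0 / (s2z * (1.0 - phi * phi))
    else:
        log_det = ar1_logdet(s2y, rho, T)

    quad = 0.0
    for j in range(J):
        a, b, r = curves[j]
        if a <= 0 or not np.isfinite(a):
            return math.inf
        denom = 1.0 + b * np.exp(-r * times)
        if np.any(denom <= 0):
            return math.inf
        Y = class_Y[j]
        Ey = Y[:, :T] - a / denom
        q = Ey[:, 0] ** 2 * inv_s2y
        if T > 1:
            innov = Ey[:, 1:] - rho * Ey[:, :-1]
            q = q + np.einsum("ij,ij->i", innov, innov) * (inv_s2y / one_m_rho2)
        if include_static:
            rz = (Y[:, T] - mus[j]) - cz * Ey[:, T - 1]
            q = q + rz * rz * inv_condz
        quad += float(q.sum())
    return 0.5 * (n_total * (d * _LOG2PI + log_det) + quad)


def _class_arrays(
    data: LongitudinalDataset, partition: MarkerPartition | None, include_static: bool
) -> list[np.ndarray]:
    M = data.joint if include_static else data.y
    if partition is None:
        return [M]
    M = M[partition.kept]
    return [M[partition.labels == j] for j in range(partition.J)]


def neg_log_lik(
    theta: np.ndarray,
    data: LongitudinalDataset,
    partition: MarkerPartition | None,
    model: str = "full",
    include_static: bool = True,
    cross_structure: str = "decay",
) -> float:
    """Negative log of the genotype-partitioned joint likelihood.

    Invalid parameter points (non-positive variances, |correlations| >= 1,
    logistic denominator crossing zero, non-PD covariance) return +inf by
    contract so the simplex search never sees an exception.
    """
    class_Y = _class_arrays(data, partition, include_static)
    Y = data.joint if include_static else data.y
    return _nll_core(
        theta, class_Y, data.grid.times, model, include_static, cross_structure,
        variance_floors(Y, include_static),
    )


# ---------------------------------------------------------------------------
# warm starts and fitting
# ---------------------------------------------------------------------------


def _moment_cov_start(
    data: LongitudinalDataset,
    class_Y: list[np.ndarray],
    curves: list[LogisticParams],
    mus: list[float] | None,
    times: np.ndarray,
    include_static: bool,
) -> tuple:
    """Moment estimates of the covariance block from curve residuals:
    pooled variance, pooled lag-1 autocorrelation, and the cross-correlation
    between the last-time residual and the static residual."""
    T = times.size
    res_y = []
    res_z = []
    for j, Y in enumerate(class_Y):
        g = curves[j].a / (1.0 + curves[j].b * np.exp(-curves[j].r * times))
        res_y.append(Y[:, :T] - g)
        if include_static:
            res_z.append(Y[:, T] - mus[j])
    E = np.vstack(res_y)
    s2y = max(float(np.mean(E * E)), 1e-8)
    lag = float(np.mean(E[:, 1:] * E[:, :-1])) / s2y if T > 1 else 0.0
    rho = float(np.clip(lag, -0.9, 0.9))
    if not include_static:
        return s2y, rho
    ez = np.concatenate(res_z)
    s2z = max(float(np.mean(ez * ez)), 1e-8)
    eT = np.concatenate([r[:, -1] for r in res_y])
    denom = math.sqrt(s2y * s2z)
    phi = float(np.clip(np.mean(eT * ez) / denom, -0.9, 0.9)) if denom > 0 else 0.0
    return s2y, rho, phi, s2z


def warm_start(
    data: LongitudinalDataset,
    partition: MarkerPartition | None,
    model: str = "full",
    include_static: bool = True,
) -> np.ndarray:
    """Deterministic data-driven start: per-class (or pooled) logistic
    least-squares fits of the class mean series, class static means, and
    moment estimates of the covariance block."""
    class_Y = _class_arrays(data, partition, include_static)
    times = data.grid.times
    T = times.size
    J = len(class_Y)

    curve_shared = model in ("null", "growth_null")
    if curve_shared:
        pooled = np.vstack(class_Y)[:, :T].mean(axis=0)
        shared_fit = fit_logistic_ls(pooled, data.grid).params
        curves = [shared_fit] * J
    else:
        curves = [fit_logistic_ls(Y[:, :T].mean(axis=0), data.grid).params for Y in class_Y]

    if include_static:
        if model in ("null", "biomass_null"):
            mz = float(np.mean(np.concatenate([Y[:, T] for Y in class_Y])))
            mus = [mz] * J
        else:
            mus = [float(Y[:, T].mean()) for Y in class_Y]
    else:
        mus = None

    cov = _moment_cov_start(data, class_Y, curves, mus, times, include_static)
    if model in ("null", "growth_null"):
        pack_curves = [curves[0]]
    else:
        pack_curves = curves
    if include_static:
        if model in ("null", "biomass_null"):
            pack_mus = [mus[0]]
        else:
            pack_mus = mus
    else:
        pack_mus = None
    return pack_theta(pack_curves, pack_mus, cov, model, include_static)


def _fit_from(
    theta0: np.ndarray,
    class_Y: list[np.ndarray],
    times: np.ndarray,
    model: str,
    include_static: bool,
    cross_structure: str,
    optim: OptimOptions,
    var_floor: tuple[float, float],
):
    res = minimize(
        _nll_core,
        theta0,
        args=(class_Y, times, model, include_static, cross_structure, var_floor),
        method="Nelder-Mead",
        options=optim.scipy_options(theta0.size),
    )
    return res


def fit_marker(
    data: LongitudinalDataset,
    partition: MarkerPartition | None,
    start: np.ndarray | None = None,
    model: str = "full",
    include_static: bool = True,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
) -> JointModelFit:
    """Maximize the marker likelihood by Nelder-Mead simplex.

    ``partition=None`` (or model="null") collapses all individuals into one
    class.  Never raises during a scan: a failed optimization returns a
    non-converged fit with log_lik = -inf.
    """
    if model == "null":
        partition = None
    class_Y = _class_arrays(data, partition, include_static)
    times = data.grid.times
    J = len(class_Y)
    var_floor = variance_floors(
        data.joint if include_static else data.y, include_static
    )

    if start is None:
        try:
            start = warm_start(data, partition, model, include_static)
        except Exception:
            start = None

    results = []
    if start is not None and np.isfinite(
        _nll_core(start, class_Y, times, model, include_static, cross_structure, var_floor)
    ):
        results.append(
            _fit_from(start, class_Y, times, model, include_static,
                      cross_structure, optim, var_floor)
        )
    if not results or not np.isfinite(results[0].fun):
        # fallback neutral start built from crude data scales
        Yall = np.vstack(class_Y)
        ymax = max(float(Yall[:, : times.size].max()), 1e-3)
        p0 = LogisticParams(a=ymax, b=5.0, r=0.5)
        mz0 = [float(Yall[:, -1].mean())] if include_static else None
        s2 = max(float(Yall[:, : times.size].var()), 1e-6)
        cov0 = (s2, 0.3, 0.0, max(float(Yall[:, -1].var()), 1e-6)) if include_static else (s2, 0.3)
        n_mz = {"full": J, "growth_null": J, "null": 1, "biomass_null": 1}[model]
        n_cv = 1 if model in ("null", "growth_null") else J
        theta0 = pack_theta(
            [p0] * n_cv,
            [mz0[0]] * n_mz if include_static else None,
            cov0,
            model,
            include_static,
        )
        results.append(
            _fit_from(theta0, class_Y, times, model, include_static,
                      cross_structure, optim, var_floor)
        )

    res = min(results, key=lambda r: r.fun)
    if not np.isfinite(res.fun):
        return JointModelFit(
            per_genotype=[],
            cov=None,
            sigma2_y=math.nan,
            rho_y=math.nan,
            log_lik=-math.inf,
            n_params=n_model_params(model, J, include_static),
            converged=False,
            model=model,
            include_static=include_static,
            nfev=int(res.nfev),
        )

    curves, mus, covnat = _unpack(res.x, model, J, include_static, var_floor)
    per_gt = []
    for j in range(J):
        a, b, r = curves[j]
        p = LogisticParams(a=float(a), b=float(b), r=float(r))
        per_gt.append((p, float(mus[j]) if mus is not None else None))
    if include_static:
        cov = CovParams(*covnat)
        s2y, rho = cov.sigma2_y, cov.rho_y
    else:
        cov = None
        s2y, rho = covnat
    return JointModelFit(
        per_genotype=per_gt,
        cov=cov,
        sigma2_y=float(s2y),
        rho_y=float(rho),
        log_lik=-float(res.fun),
        n_params=n_model_params(model, J, include_static),
        converged=bool(res.success),
        model=model,
        include_static=include_static,
        nfev=int(res.nfev),
        theta=res.x,
    )


def fit_null(
    data: LongitudinalDataset,
    include_static: bool = True,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
) -> JointModelFit:
    """Single-class fit shared by every marker of a dataset (cached on the
    dataset, since it does not involve genotypes)."""
    key = ("null", include_static, cross_structure, optim)
    if key not in data._cache:
        data._cache[key] = fit_marker(
            data,
            None,
            model="null",
            include_static=include_static,
            cross_structure=cross_structure,
            optim=optim,
        )
    return data._cache[key]
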