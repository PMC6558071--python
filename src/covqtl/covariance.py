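"""Joint covariance of the longitudinal trait and the terminal static trait.

The (T+1) x (T+1) covariance of the stacked observation (y(t_1..t_T), z) is

    Sigma = [[ Sigma_y,    Sigma_yz ],
             [ Sigma_yz',  sigma2_z ]]

with a stationary AR(1) longitudinal block, Sigma_y[s, t] =
sigma2_y * rho_y**|s-t|, and a cross block coupling the static trait to the
curve through the correlation coefficient phi.  Two cross-block conventions
are provided:

``decay`` (default)
    Sigma_yz[t] = phi * sigma_y * sigma_z * rho_y**(T - t): the static
    trait, measured after the last longitudinal time point, correlates most
    with the final measurement and the correlation decays backwards at the
    AR(1) rate.  This embeds z as one further step of the same Markov
    process (rescaled to variance sigma2_z), so Sigma is positive definite
    whenever |rho_y| < 1 and |phi| < 1, and its inverse is tridiagonal.

``constant``
    Sigma_yz[t] = phi * sigma_y * sigma_z for every t; positive
    definiteness is then a genuine runtime check.

The AR(1) block is indexed by measurement *order*, not clock time: the
correlation between consecutive measurements is rho_y regardless of grid
spacing (the classical stationary first-order autoregression on an ordered
series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

__all__ = [
    "CovParams",
    "JointCovariance",
    "PDViolationError",
    "build_ar1_block",
    "build_joint_cov",
    "solve_and_logdet",
]


class PDViolationError(ValueError):
    """Assembled covariance is not positive definite.

    Carries the offending parameters so the likelihood layer can map the
    failure to a -inf log-likelihood instead of crashing a genome scan.
    """

    def __init__(self, message: str, params: "CovParams | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class CovParams:
    """Covariance parameters (sigma2_y, rho_y, phi, sigma2_z).

    sigma2_y : longitudinal residual variance (trait units squared)
    rho_y    : AR(1) correlation between consecutive measurements, |rho_y| < 1
    phi      : dynamic-static correlation coefficient, |phi| < 1
    sigma2_z : static-trait residual variance
    """

    sigma2_y: float
    rho_y: float
    phi: float
    sigma2_z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.sigma2_y, self.rho_y, self.phi, self.sigma2_z)):
            raise ValueError("non-finite covariance parameters")
        if self.sigma2_y <= 0 or self.sigma2_z <= 0:
            raise ValueError("variances must be positive")
        if abs(self.rho_y) >= 1:
            raise ValueError(f"|rho_y| must be < 1, got {self.rho_y}")
        if abs(self.phi) >= 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")


@dataclass
class JointCovariance:
    matrix: np.ndarray
    log_det: float
    cholesky: np.ndarray  # lower-triangular factor
    cholesky_ok: bool
    params: CovParams
    cross_structure: str

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def build_ar1_block(sigma2_y: float, rho_y: float, T: int) -> np.ndarray:
    """Stationary AR(1) covariance: entry (s, t) = sigma2_y * rho_y**|s-t|."""
    if sigma2_y <= 0:
        raise ValueError("sigma2_y must be positive")
    if abs(rho_y) >= 1:
        raise ValueError(f"|rho_y| must be < 1, got {rho_y}")
    if T < 1:
        raise ValueError("T must be >= 1")
    idx = np.arange(T)
    return sigma2_y * rho_y ** np.abs(idx[:, None] - idx[None, :])


def build_joint_cov(c: CovParams, T: int, cross_structure: str = "decay") -> JointCovariance:
    """Assemble the joint (T+1) x (T+1) covariance and verify it by Cholesky."""
    if cross_structure not in ("decay", "constant"):
        raise ValueError(f"unknown cross_structure {cross_structure!r}")
    S = np.empty((T + 1, T + 1), dtype=float)
    S[:T, :T] = build_ar1_block(c.sigma2_y, c.rho_y, T)
    sy = np.sqrt(c.sigma2_y)
    sz = np.sqrt(c.sigma2_z)
    if cross_structure == "decay":
        cross = c.phi * sy * sz * c.rho_y ** (T - 1 - np.arange(T))
    else:
        cross = np.full(T, c.phi * sy * sz)
    S[:T, T] = cross
    S[T, :T] = cross
    S[T, T] = c.sigma2_z
    try:
        L = sla.cholesky(S, lower=True)
    except sla.LinAlgError as exc:
        raise PDViolationError(f"joint covariance not positive definite: {exc}", c) from exc
    log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
    return JointCovariance(
        matrix=S,
        log_det=log_det,
        cholesky=L,
        cholesky_ok=True,
        params=c,
        cross_structure=cross_structure,
    )


def solve_and_logdet(S: JointCovariance, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (Sigma^{-1} v, log det Sigma) via the cached Cholesky factor."""
    if not S.cholesky_ok:
        raise PDViolationError("covariance was not positive definite", S.params)
    x = sla.cho_solve((S.cholesky, True), np.asarray(v, dtype=float))
    return x, S.log_det


# ---------------------------------------------------------------------------
# Fast closed forms for the Markov ("decay") convention.
#
# Under the decay cross structure the stacked vector (y_1, ..., y_T, z) is a
# Gaussian Markov chain, so the log determinant and quadratic forms have
# O(T) innovation expressions.  These are used heavily by the likelihood
# layer; build_joint_cov is the reference they are tested against.
# ---------------------------------------------------------------------------


def markov_logdet(c: CovParams, T: int) -> float:
    """log det Sigma for the decay convention, via conditional variances."""
    ld = np.log(c.sigma2_y)  # first time point
    if T > 1:
        ld += (T - 1) * np.log(c.sigma2_y * (1.0 - c.rho_y**2))
    ld += np.log(c.sigma2_z * (1.0 - c.phi**2))
    return float(ld)


def markov_quadforms(E: np.ndarray, c: CovParams) -> np.ndarray:
    """Quadratic forms e' Sigma^{-1} e for rows of E, decay convention.

    E has shape (n, T+1): residual vectors with the static-trait residual in
    the last column.  Returns a length-n vector.  O(n*T) and allocation-light;
    this is the inner loop of every model fit.
    """
    E = np.atleast_2d(E)
    T = E.shape[1] - 1
    sy2 = c.sigma2_y
    Ey = E[:, :T]
    ez = E[:, T]
    q = Ey[:, 0] ** 2 / sy2
    if T > 1:
        innov = Ey[:, 1:] - c.rho_y * Ey[:, :-1]
        q = q + np.einsum("ij,ij->i", innov, innov) / (sy2 * (1.0 - c.rho_y**2))
    # z | y_T: mean phi * (sigma_z/sigma_y) * e_T, variance sigma2_z (1 - phi^2)
    resid_z = ez - c.phi * np.sqrt(c.sigma2_z / sy2) * Ey[:, T - 1]
    q = q + resid_z**2 / (c.sigma2_z * (1.0 - c.phi**2))
    return q


def markov_quadforms_y(Ey: np.ndarray, sigma2_y: float, rho_y: float) -> np.ndarray:
    """Quadratic forms for the longitudinal block alone (AR(1) only)."""
    Ey = np.atleast_2d(Ey)
    T = Ey.shape[1]
    q = Ey[:, 0] ** 2 / sigma2_y
    if T > 1:
        innov = Ey[:, 1:] - rho_y * Ey[:, :-1]
        q = q + np.einsum("ij,ij->i", innov, innov) / (sigma2_y * (1.0 - rho_y**2))
    return q


def ar1_logdet(sigma2_y: float, rho_y: float, T: int) -> float:
    """log det of the T x T AR(1) block: sigma2_y^T (1-rho^2)^(T-1)."""
    ld = T * np.log(sigma2_y)
    if T > 1:
        ld += (T - 1) * np.log(1.0 - rho_y**2)
    return float(ld)
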